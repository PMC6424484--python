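"""Window diversity statistics, differentiation, sweep scan, LD and f4.

All window arithmetic tiles the genome with half-open intervals
``[start, start + w)`` starting at position 1, matching the 1-based VCF
coordinate convention.  Statistics use pairwise-available data: a site's
sample size is the number of non-missing haplotypes at that site.

Per-site pi and Watterson's theta are normalised by the number of
*accessible* sites in the window — sites with a call rate of at least
80%, recorded in ``n_sites_typed`` — aligning the window denominator
with the genome-wide site filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import MISSING, GenotypeMatrix, ValidationError

ACCESSIBLE_CALL_RATE = 0.8


@dataclass
class WindowStat:
    chrom: str
    start: int
    end: int
    n_sites_typed: int
    data_fraction: float
    pi: float
    theta_w: float
    tajima_d: float  # nan when undefined


@dataclass
class FstWindow:
    chrom: str
    start: int
    end: int
    fst: float
    n_sites: int


@dataclass
class SweepWindow:
    chrom: str
    start: int
    end: int
    pi_wild: float
    pi_dom: float
    ratio: float  # inf when pi_dom == 0 < pi_wild
    top1pct_flag: bool


@dataclass
class LDBin:
    distance_bin_start: int
    distance_bin_end: int
    mean_r2: float
    n_pairs: int


@dataclass
class F4Result:
    f4_value: float
    jackknife_se: float
    z_score: float
    n_blocks: int


# ----------------------------------------------------------------------
# site filters


def filter_sites(g: GenotypeMatrix, min_call_rate: float = 0.8, min_maf: float = 0.02) -> GenotypeMatrix:
    """Retain sites with call rate >= ``min_call_rate`` and MAF >= ``min_maf``.

    Call rate and allele frequency are computed over non-missing
    haplotype slots; site order is preserved.
    """
    if not 0.0 <= min_maf <= 0.5:
        raise ValidationError("min_maf must be in [0, 0.5]")
    alt, called = g.allele_counts()
    total = 2 * g.n_samples
    call_rate = called / total
    with np.errstate(invalid="ignore"):
        p = np.where(called > 0, alt / np.maximum(called, 1), 0.0)
    maf = np.minimum(p, 1.0 - p)
    keep = (call_rate >= min_call_rate) & (maf >= min_maf)
    return g.take_sites(keep)


def thin_sites(
    g: GenotypeMatrix,
    window_bp: int = 50_000,
    min_spacing_bp: int = 25_000,
    seed: int = 0,
) -> GenotypeMatrix:
    """At most one polymorphic site per window, consecutive retained sites
    at least ``min_spacing_bp`` apart; uniform choice among eligible sites.
    """
    if not window_bp > min_spacing_bp >= 0:
        raise ValidationError("need window_bp > min_spacing_bp >= 0")
    rng = np.random.default_rng(seed)
    alt, called = g.allele_counts()
    polymorphic = (alt > 0) & (alt < called)
    keep_idx: list[int] = []
    for chrom in _chrom_order(g.chrom):
        on_chrom = np.flatnonzero(g.chrom == chrom)
        last_pos = -np.inf
        max_pos = g.pos[on_chrom].max()
        start = 1
        while start <= max_pos:
            in_window = on_chrom[
                (g.pos[on_chrom] >= start) & (g.pos[on_chrom] < start + window_bp)
            ]
            eligible = in_window[
                polymorphic[in_window] & (g.pos[in_window] >= last_pos + min_spacing_bp)
            ]
            if len(eligible):
                chosen = int(rng.choice(eligible))
                keep_idx.append(chosen)
                last_pos = g.pos[chosen]
            start += window_bp
    return g.take_sites(np.array(sorted(keep_idx), dtype=int))


# ----------------------------------------------------------------------
# diversity


def _harmonic(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n + 1))) if n >= 1 else 0.0


def tajima_constants(n: int) -> dict[str, float]:
    """Standard constants a1, a2, b1, b2, c1, c2, e1, e2 for sample size n."""
    a1 = _harmonic(n - 1)
    a2 = float(np.sum(1.0 / np.arange(1, n) ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def _chrom_order(chrom: np.ndarray) -> list:
    seen: list = []
    for c in chrom:
        if c not in seen:
            seen.append(c)
    return seen


def _windows(pos_max: int, window_bp: int):
    start = 1
    while start <= pos_max:
        yield start, start + window_bp
        start += window_bp


def window_diversity(
    g: GenotypeMatrix,
    window_bp: int = 10_000,
    min_data_fraction: float = 0.3,
) -> list[WindowStat]:
    """Per-window pi, Watterson's theta and Tajima's D.

    pi is the mean pairwise difference per accessible site; theta_w sums
    the per-site Watterson contribution 1/a_{n_s - 1} over segregating
    sites.  Tajima's D uses the standard variance constants evaluated at
    the mean per-site haplotype count (exact when the count is uniform);
    it is undefined (nan) for fewer than 4 haplotypes or zero
    segregating sites.  Windows failing the data-fraction rule are
    omitted.
    """
    if g.n_sites == 0:
        raise ValidationError("empty genotype matrix")
    alt, called = g.allele_counts()
    out: list[WindowStat] = []
    total_slots = 2 * g.n_samples
    for chrom in _chrom_order(g.chrom):
        on_chrom = np.flatnonzero(g.chrom == chrom)
        pos = g.pos[on_chrom]
        for start, end in _windows(int(pos.max()), window_bp):
            idx = on_chrom[(pos >= start) & (pos < end)]
            if len(idx) == 0:
                continue
            call_rate = called[idx] / total_slots
            accessible = idx[(call_rate >= ACCESSIBLE_CALL_RATE) & (called[idx] >= 2)]
            n_typed = len(accessible)
            frac = n_typed / len(idx)
            if frac < min_data_fraction or n_typed == 0:
                continue
            c1 = alt[accessible].astype(float)
            ns = called[accessible].astype(float)
            pi_sum = float(np.sum(2.0 * c1 * (ns - c1) / (ns * (ns - 1.0))))
            seg = (c1 > 0) & (c1 < ns)
            theta_sum = float(
                np.sum([1.0 / _harmonic(int(n) - 1) for n in ns[seg]])
            ) if seg.any() else 0.0
            S = int(seg.sum())
            n_mean = int(round(float(ns.mean())))
            if n_mean >= 4 and S > 0:
                k = tajima_constants(n_mean)
                var = k["e1"] * S + k["e2"] * S * (S - 1)
                d = (pi_sum - theta_sum) / np.sqrt(var) if var > 0 else np.nan
            else:
                d = np.nan
            out.append(
                WindowStat(
                    chrom=str(chrom), start=start, end=end,
                    n_sites_typed=n_typed, data_fraction=frac,
                    pi=pi_sum / n_typed, theta_w=theta_sum / n_typed,
                    tajima_d=float(d),
                )
            )
    return out


# ----------------------------------------------------------------------
# differentiation


def hudson_fst(
    gA: GenotypeMatrix, gB: GenotypeMatrix, window_bp: int = 10_000
) -> list[FstWindow]:
    """Hudson's Fst, ratio-of-averages per non-overlapping window.

    Per site: num = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1) and
    den = p1(1-p2) + p2(1-p1); window Fst = sum(num)/sum(den).  Sites
    with fewer than 2 called haplotypes in either group are skipped.
    """
    if not (
        np.array_equal(gA.chrom, gB.chrom) and np.array_equal(gA.pos, gB.pos)
    ):
        raise ValidationError("matrices must share site coordinates")
    a1, n1 = gA.allele_counts()
    a2, n2 = gB.allele_counts()
    usable = (n1 >= 2) & (n2 >= 2)
    p1 = np.where(usable, a1 / np.maximum(n1, 1), np.nan)
    p2 = np.where(usable, a2 / np.maximum(n2, 1), np.nan)
    with np.errstate(invalid="ignore"):
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / np.maximum(n1 - 1, 1) - p2 * (1 - p2) / np.maximum(n2 - 1, 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    out: list[FstWindow] = []
    for chrom in _chrom_order(gA.chrom):
        on_chrom = np.flatnonzero(gA.chrom == chrom)
        pos = gA.pos[on_chrom]
        for start, end in _windows(int(pos.max()), window_bp):
            idx = on_chrom[(pos >= start) & (pos < end)]
            idx = idx[usable[idx]]
            if len(idx) == 0:
                continue
            den_sum = float(np.nansum(den[idx]))
            if den_sum == 0.0:
                continue
            fst = float(np.nansum(num[idx])) / den_sum
            out.append(FstWindow(chrom=str(chrom), start=start, end=end, fst=fst, n_sites=len(idx)))
    return out


def mean_fst(windows: list[FstWindow]) -> float:
    return float(np.mean([w.fst for w in windows])) if windows else np.nan


# ----------------------------------------------------------------------
# sweep scan


def sweep_scan(
    wild_stats: list[WindowStat], dom_stats: list[WindowStat]
) -> list[SweepWindow]:
    """pi_wild / pi_domesticate ratio per shared window, flagging the top 1%.

    The flag requires strict exceedance of the empirical 99th percentile
    of finite ratios (linear interpolation); infinite ratios — zero
    domesticate diversity with positive wild diversity — are always
    flagged.
    """
    dom_by_key = {(w.chrom, w.start): w for w in dom_stats}
    shared = [
        (w, dom_by_key[(w.chrom, w.start)])
        for w in wild_stats
        if (w.chrom, w.start) in dom_by_key
    ]
    if not shared:
        raise ValidationError("no shared windows between wild and domesticate scans")
    ratios = []
    for w, d in shared:
        if d.pi > 0:
            ratios.append(w.pi / d.pi)
        elif w.pi > 0:
            ratios.append(np.inf)
        else:
            ratios.append(np.nan)
    ratios = np.array(ratios)
    finite = ratios[np.isfinite(ratios)]
    q99 = float(np.quantile(finite, 0.99)) if len(finite) else np.inf
    out = []
    for (w, d), r in zip(shared, ratios):
        flag = bool(np.isinf(r) or (np.isfinite(r) and r > q99))
        out.append(
            SweepWindow(
                chrom=w.chrom, start=w.start, end=w.end,
                pi_wild=w.pi, pi_dom=d.pi, ratio=float(r), top1pct_flag=flag,
            )
        )
    return out


# ----------------------------------------------------------------------
# linkage disequilibrium


def ld_decay(
    g: GenotypeMatrix,
    region_window_bp: int = 1_000_000,
    bin_bp: int = 1_000,
) -> list[LDBin]:
    """Mean genotype-dosage r^2 binned by inter-site distance.

    r^2 is the squared Pearson correlation of alt-allele dosages over
    samples non-missing at both sites (phase-free); pairs are restricted
    to the same region window; zero-variance sites contribute no pairs.
    """
    if g.n_sites < 2:
        raise ValidationError("need at least 2 sites for LD")
    dosage = g.dosage()
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for chrom in _chrom_order(g.chrom):
        on_chrom = np.flatnonzero(g.chrom == chrom)
        pos = g.pos[on_chrom]
        for start, end in _windows(int(pos.max()), region_window_bp):
            idx = on_chrom[(pos >= start) & (pos < end)]
            if len(idx) < 2:
                continue
            X = dosage[:, idx]
            ok = ~np.isnan(X)
            Xz = np.where(ok, X, 0.0)
            okf = ok.astype(float)
            n = okf.T @ okf
            sx = Xz.T @ okf
            sy = okf.T @ Xz
            sxy = Xz.T @ Xz
            sxx = (Xz**2).T @ okf
            syy = okf.T @ (Xz**2)
            with np.errstate(invalid="ignore", divide="ignore"):
                cov = sxy - sx * sy / n
                vx = sxx - sx**2 / n
                vy = syy - sy**2 / n
                r2 = cov**2 / (vx * vy)
            p = g.pos[idx]
            dist = np.abs(p[None, :] - p[:, None])
            iu = np.triu_indices(len(idx), k=1)
            r2u, du, nu = r2[iu], dist[iu], n[iu]
            valid = np.isfinite(r2u) & (nu >= 2)
            bins = (du[valid] // bin_bp).astype(int)
            if len(bins):
                s = np.bincount(bins, weights=r2u[valid])
                c = np.bincount(bins)
                for b in np.flatnonzero(c):
                    sums[b] = sums.get(b, 0.0) + float(s[b])
                    counts[b] = counts.get(b, 0) + int(c[b])
    return [
        LDBin(
            distance_bin_start=b * bin_bp,
            distance_bin_end=(b + 1) * bin_bp,
            mean_r2=sums[b] / counts[b],
            n_pairs=counts[b],
        )
        for b in sorted(sums)
    ]


def moving_average(values: np.ndarray, half_window: int = 2) -> np.ndarray:
    """Centered moving-average smoother for plotting LD decay curves."""
    v = np.asarray(values, dtype=float)
    out = np.empty_like(v)
    for i in range(len(v)):
        lo, hi = max(0, i - half_window), min(len(v), i + half_window + 1)
        out[i] = np.nanmean(v[lo:hi])
    return out


# ----------------------------------------------------------------------
# four-population test


def f4_test(
    gA: GenotypeMatrix,
    gB: GenotypeMatrix,
    gC: GenotypeMatrix,
    gD: GenotypeMatrix,
    block_size: int = 100,
) -> F4Result:
    """f4(A,B;C,D) with a leave-one-block-out jackknife standard error.

    f4 is the mean over usable sites of (pA - pB)(pC - pD); blocks are
    consecutive runs of ``block_size`` usable sites.
    """
    mats = [gA, gB, gC, gD]
    for m in mats[1:]:
        if not (np.array_equal(m.chrom, gA.chrom) and np.array_equal(m.pos, gA.pos)):
            raise ValidationError("matrices must share site coordinates")
    freqs, called = [], []
    for m in mats:
        a, n = m.allele_counts()
        freqs.append(np.where(n > 0, a / np.maximum(n, 1), np.nan))
        called.append(n)
    usable = np.all([n > 0 for n in called], axis=0)
    within_poly = np.any([(f > 0) & (f < 1) for f in freqs], axis=0)
    between_diff = np.zeros_like(usable)
    for i in range(4):
        for j in range(i + 1, 4):
            with np.errstate(invalid="ignore"):
                between_diff |= freqs[i] != freqs[j]
    if not np.any(usable & (within_poly | between_diff)):
        raise ValidationError("all sites monomorphic in all four groups")
    idx = np.flatnonzero(usable)
    prod = (freqs[0][idx] - freqs[1][idx]) * (freqs[2][idx] - freqs[3][idx])
    n_blocks = int(np.ceil(len(prod) / block_size))
    if n_blocks < 2:
        raise ValidationError("need at least 2 jackknife blocks")
    f4 = float(np.mean(prod))
    loo = []
    for b in range(n_blocks):
        mask = np.ones(len(prod), dtype=bool)
        mask[b * block_size : (b + 1) * block_size] = False
        loo.append(float(np.mean(prod[mask])))
    loo = np.array(loo)
    se = float(np.sqrt((n_blocks - 1) / n_blocks * np.sum((loo - loo.mean()) ** 2)))
    z = f4 / se if se > 0 else np.nan
    return F4Result(f4_value=f4, jackknife_se=se, z_score=float(z), n_blocks=n_blocks)
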