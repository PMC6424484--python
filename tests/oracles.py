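"""Independent brute-force reference implementations.

Every function here recomputes a statistic from its definition with
plain Python loops, independently of the package's vectorized code
paths, so that agreement is evidence of correctness rather than shared
bugs.
"""

from __future__ import annotations

import itertools
from math import comb, isnan

import numpy as np

MISSING = -1


# ----------------------------------------------------------------------
# diversity (complete-data haplotype matrix, rows = haplotypes)


def tajima_stats(haps: np.ndarray) -> tuple[float, float, float]:
    """(pi_sum, theta_sum, D) from the published formulas; D is nan when
    undefined.  ``haps``: (n, m) 0/1 matrix with no missing data."""
    n, m = haps.shape
    pi_sum = 0.0
    S = 0
    for j in range(m):
        ones = int(haps[:, j].sum())
        if 0 < ones < n:
            S += 1
        diffs = ones * (n - ones)
        pi_sum += diffs / comb(n, 2)
    a1 = sum(1.0 / i for i in range(1, n))
    theta_sum = S / a1
    if n < 4 or S == 0:
        return pi_sum, theta_sum, float("nan")
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    d = (pi_sum - theta_sum) / var**0.5 if var > 0 else float("nan")
    return pi_sum, theta_sum, d


def hudson_fst(countsA, countsB) -> float:
    """Ratio-of-averages Hudson Fst from per-site (alt, called) counts."""
    num = den = 0.0
    for (a1, n1), (a2, n2) in zip(countsA, countsB):
        if n1 < 2 or n2 < 2:
            continue
        p1, p2 = a1 / n1, a2 / n2
        num += (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den += p1 * (1 - p2) + p2 * (1 - p1)
    return num / den if den else float("nan")


def ld_bins(dosage: np.ndarray, positions: np.ndarray, bin_bp: int) -> dict[int, tuple[float, int]]:
    """Mean r^2 per distance bin by direct all-pairs loops (pairwise-
    complete Pearson correlation of dosages)."""
    m = dosage.shape[1]
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for i in range(m):
        for j in range(i + 1, m):
            xi, xj = dosage[:, i], dosage[:, j]
            ok = ~(np.isnan(xi) | np.isnan(xj))
            if ok.sum() < 2:
                continue
            a, b = xi[ok], xj[ok]
            va = a.var()
            vb = b.var()
            if va == 0 or vb == 0:
                continue
            r = np.corrcoef(a, b)[0, 1]
            d = abs(int(positions[j]) - int(positions[i]))
            k = d // bin_bp
            sums[k] = sums.get(k, 0.0) + r * r
            counts[k] = counts.get(k, 0) + 1
    return {k: (sums[k] / counts[k], counts[k]) for k in sums}


def f4_jackknife(freqs: list[np.ndarray], block_size: int) -> tuple[float, float]:
    """(f4, jackknife SE) by an explicit delete-one-block loop over
    per-site allele frequencies of the four groups (no nans)."""
    pa, pb, pc, pd = freqs
    prod = [(pa[i] - pb[i]) * (pc[i] - pd[i]) for i in range(len(pa))]
    f4 = sum(prod) / len(prod)
    n_blocks = (len(prod) + block_size - 1) // block_size
    loo = []
    for b in range(n_blocks):
        rest = [
            v for i, v in enumerate(prod) if not (b * block_size <= i < (b + 1) * block_size)
        ]
        loo.append(sum(rest) / len(rest))
    mean = sum(loo) / len(loo)
    se = ((n_blocks - 1) / n_blocks * sum((v - mean) ** 2 for v in loo)) ** 0.5
    return f4, se


# ----------------------------------------------------------------------
# distances and silhouettes


def ibs_distance(dosage: np.ndarray) -> np.ndarray:
    """1 - IBS over mutually non-missing sites, by direct loops."""
    n = dosage.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals = []
            for a, b in zip(dosage[i], dosage[j]):
                if not (isnan(a) or isnan(b)):
                    vals.append((2 - abs(a - b)) / 2)
            out[i, j] = out[j, i] = 1 - sum(vals) / len(vals)
    return out


def silhouettes(dist: np.ndarray, labels: list[str]) -> list[float]:
    """s(i) = (b - a)/max(a, b) with b = nearest foreign-group mean."""
    n = len(labels)
    out = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        a = sum(dist[i][j] for j in own) / len(own)
        bs = []
        for g in set(labels) - {labels[i]}:
            members = [j for j in range(n) if labels[j] == g]
            bs.append(sum(dist[i][j] for j in members) / len(members))
        b = min(bs)
        out.append((b - a) / max(a, b) if max(a, b) > 0 else float("nan"))
    return out


# ----------------------------------------------------------------------
# Mann-Whitney exact p by rank-sum distribution enumeration


def mwu_two_sided_p(x, y) -> float:
    """Two-sided exact p from the permutation distribution of U, where
    U is computed directly from pairwise comparisons (ties count 1/2)."""
    pooled = list(x) + list(y)
    n1 = len(x)
    n = len(pooled)

    def u_of(combo):
        in_first = set(combo)
        rest = [pooled[i] for i in range(n) if i not in in_first]
        u = 0.0
        for i in combo:
            for v in rest:
                if pooled[i] > v:
                    u += 1.0
                elif pooled[i] == v:
                    u += 0.5
        return u

    u_obs = u_of(tuple(range(n1)))
    center = n1 * (n - n1) / 2.0
    dev = abs(u_obs - center)
    extreme = total = 0
    for combo in itertools.combinations(range(n), n1):
        total += 1
        if abs(u_of(combo) - center) >= dev - 1e-12:
            extreme += 1
    return extreme / total


# ----------------------------------------------------------------------
# minimum spanning tree by Prüfer enumeration


def mst_weight_exhaustive(strings: list[str]) -> int:
    """Minimum total weight over all labeled spanning trees (Prüfer)."""
    n = len(strings)
    if n == 1:
        return 0
    dist = [
        [sum(a != b for a, b in zip(strings[i], strings[j])) for j in range(n)]
        for i in range(n)
    ]
    if n == 2:
        return dist[0][1]
    best = None
    for prufer in itertools.product(range(n), repeat=n - 2):
        degree = [1] * n
        for v in prufer:
            degree[v] += 1
        weight = 0
        deg = list(degree)
        seq = list(prufer)
        leaves = sorted(v for v in range(n) if deg[v] == 1)
        for v in seq:
            leaf = leaves.pop(0)
            weight += dist[leaf][v]
            deg[v] -= 1
            if deg[v] == 1:
                import bisect

                bisect.insort(leaves, v)
        weight += dist[leaves[0]][leaves[1]]
        if best is None or weight < best:
            best = weight
    return best
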