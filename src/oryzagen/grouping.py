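"""Genetic distances, trees, ordination, and silhouette-based curation.

Group labels are taken as given (from the metadata file); the silhouette
filter curates them rather than inferring clusters.  The per-sample
silhouette score is s(i) = (b(i) - a(i)) / max(a(i), b(i)) with a(i) the
mean distance to the sample's own group (excluding itself) and b(i), by
default, the mean distance to the nearest foreign group (the Rousseeuw
convention); ``b_mode="all-foreign-mean"`` instead averages over all
foreign samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import GenotypeMatrix, ValidationError


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValidationError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T):
            raise ValidationError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValidationError("distance matrix diagonal not zero")
        if np.any(self.values < -1e-12):
            raise ValidationError("negative distances")

    def subset(self, ids: list[str]) -> "DistanceMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(rows, rows)])


@dataclass
class SilhouetteReport:
    sample_ids: list[str]
    labels: list[str]
    a: np.ndarray  # mean within-group distance
    b: np.ndarray  # foreign-group distance
    s: np.ndarray  # silhouette score, nan when undefined


@dataclass
class CoreSet:
    retained: list[str]
    iterations_run: int
    removed_per_iteration: list[list[str]]
    final_report: SilhouetteReport
    stopped_on_small_group: bool = False


def pairwise_distance(g: GenotypeMatrix) -> DistanceMatrix:
    """1 - IBS distance from alt-allele dosages.

    IBS(i, j) is the mean over mutually non-missing sites of
    (2 - |dosage_i - dosage_j|) / 2.  A pair with no mutually typed
    sites is an error.
    """
    if g.n_samples < 2:
        raise ValidationError("need at least 2 samples")
    d = g.dosage()
    ok = ~np.isnan(d)
    dz = np.where(ok, d, 0.0)
    okf = ok.astype(float)
    n_shared = okf @ okf.T
    # sum over shared sites of |di - dj| via the identity on dosage values
    # |di - dj| for di,dj in {0,1,2}: use three indicator matrices
    absdiff = np.zeros_like(n_shared)
    for a in (0, 1, 2):
        ia = ((d == a) & ok).astype(float)
        for b in (0, 1, 2):
            ib = ((d == b) & ok).astype(float)
            if abs(a - b):
                absdiff += abs(a - b) * (ia @ ib.T)
    bad = np.argwhere(n_shared == 0)
    bad = bad[bad[:, 0] < bad[:, 1]]
    if len(bad):
        i, j = bad[0]
        raise ValidationError(
            f"no mutually typed sites for pair ({g.sample_ids[i]}, {g.sample_ids[j]})"
        )
    ibs = (2.0 * n_shared - absdiff) / (2.0 * n_shared)
    values = 1.0 - ibs
    np.fill_diagonal(values, 0.0)
    values = (values + values.T) / 2.0
    return DistanceMatrix(list(g.sample_ids), values)


def neighbor_joining(dm: DistanceMatrix) -> str:
    """Saitou-Nei neighbor joining; returns an unrooted newick string.

    Delegated to scikit-bio; negative branch lengths are clamped at 0.
    """
    if len(dm.sample_ids) < 3:
        raise ValidationError("need at least 3 samples for NJ")
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj

    tree = nj(SkbioDM(dm.values, ids=dm.sample_ids))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return str(tree).strip()


def classical_mds(dm: DistanceMatrix, k: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS on double-centered squared distances.

    Axes are ordered by eigenvalue; the sign convention makes the first
    nonzero loading of each axis positive.  Returns ``(n, k)`` coords.
    """
    if k <= 0:
        raise ValidationError("k must be positive")
    n = len(dm.sample_ids)
    if k >= n:
        raise ValidationError("k must be smaller than the number of samples")
    D2 = dm.values**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1][:k]
    coords = eigvec[:, order] * np.sqrt(np.maximum(eigval[order], 0.0))
    for j in range(k):
        col = coords[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if len(nz) and col[nz[0]] < 0:
            coords[:, j] = -col
    return coords


def silhouette_scores(
    dm: DistanceMatrix, labels: dict[str, str] | list[str], b_mode: str = "nearest"
) -> SilhouetteReport:
    """Per-sample silhouette scores s = (b - a) / max(a, b).

    ``b_mode="nearest"`` takes b(i) as the minimum over foreign groups of
    the mean distance to that group; ``"all-foreign-mean"`` averages over
    all foreign samples.  Groups of size 1 at input are an error; a
    sample whose score is undefined (max(a, b) == 0) gets s = nan.
    """
    ids = dm.sample_ids
    if isinstance(labels, dict):
        lab = [labels[s] for s in ids]
    else:
        lab = list(labels)
        if len(lab) != len(ids):
            raise ValidationError("labels length mismatch")
    if b_mode not in ("nearest", "all-foreign-mean"):
        raise ValidationError(f"unknown b_mode {b_mode!r}")
    groups: dict[str, list[int]] = {}
    for i, g in enumerate(lab):
        groups.setdefault(g, []).append(i)
    for g, members in groups.items():
        if len(members) < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 members")
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    n = len(ids)
    a = np.zeros(n)
    b = np.zeros(n)
    s = np.zeros(n)
    V = dm.values
    for i in range(n):
        own = [j for j in groups[lab[i]] if j != i]
        a[i] = float(np.mean(V[i, own]))
        foreign_means = [
            float(np.mean(V[i, members]))
            for g, members in groups.items()
            if g != lab[i]
        ]
        if b_mode == "nearest":
            b[i] = min(foreign_means)
        else:
            foreign_all = [j for j in range(n) if lab[j] != lab[i]]
            b[i] = float(np.mean(V[i, foreign_all]))
        denom = max(a[i], b[i])
        s[i] = (b[i] - a[i]) / denom if denom > 0 else np.nan
    return SilhouetteReport(sample_ids=list(ids), labels=lab, a=a, b=b, s=s)


def iterative_core_filter(
    dm: DistanceMatrix,
    labels: dict[str, str] | list[str],
    threshold: float = 0.1,
    b_mode: str = "nearest",
) -> CoreSet:
    """Iteratively remove poorly assigned samples until all scores exceed
    the threshold.

    Each iteration removes every sample with a negative score if any
    exist, otherwise every sample with score <= threshold; iteration
    stops when all remaining scores exceed the threshold, or when a
    removal would shrink a group below 2 members (then the run stops and
    is flagged).  Samples with undefined scores are retained.
    """
    if not -1.0 <= threshold < 1.0:
        raise ValidationError("threshold must be in [-1, 1)")
    ids = list(dm.sample_ids)
    if isinstance(labels, dict):
        label_of = dict(labels)
    else:
        label_of = dict(zip(ids, labels))
    current = list(ids)
    removed_per_iteration: list[list[str]] = []
    stopped = False
    iterations = 0
    while True:
        iterations += 1
        sub = dm.subset(current)
        report = silhouette_scores(sub, [label_of[s] for s in current], b_mode=b_mode)
        scores = dict(zip(report.sample_ids, report.s))
        defined = {s: v for s, v in scores.items() if np.isfinite(v)}
        negatives = [s for s, v in defined.items() if v < 0]
        low = [s for s, v in defined.items() if v <= threshold]
        to_remove = negatives if negatives else low
        if not to_remove:
            removed_per_iteration.append([])
            break
        # would any group fall below 2 members?
        survivors = [s for s in current if s not in set(to_remove)]
        sizes: dict[str, int] = {}
        for s in survivors:
            sizes[label_of[s]] = sizes.get(label_of[s], 0) + 1
        if any(v < 2 for v in sizes.values()) or len(sizes) < 2:
            stopped = True
            removed_per_iteration.append([])
            break
        removed_per_iteration.append(sorted(to_remove))
        current = survivors
    final = silhouette_scores(
        dm.subset(current), [label_of[s] for s in current], b_mode=b_mode
    )
    return CoreSet(
        retained=current,
        iterations_run=iterations,
        removed_per_iteration=removed_per_iteration,
        final_report=final,
        stopped_on_small_group=stopped,
    )
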