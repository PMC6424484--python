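import numpy as np
import pytest

import oracles
from conftest import make_matrix, random_matrix
from oryzagen import grouping
from oryzagen.datatypes import ValidationError


def dm_from(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"s{i}" for i in range(len(values))]
    return grouping.DistanceMatrix(ids, values)


def euclidean_dm(points, ids=None):
    points = np.asarray(points, dtype=float)
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    return dm_from(d, ids)


# ----------------------------------------------------------------------
# distances


def test_identical_genotypes_distance_zero():
    haps = np.tile(np.array([0, 1, 1, 0], dtype=np.int8), (4, 1))
    m = make_matrix(haps)
    dm = grouping.pairwise_distance(m)
    assert np.allclose(dm.values, 0.0)


def test_opposite_homozygotes_distance_one():
    a = np.zeros((1, 2, 6), dtype=np.int8)
    b = np.ones((1, 2, 6), dtype=np.int8)
    m = make_matrix(np.concatenate([a, b]), sample_ids=["a", "b"])
    dm = grouping.pairwise_distance(m)
    assert dm.values[0, 1] == pytest.approx(1.0)


def test_distance_matches_brute_force_with_missing_data():
    rng = np.random.default_rng(5)
    m = random_matrix(rng, 8, 50, missing_rate=0.2)
    dm = grouping.pairwise_distance(m)
    expected = oracles.ibs_distance(m.dosage())
    assert np.allclose(dm.values, expected, atol=1e-9)


def test_pair_with_no_shared_sites_is_an_error():
    g = np.zeros((2, 2, 2), dtype=np.int8)
    g[0, :, 0] = -1
    g[1, :, 1] = -1
    m = make_matrix(g, sample_ids=["a", "b"])
    with pytest.raises(ValidationError, match="a.*b"):
        grouping.pairwise_distance(m)


# ----------------------------------------------------------------------
# neighbor joining


def _tips_and_splits(newick):
    from io import StringIO

    from skbio import TreeNode

    tree = TreeNode.read(StringIO(newick))
    splits = set()
    for node in tree.non_tips():
        names = frozenset(t.name for t in node.tips())
        splits.add(names)
    return tree, splits


def test_nj_recovers_additive_four_taxon_topology():
    """Additive matrix for ((A,B),(C,D)); the AB|CD split satisfies the
    four-point condition and must be recovered."""
    #      A  B  C  D   (A-B cherry dist 2, internal branch 4)
    d = np.array(
        [
            [0, 2, 7, 7],
            [2, 0, 7, 7],
            [7, 7, 0, 2],
            [7, 7, 2, 0],
        ],
        dtype=float,
    )
    # four-point condition oracle: d(AB)+d(CD) < d(AC)+d(BD) = d(AD)+d(BC)
    assert d[0, 1] + d[2, 3] < d[0, 2] + d[1, 3] == d[0, 3] + d[1, 2]
    newick = grouping.neighbor_joining(dm_from(d, ["A", "B", "C", "D"]))
    _, splits = _tips_and_splits(newick)
    assert frozenset({"A", "B"}) in splits or frozenset({"C", "D"}) in splits


def test_nj_three_taxa_branch_lengths():
    d = np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]], dtype=float)
    newick = grouping.neighbor_joining(dm_from(d, ["A", "B", "C"]))
    tree, _ = _tips_and_splits(newick)
    for tip in tree.tips():
        assert tip.length == pytest.approx(1.0)


def test_nj_topology_invariant_under_input_order():
    rng = np.random.default_rng(8)
    pts = rng.normal(size=(6, 3))
    ids = ["a", "b", "c", "d", "e", "f"]
    dm = euclidean_dm(pts, ids)
    perm = [3, 1, 5, 0, 2, 4]
    dmp = dm_from(dm.values[np.ix_(perm, perm)], [ids[i] for i in perm])
    _, splits1 = _tips_and_splits(grouping.neighbor_joining(dm))
    _, splits2 = _tips_and_splits(grouping.neighbor_joining(dmp))
    # unrooted split sets must agree up to complementation
    tips = frozenset(ids)

    def canon(splits):
        return {min(s, tips - s, key=sorted) for s in splits if 1 < len(s) < 5}

    assert canon(splits1) == canon(splits2)


def test_nj_rejects_asymmetric_input():
    with pytest.raises(Exception):
        grouping.DistanceMatrix(["a", "b", "c"], np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0.0]]))


# ----------------------------------------------------------------------
# classical MDS


def test_mds_recovers_euclidean_configuration():
    rng = np.random.default_rng(0)
    pts = rng.normal(size=(7, 2))
    dm = euclidean_dm(pts)
    coords = grouping.classical_mds(dm, k=2)
    rec = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
    assert np.allclose(rec, dm.values, atol=1e-9)


def test_mds_regular_simplex_preserves_distances():
    n = 5
    d = np.ones((n, n)) - np.eye(n)
    coords = grouping.classical_mds(dm_from(d), k=n - 1)
    rec = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
    assert np.allclose(rec, d, atol=1e-9)


def test_mds_matches_eigendecomposition_oracle():
    rng = np.random.default_rng(3)
    pts = rng.normal(size=(8, 4))
    dm = euclidean_dm(pts)
    coords = grouping.classical_mds(dm, k=3)
    n = len(dm.sample_ids)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (dm.values**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:3]
    expected = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0))
    for j in range(3):
        col = expected[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if len(nz) and col[nz[0]] < 0:
            expected[:, j] = -col
    assert np.allclose(coords, expected, atol=1e-9)


def test_mds_rejects_bad_k():
    dm = dm_from(np.zeros((3, 3)))
    with pytest.raises(ValidationError):
        grouping.classical_mds(dm, k=0)
    with pytest.raises(ValidationError):
        grouping.classical_mds(dm, k=3)


# ----------------------------------------------------------------------
# silhouettes


def test_silhouette_zero_when_a_equals_b():
    # two groups of two, every distance equal
    d = np.ones((4, 4)) - np.eye(4)
    rep = grouping.silhouette_scores(dm_from(d), ["g1", "g1", "g2", "g2"])
    assert np.allclose(rep.s, 0.0)


def test_two_tight_clusters_closed_form():
    """Within-distance 1, between-distance 3: every s = (3-1)/3 = 2/3."""
    n = 6
    d = np.ones((n, n))
    d[:3, 3:] = 3.0
    d[3:, :3] = 3.0
    np.fill_diagonal(d, 0.0)
    rep = grouping.silhouette_scores(dm_from(d), ["a"] * 3 + ["b"] * 3)
    assert np.allclose(rep.s, 2.0 / 3.0)
    assert np.allclose(rep.a, 1.0)
    assert np.allclose(rep.b, 3.0)


def test_silhouette_matches_brute_force():
    rng = np.random.default_rng(12)
    pts = rng.normal(size=(12, 2))
    labels = ["g1"] * 4 + ["g2"] * 4 + ["g3"] * 4
    dm = euclidean_dm(pts)
    rep = grouping.silhouette_scores(dm, labels)
    expected = oracles.silhouettes(dm.values, labels)
    assert np.allclose(rep.s, expected, atol=1e-9)
    # Eq-style identity on every emitted row
    for a, b, s in zip(rep.a, rep.b, rep.s):
        assert s == pytest.approx((b - a) / max(a, b), abs=1e-12)
        assert -1.0 <= s <= 1.0


def test_singleton_group_is_an_error():
    d = np.ones((3, 3)) - np.eye(3)
    with pytest.raises(ValidationError):
        grouping.silhouette_scores(dm_from(d), ["a", "a", "b"])


# ----------------------------------------------------------------------
# iterative core filter


def planted_fixture():
    """3 clean clusters of 10 plus 4 samples midway between cluster pairs."""
    rng = np.random.default_rng(4)
    centers = np.array([[0.0, 0.0], [10.0, 0.0], [5.0, 8.66]])
    pts, labels, ids = [], [], []
    for c, center in enumerate(centers):
        for i in range(10):
            pts.append(center + rng.normal(scale=0.3, size=2))
            labels.append(f"g{c}")
            ids.append(f"g{c}-{i}")
    mid_pairs = [(0, 1), (1, 2), (0, 2), (0, 1)]
    for k, (a, b) in enumerate(mid_pairs):
        pts.append((centers[a] + centers[b]) / 2 + rng.normal(scale=0.05, size=2))
        labels.append(f"g{a}")
        ids.append(f"mid-{k}")
    return euclidean_dm(np.array(pts), ids), dict(zip(ids, labels))


def test_filter_fixed_point_when_all_scores_high():
    n = 6
    d = np.ones((n, n))
    d[:3, 3:] = 5.0
    d[3:, :3] = 5.0
    np.fill_diagonal(d, 0.0)
    core = grouping.iterative_core_filter(dm_from(d), ["a"] * 3 + ["b"] * 3, 0.1)
    assert core.retained == [f"s{i}" for i in range(6)]
    assert core.iterations_run == 1
    assert core.removed_per_iteration == [[]]


def test_filter_removes_exactly_the_planted_midway_samples():
    dm, labels = planted_fixture()
    core = grouping.iterative_core_filter(dm, labels, threshold=0.1)
    removed = set(dm.sample_ids) - set(core.retained)
    assert removed == {"mid-0", "mid-1", "mid-2", "mid-3"}
    assert all(np.isnan(v) or v > 0.1 for v in core.final_report.s)


def test_filter_monotone_in_threshold():
    dm, labels = planted_fixture()
    strict = grouping.iterative_core_filter(dm, labels, threshold=0.12)
    loose = grouping.iterative_core_filter(dm, labels, threshold=0.1)
    assert set(strict.retained) <= set(loose.retained)


def test_filter_terminates_within_n_iterations():
    rng = np.random.default_rng(7)
    pts = rng.normal(size=(14, 2))  # unstructured: heavy filtering
    labels = ["a"] * 7 + ["b"] * 7
    dm = euclidean_dm(pts)
    core = grouping.iterative_core_filter(dm, labels, threshold=0.1)
    assert core.iterations_run <= len(dm.sample_ids)
    for g in ("a", "b"):
        assert sum(1 for s in core.retained if labels[dm.sample_ids.index(s)] == g) >= 2


def test_mds_separates_synthetic_domesticate_groups(default_sim):
    """On the default synthetic fixture the mean within-group MDS
    distance is smaller than the mean between-group distance."""
    from oryzagen import popgen

    matrix, samples = default_sim["matrix"], default_sim["samples"]
    dom_ids = samples.ids_of_species("domesticate")
    thinned = popgen.thin_sites(popgen.filter_sites(matrix, 0.8, 0.02), seed=0)
    dm = grouping.pairwise_distance(thinned.take_samples(dom_ids))
    coords = grouping.classical_mds(dm, k=2)
    group = [samples.group_of()[s] for s in dm.sample_ids]
    d = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
    within, between = [], []
    n = len(group)
    for i in range(n):
        for j in range(i + 1, n):
            (within if group[i] == group[j] else between).append(d[i, j])
    assert np.mean(within) < np.mean(between)


def test_filter_threshold_validation():
    dm, labels = planted_fixture()
    with pytest.raises(ValidationError):
        grouping.iterative_core_filter(dm, labels, threshold=1.0)
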