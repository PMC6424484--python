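import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from conftest import make_matrix, random_matrix
from oryzagen import popgen
from oryzagen.datatypes import ValidationError
from oryzagen.simulate import SimConfig, simulate_dataset


# ----------------------------------------------------------------------
# site filters


def test_filter_drops_low_call_rate_site():
    g = np.zeros((10, 2, 1), dtype=np.int8)
    g[:3, :, 0] = -1  # 7/10 genotypes called
    g[3:5, 0, 0] = 1  # keep the site polymorphic
    m = make_matrix(g)
    out = popgen.filter_sites(m, min_call_rate=0.8, min_maf=0.0)
    assert out.n_sites == 0


def test_filter_drops_rare_allele():
    g = np.zeros((50, 2, 1), dtype=np.int8)
    g[0, 0, 0] = 1  # 1 alt of 100 alleles
    m = make_matrix(g)
    assert popgen.filter_sites(m, min_call_rate=0.8, min_maf=0.02).n_sites == 0
    assert popgen.filter_sites(m, min_call_rate=0.8, min_maf=0.01).n_sites == 1


def test_filter_matches_per_site_brute_force():
    rng = np.random.default_rng(0)
    m = random_matrix(rng, 12, 200, missing_rate=0.15)
    out = popgen.filter_sites(m, 0.8, 0.02)
    kept = []
    for j in range(m.n_sites):
        h = m.haplotypes()[:, j]
        called = h[h != -1]
        rate = len(called) / (2 * m.n_samples)
        if rate < 0.8 or len(called) == 0:
            continue
        p = (called == 1).mean()
        if min(p, 1 - p) >= 0.02:
            kept.append(m.pos[j])
    assert list(out.pos) == kept


def test_thin_sites_one_per_window_and_spacing():
    rng = np.random.default_rng(3)
    m = random_matrix(rng, 8, 120, pos_scale=2000)
    out = popgen.thin_sites(m, window_bp=50_000, min_spacing_bp=25_000, seed=5)
    assert np.all(np.diff(out.pos) >= 25_000)
    for start in range(1, int(m.pos.max()) + 1, 50_000):
        in_w = (out.pos >= start) & (out.pos < start + 50_000)
        assert in_w.sum() <= 1
    again = popgen.thin_sites(m, window_bp=50_000, min_spacing_bp=25_000, seed=5)
    assert list(out.pos) == list(again.pos)


def test_thin_sites_single_window():
    g = np.zeros((4, 2, 3), dtype=np.int8)
    g[0, :, :] = 1
    m = make_matrix(g, pos=[100, 200, 300])
    out = popgen.thin_sites(m, seed=0)
    assert out.n_sites == 1


# ----------------------------------------------------------------------
# window diversity


def test_two_haplotypes_pi_theta_and_undefined_d():
    """Two haplotypes differing at 1 of 10 sites: pi = theta = 0.1, D
    undefined (the variance term vanishes at n = 2)."""
    haps = np.zeros((2, 10), dtype=np.int8)
    haps[0, 4] = 1
    m = make_matrix(haps, pos=np.arange(1, 11))
    (w,) = popgen.window_diversity(m, window_bp=10_000, min_data_fraction=0.0)
    assert w.pi == pytest.approx(0.1)
    assert w.theta_w == pytest.approx(0.1)
    assert np.isnan(w.tajima_d)


def test_monomorphic_window_zero_diversity():
    haps = np.zeros((6, 8), dtype=np.int8)
    m = make_matrix(haps, pos=np.arange(1, 9))
    (w,) = popgen.window_diversity(m, window_bp=10_000, min_data_fraction=0.0)
    assert w.pi == 0.0 and w.theta_w == 0.0


def test_four_haplotypes_match_published_formulas():
    """n = 4, one site at derived count 2 over 10 accessible sites."""
    haps = np.zeros((4, 10), dtype=np.int8)
    haps[:2, 3] = 1
    m = make_matrix(haps, pos=np.arange(1, 11))
    (w,) = popgen.window_diversity(m, window_bp=10_000, min_data_fraction=0.0)
    pi_sum, theta_sum, d = oracles.tajima_stats(haps)
    assert w.pi == pytest.approx(pi_sum / 10, abs=1e-12)
    assert w.theta_w == pytest.approx(theta_sum / 10, abs=1e-12)
    assert w.tajima_d == pytest.approx(d, abs=1e-12)


def test_window_data_fraction_rule_omits_sparse_windows():
    g = np.zeros((10, 2, 4), dtype=np.int8)
    g[:8, :, 0] = -1  # site 1: call rate 0.2 -> inaccessible
    g[:8, :, 1] = -1
    g[:8, :, 2] = -1
    m = make_matrix(g, pos=[10, 20, 30, 40])
    assert popgen.window_diversity(m, 10_000, min_data_fraction=0.3) == []
    kept = popgen.window_diversity(m, 10_000, min_data_fraction=0.25)
    assert len(kept) == 1 and kept[0].n_sites_typed == 1


@settings(deadline=None, derandomize=True, max_examples=25)
@given(seed=st.integers(0, 10_000))
def test_pi_theta_invariant_under_reordering_and_allele_swap(seed):
    rng = np.random.default_rng(seed)
    haps = rng.integers(0, 2, size=(8, 12)).astype(np.int8)
    m = make_matrix(haps, pos=np.arange(1, 13))
    (w,) = popgen.window_diversity(m, 10_000, 0.0)
    perm = rng.permutation(4)
    m2 = make_matrix(haps.reshape(4, 2, 12)[perm], pos=np.arange(1, 13))
    (w2,) = popgen.window_diversity(m2, 10_000, 0.0)
    m3 = make_matrix(1 - haps, pos=np.arange(1, 13))
    (w3,) = popgen.window_diversity(m3, 10_000, 0.0)
    for other in (w2, w3):
        assert other.pi == pytest.approx(w.pi, abs=1e-12)
        assert other.theta_w == pytest.approx(w.theta_w, abs=1e-12)


# ----------------------------------------------------------------------
# Hudson Fst


def _counts(m):
    a, n = m.allele_counts()
    return list(zip(a.tolist(), n.tolist()))


def test_fixed_difference_gives_fst_one():
    ga = make_matrix(np.ones((8, 5), dtype=np.int8), pos=np.arange(1, 6))
    gb = make_matrix(np.zeros((8, 5), dtype=np.int8), pos=np.arange(1, 6))
    (w,) = popgen.hudson_fst(ga, gb, window_bp=10_000)
    assert w.fst == pytest.approx(1.0)


def test_self_comparison_equals_analytic_correction():
    """Comparing a sample set against itself gives exactly -1/(n-1):
    the unbiasedness correction, not 0, is the estimator's fixed point."""
    rng = np.random.default_rng(2)
    m = random_matrix(rng, 6, 40)
    windows = popgen.hudson_fst(m, m, window_bp=10**9)
    n = 12  # haplotypes
    assert windows[0].fst == pytest.approx(-1.0 / (n - 1), abs=1e-12)


def test_hudson_fst_matches_brute_force():
    rng = np.random.default_rng(4)
    for _ in range(20):
        ga = random_matrix(rng, 6, 50, missing_rate=0.1)
        gb = make_matrix(
            rng.integers(0, 2, size=(5, 2, 50)).astype(np.int8), pos=ga.pos
        )
        (w,) = popgen.hudson_fst(ga, gb, window_bp=10**9)
        expected = oracles.hudson_fst(_counts(ga), _counts(gb))
        assert w.fst == pytest.approx(expected, abs=1e-9)


def test_fst_vanishes_as_divergence_vanishes():
    """Groups drawn from a common founder pool show near-zero mean Fst;
    between-region Fst grows monotonically with the divergence knob."""
    def dataset(mu_region):
        cfg = SimConfig(
            n_wild_per_region=12, n_dom_per_group=2, n_feral=1,
            n_sites_per_chrom=600, chrom_length=300_000, n_focal_sites=40,
            mu_region=mu_region, mu_founder=5.0, rng_seed=11, loci=[],
        )
        return simulate_dataset(cfg)

    matrix, samples, _ = dataset(10.0)
    pool = samples.ids_in_group("WILD0")
    ga = matrix.take_samples(pool[:6])
    gb = matrix.take_samples(pool[6:])
    common = popgen.mean_fst(popgen.hudson_fst(ga, gb, 10_000))
    assert abs(common) < 0.05

    def between(mu_region):
        m, s, _ = dataset(mu_region)
        return popgen.mean_fst(
            popgen.hudson_fst(
                m.take_samples(s.ids_in_group("WILD0")),
                m.take_samples(s.ids_in_group("WILD1")),
                10_000,
            )
        )

    mid, high = between(10.0), between(40.0)
    assert common < mid < high


# ----------------------------------------------------------------------
# sweep scan


def _stats_from_pi(pis, chrom="chr1"):
    return [
        popgen.WindowStat(chrom, 1 + i * 10_000, 1 + (i + 1) * 10_000, 5, 1.0, pi, pi, 0.0)
        for i, pi in enumerate(pis)
    ]


def test_single_outlier_window_flagged():
    wild = _stats_from_pi([1.0] * 100)
    dom_pi = [0.5] * 100
    dom_pi[42] = 0.02  # ratio 50, rest = 2
    dom = _stats_from_pi(dom_pi)
    scan = popgen.sweep_scan(wild, dom)
    flagged = [w for w in scan if w.top1pct_flag]
    assert len(flagged) == 1 and flagged[0].start == 1 + 42 * 10_000


def test_degenerate_ratio_distribution_flags_nothing():
    wild = _stats_from_pi([0.3] * 50)
    scan = popgen.sweep_scan(wild, _stats_from_pi([0.3] * 50))
    assert not any(w.top1pct_flag for w in scan)


def test_infinite_ratio_always_flagged():
    wild = _stats_from_pi([0.3] * 50)
    dom_pi = [0.3] * 50
    dom_pi[7] = 0.0
    scan = popgen.sweep_scan(wild, _stats_from_pi(dom_pi))
    assert [w.top1pct_flag for w in scan] == [i == 7 for i in range(50)]


def test_no_shared_windows_is_an_error():
    with pytest.raises(ValidationError):
        popgen.sweep_scan(_stats_from_pi([1.0], chrom="chr1"), _stats_from_pi([1.0], chrom="chr2"))


# ----------------------------------------------------------------------
# LD decay


def test_identical_dosage_vectors_have_r2_one():
    haps = np.array([[0, 0], [0, 0], [1, 1], [1, 1], [0, 0], [1, 1]], dtype=np.int8)
    m = make_matrix(haps, pos=[100, 1600])
    (b,) = popgen.ld_decay(m, bin_bp=1000)
    assert b.mean_r2 == pytest.approx(1.0)
    assert b.distance_bin_start == 1000  # distance 1500 -> second bin


def test_orthogonal_dosage_vectors_have_r2_zero():
    # dosages site1: 2,2,0,0 ; site2: 2,0,2,0 -> correlation 0
    haps = np.array(
        [[1, 1], [1, 1], [1, 0], [1, 0], [0, 1], [0, 1], [0, 0], [0, 0]], dtype=np.int8
    )
    m = make_matrix(haps, pos=[100, 900])
    (b,) = popgen.ld_decay(m, bin_bp=1000)
    assert b.mean_r2 == pytest.approx(0.0, abs=1e-12)


def test_ld_bins_match_all_pairs_brute_force():
    rng = np.random.default_rng(9)
    m = random_matrix(rng, 10, 20, missing_rate=0.1, pos_scale=400)
    bins = popgen.ld_decay(m, region_window_bp=10**9, bin_bp=1000)
    expected = oracles.ld_bins(m.dosage(), m.pos, 1000)
    got = {b.distance_bin_start // 1000: (b.mean_r2, b.n_pairs) for b in bins}
    assert set(got) == set(expected)
    for k in expected:
        assert got[k][1] == expected[k][1]
        assert got[k][0] == pytest.approx(expected[k][0], abs=1e-9)


# ----------------------------------------------------------------------
# f4


def test_f4_zero_when_first_pair_identical():
    rng = np.random.default_rng(1)
    ga = random_matrix(rng, 5, 300)
    gc = make_matrix(rng.integers(0, 2, (5, 2, 300)).astype(np.int8), pos=ga.pos)
    gd = make_matrix(rng.integers(0, 2, (5, 2, 300)).astype(np.int8), pos=ga.pos)
    res = popgen.f4_test(ga, ga, gc, gd, block_size=100)
    assert res.f4_value == 0.0


def test_f4_antisymmetric_in_first_pair():
    rng = np.random.default_rng(2)
    mats = [random_matrix(rng, 5, 300) for _ in range(4)]
    for m in mats[1:]:
        m.pos = mats[0].pos
        m.chrom = mats[0].chrom
    a = popgen.f4_test(mats[0], mats[1], mats[2], mats[3], 100)
    b = popgen.f4_test(mats[1], mats[0], mats[2], mats[3], 100)
    assert a.f4_value == pytest.approx(-b.f4_value, abs=1e-15)
    assert a.jackknife_se == pytest.approx(b.jackknife_se, abs=1e-15)


def test_f4_and_jackknife_match_explicit_loop():
    rng = np.random.default_rng(3)
    mats = [random_matrix(rng, 6, 500) for _ in range(4)]
    for m in mats[1:]:
        m.pos = mats[0].pos
        m.chrom = mats[0].chrom
    res = popgen.f4_test(*mats, block_size=100)
    freqs = []
    for m in mats:
        a, n = m.allele_counts()
        freqs.append(a / n)
    f4, se = oracles.f4_jackknife(freqs, 100)
    assert res.f4_value == pytest.approx(f4, abs=1e-12)
    assert res.jackknife_se == pytest.approx(se, abs=1e-12)
    assert res.n_blocks == 5


def test_f4_errors_on_monomorphic_input():
    z = make_matrix(np.zeros((4, 2, 200), dtype=np.int8))
    with pytest.raises(ValidationError):
        popgen.f4_test(z, z, z, z, 100)
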