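import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from conftest import make_matrix
from oryzagen import haplonet as hn
from oryzagen.datatypes import ValidationError


def hapset(strings, carriers=None, status=None):
    haps = np.array([[int(c) for c in s] for s in strings], dtype=np.int8)
    carriers = carriers or [(f"s{i}", 0) for i in range(len(strings))]
    return hn.HaplotypeSet(
        chrom="chr1", start=1, end=1000,
        positions=np.arange(1, haps.shape[1] + 1) * 10,
        haplotypes=haps, carriers=carriers,
        causal_status=status or [],
    )


# ----------------------------------------------------------------------
# four-gamete test


def test_balanced_four_gametes_detected():
    col_i = np.array([0] * 50 + [1] * 50)
    col_j = np.array([0] * 25 + [1] * 25 + [0] * 25 + [1] * 25)
    assert hn.four_gamete_pair(col_i, col_j, 0.01) is True


def test_three_gametes_not_recombination():
    col_i = np.array([0, 0, 1, 1, 0, 1])
    col_j = np.array([0, 1, 0, 0, 1, 0])  # gametes {00, 01, 10}
    assert hn.four_gamete_pair(col_i, col_j, 0.01) is False


def test_rare_fourth_gamete_treated_as_error():
    """A fourth gamete at 0.5% frequency is below the 1% tolerance."""
    col_i = np.array([0] * 150 + [1] * 50)
    col_j = np.array([0] * 100 + [1] * 50 + [0] * 49 + [1] * 1)
    freq = 1 / 200
    assert freq < 0.01
    assert hn.four_gamete_pair(col_i, col_j, error_freq=0.01) is False
    assert hn.four_gamete_pair(col_i, col_j, error_freq=0.005) is True


def test_missing_entries_dropped_pairwise():
    col_i = np.array([0, 0, 1, 1, -1])
    col_j = np.array([0, 1, 0, -1, 1])
    assert hn.four_gamete_pair(col_i, col_j, 0.01) is False  # 11 never co-observed


# ----------------------------------------------------------------------
# non-recombining scan


def test_clean_region_passes_through_unchanged():
    h = hapset(["000", "001", "011", "111"], status=["ancestral"] * 4)
    out, report = hn.nonrecombining_scan(h, [0, 1], [2, 3], 0.01)
    assert report.status == "clean"
    assert np.array_equal(out.haplotypes, h.haplotypes)


def test_wild_only_recombinant_carriers_removed():
    """A fourth-gamete pair confined to the wild partition removes the
    haplotypes carrying the minority gamete; the rest stay intact."""
    wild = ["00"] * 2 + ["01"] * 4 + ["10"] * 4 + ["11"] * 4
    dom = ["11", "11", "01"]
    h = hapset(wild + dom)
    wild_rows = list(range(len(wild)))
    dom_rows = list(range(len(wild), len(wild) + len(dom)))
    # oracle: exhaustive pair scan of the wild partition
    wild_haps = h.haplotypes[wild_rows]
    failing = [
        (i, j)
        for i in range(2)
        for j in range(i + 1, 2)
        if hn.four_gamete_pair(wild_haps[:, i], wild_haps[:, j], 0.01)
    ]
    assert failing == [(0, 1)]  # exactly one failing pair
    out, report = hn.nonrecombining_scan(h, wild_rows, dom_rows, 0.01)
    assert report.status == "cleaned"
    # the minority gamete '00' has exactly 2 carriers: s0 and s1
    removed_ids = {sid for sid, _ in report.removed}
    assert removed_ids == {"s0", "s1"}
    assert out.n_haplotypes == len(wild) + len(dom) - 2


def test_domesticate_recombination_rejects_region():
    dom = ["00", "01", "10", "11", "11", "00", "01", "10"]
    wild = ["00", "00"]
    h = hapset(wild + dom)
    out, report = hn.nonrecombining_scan(h, [0, 1], list(range(2, 10)), 0.01)
    assert report.status == "rejected"
    assert np.array_equal(out.haplotypes, h.haplotypes)


def test_scan_output_is_idempotent():
    rng = np.random.default_rng(0)
    strings = ["".join(map(str, rng.integers(0, 2, 6))) for _ in range(20)]
    h = hapset(strings)
    wild_rows = list(range(12))
    dom = ["000000", "000111", "000111"] * 3
    h2 = hapset(strings[:12] + dom)
    dom_rows = list(range(12, 21))
    out, report = hn.nonrecombining_scan(h2, wild_rows, dom_rows, 0.01)
    if report.status == "rejected":
        pytest.skip("random fixture recombined in domesticates")
    kept_wild = [i for i, c in enumerate(out.carriers) if c in [h2.carriers[r] for r in wild_rows]]
    kept_dom = [i for i in range(out.n_haplotypes) if i not in kept_wild]
    out2, report2 = hn.nonrecombining_scan(out, kept_wild, kept_dom, 0.01)
    assert report2.status == "clean"
    assert np.array_equal(out2.haplotypes, out.haplotypes)


# ----------------------------------------------------------------------
# collapsing and MST


def test_collapse_merges_identical_strings():
    h = hapset(["0101"] * 4, status=["ancestral"] * 4)
    nodes = hn.collapse_haplotypes(h)
    assert len(nodes) == 1
    assert nodes[0].count == 4
    assert nodes[0].label == "I"


def test_collapse_all_distinct():
    h = hapset(["000", "001", "010", "100"])
    nodes = hn.collapse_haplotypes(h)
    assert [n.count for n in nodes] == [1, 1, 1, 1]
    assert [n.label for n in nodes] == ["I", "II", "III", "IV"]


def test_collapse_counts_match_direct_tally():
    rng = np.random.default_rng(2)
    strings = ["".join(map(str, rng.integers(0, 2, 4))) for _ in range(30)]
    h = hapset(strings)
    nodes = hn.collapse_haplotypes(h)
    tally: dict[str, int] = {}
    for s in strings:
        tally[s] = tally.get(s, 0) + 1
    assert {n.string: n.count for n in nodes} == tally
    counts = [n.count for n in nodes]
    assert counts == sorted(counts, reverse=True)


def test_collapse_separates_causal_status():
    """Identical strings with different causal status stay separate nodes
    (a shared haplotype splits into carrier/non-carrier subgroups)."""
    h = hapset(["01", "01", "01"], status=["derived", "derived", "ancestral"])
    nodes = hn.collapse_haplotypes(h)
    assert len(nodes) == 2
    assert {(n.causal_status, n.count) for n in nodes} == {("derived", 2), ("ancestral", 1)}


def test_mst_simple_chain():
    nodes = hn.collapse_haplotypes(hapset(["000", "001", "011"]))
    net = hn.hamming_mst(nodes)
    weights = sorted(w for _, _, w in net.edges)
    assert weights == [1, 1]
    assert sum(weights) == 2


def test_mst_single_node():
    net = hn.hamming_mst(hn.collapse_haplotypes(hapset(["0101"])))
    assert net.edges == []


def test_mst_weight_matches_exhaustive_enumeration():
    """Six random length-8 strings: MST total weight equals the minimum
    over all 6^4 labeled spanning trees (Prüfer enumeration)."""
    rng = np.random.default_rng(5)
    for _ in range(5):
        strings = list({"".join(map(str, rng.integers(0, 2, 8))) for _ in range(10)})[:6]
        nodes = hn.collapse_haplotypes(hapset(strings))
        net = hn.hamming_mst(nodes)
        total = sum(w for _, _, w in net.edges)
        assert total == oracles.mst_weight_exhaustive([n.string for n in nodes])


@settings(deadline=None, derandomize=True, max_examples=20)
@given(seed=st.integers(0, 10_000))
def test_mst_agrees_with_networkx_and_edge_weights_check_out(seed):
    rng = np.random.default_rng(seed)
    strings = list({"".join(map(str, rng.integers(0, 2, 6))) for _ in range(8)})
    nodes = hn.collapse_haplotypes(hapset(strings))
    net = hn.hamming_mst(nodes)
    G = nx.Graph()
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            G.add_edge(a.label, b.label, weight=sum(x != y for x, y in zip(a.string, b.string)))
    if len(nodes) > 1:
        ref = nx.minimum_spanning_tree(G)
        assert sum(w for _, _, w in net.edges) == sum(
            d["weight"] for _, _, d in ref.edges(data=True)
        )
    by_label = net.node_by_label()
    for a, b, w in net.edges:
        assert w == sum(x != y for x, y in zip(by_label[a].string, by_label[b].string))


def test_extraction_requires_phase_and_drops_missing():
    g = np.array(
        [
            [[0, 1, 0], [1, 1, 0]],
            [[0, -1, 1], [0, 0, 1]],
        ],
        dtype=np.int8,
    )
    m = make_matrix(g, pos=[10, 20, 30], sample_ids=["a", "b"])
    h = hn.extract_haplotypes(m, "chr1", 1, 100)
    assert h.n_excluded_missing == 1
    assert h.n_haplotypes == 3
    m_unphased = make_matrix(g, pos=[10, 20, 30], phased=False)
    with pytest.raises(ValidationError):
        hn.extract_haplotypes(m_unphased, "chr1", 1, 100)


def test_roman_labels():
    assert [hn.roman(i) for i in (1, 4, 9, 14)] == ["I", "IV", "IX", "XIV"]
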