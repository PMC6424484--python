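"""Four-gamete screening and hamming-distance haplotype networks.

A region qualifies for network construction only if it shows no evidence
of recombination.  Every pair of biallelic sites is checked with the
four-gamete test; a fourth gamete observed below the error-frequency
tolerance (default 1%) is treated as genotyping error, not
recombination.  Recombination inside the domesticate partition rejects
the region outright (the caller must shrink it); recombination confined
to the wild partition removes the wild haplotypes carrying the fourth
gamete, since they carry no information about the domesticate
haplotype's origin.

Cleaned haplotypes are collapsed into nodes — identical allele strings
with identical causal status (mirroring the split of a shared haplotype
into carrier and non-carrier subgroups) — and connected by a minimum
spanning tree under hamming distance.  MSTs are not unique; ties among
equal-weight edges are broken toward the lexicographically smallest node
label pair so outputs are reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeMatrix, ValidationError


def roman(n: int) -> str:
    """1 -> I, 2 -> II, ... (labels for haplotype nodes)."""
    numerals = [
        (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"), (90, "XC"),
        (50, "L"), (40, "XL"), (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
    ]
    out = []
    for value, sym in numerals:
        while n >= value:
            out.append(sym)
            n -= value
    return "".join(out)


@dataclass
class HaplotypeSet:
    """Phased haplotypes over a region's polymorphic sites."""

    chrom: str
    start: int
    end: int
    positions: np.ndarray  # site positions, length L
    haplotypes: np.ndarray  # (H, L) in {0, 1}
    carriers: list[tuple[str, int]]  # (sample_id, haplotype index) per row
    causal_status: list[str] = field(default_factory=list)  # derived/ancestral/unknown
    n_excluded_missing: int = 0

    def __post_init__(self) -> None:
        if not self.causal_status:
            self.causal_status = ["unknown"] * len(self.carriers)
        if len(self.carriers) != self.haplotypes.shape[0]:
            raise ValidationError("carriers do not partition the haplotypes")
        if len(self.causal_status) != len(self.carriers):
            raise ValidationError("causal_status length mismatch")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    def strings(self) -> list[str]:
        return ["".join(map(str, row)) for row in self.haplotypes]

    def take(self, rows) -> "HaplotypeSet":
        rows = list(rows)
        return replace(
            self,
            haplotypes=self.haplotypes[rows],
            carriers=[self.carriers[i] for i in rows],
            causal_status=[self.causal_status[i] for i in rows],
        )


def extract_haplotypes(g: GenotypeMatrix, chrom: str, start: int, end: int) -> HaplotypeSet:
    """Polymorphic sites of ``[start, end)`` as phased haplotype strings.

    Requires phased input.  Haplotypes with any missing allele in the
    region are excluded (count recorded); sites monomorphic among the
    remaining haplotypes are dropped.
    """
    if not g.phased:
        raise ValidationError("haplotype extraction requires phased genotypes")
    in_region = np.flatnonzero((g.chrom == chrom) & (g.pos >= start) & (g.pos < end))
    if len(in_region) == 0:
        raise ValidationError(f"no sites in {chrom}:{start}-{end}")
    haps = g.haplotypes()[:, in_region]
    carriers = [(sid, h) for sid in g.sample_ids for h in (0, 1)]
    complete = ~np.any(haps == MISSING, axis=1)
    kept = haps[complete]
    carriers = [c for c, ok in zip(carriers, complete) if ok]
    poly = np.flatnonzero((kept.min(axis=0) == 0) & (kept.max(axis=0) == 1)) if len(kept) else np.array([], int)
    return HaplotypeSet(
        chrom=chrom, start=start, end=end,
        positions=g.pos[in_region][poly],
        haplotypes=kept[:, poly].astype(np.int8),
        carriers=carriers,
        n_excluded_missing=int((~complete).sum()),
    )


def set_causal_from_allele(h: HaplotypeSet, g: GenotypeMatrix, chrom: str, pos: int) -> HaplotypeSet:
    """Causal status per haplotype from the allele at a causal SNP site."""
    site = np.flatnonzero((g.chrom == chrom) & (g.pos == pos))
    if len(site) != 1:
        raise ValidationError(f"causal site {chrom}:{pos} not found")
    alleles = g.haplotypes()[:, site[0]]
    row_of = {(sid, hap): i for i, (sid, hap) in enumerate(
        [(s, k) for s in g.sample_ids for k in (0, 1)]
    )}
    status = []
    for sid, hap in h.carriers:
        a = alleles[row_of[(sid, hap)]]
        status.append("unknown" if a == MISSING else ("derived" if a == 1 else "ancestral"))
    return replace(h, causal_status=status)


def set_causal_from_sample_status(
    h: HaplotypeSet,
    derived_samples: set[str],
    unknown_samples: set[str] = frozenset(),
) -> HaplotypeSet:
    """Causal status from per-sample carrier status (e.g. deletion calls)."""
    status = [
        "derived" if sid in derived_samples
        else ("unknown" if sid in unknown_samples else "ancestral")
        for sid, _ in h.carriers
    ]
    return replace(h, causal_status=status)


# ----------------------------------------------------------------------
# four-gamete test


def four_gamete_pair(col_i: np.ndarray, col_j: np.ndarray, error_freq: float = 0.01) -> bool:
    """True iff the pair shows all four gametes with the rarest at or
    above the error-frequency tolerance."""
    col_i = np.asarray(col_i)
    col_j = np.asarray(col_j)
    if col_i.shape != col_j.shape:
        raise ValidationError("columns must have the same length")
    ok = (col_i != MISSING) & (col_j != MISSING)
    ci, cj = col_i[ok], col_j[ok]
    if len(ci) == 0:
        return False
    code = 2 * ci.astype(int) + cj.astype(int)
    counts = np.bincount(code, minlength=4)
    if np.count_nonzero(counts) < 4:
        return False
    return bool(counts.min() / len(ci) >= error_freq)


def _fourth_gamete(ci: np.ndarray, cj: np.ndarray) -> tuple[int, int]:
    """Minority gamete at a failing pair.

    Ties are broken by preferring the gamete containing the rarer allele
    at site i, then at site j.
    """
    code = 2 * ci.astype(int) + cj.astype(int)
    counts = np.bincount(code, minlength=4)
    min_count = counts[counts > 0].min()
    candidates = [g for g in range(4) if counts[g] == min_count]
    if len(candidates) > 1:
        rare_i = 1 if (ci == 1).sum() < (ci == 0).sum() else 0
        with_rare_i = [g for g in candidates if g >> 1 == rare_i]
        if with_rare_i:
            candidates = with_rare_i
    if len(candidates) > 1:
        rare_j = 1 if (cj == 1).sum() < (cj == 0).sum() else 0
        with_rare_j = [g for g in candidates if g & 1 == rare_j]
        if with_rare_j:
            candidates = with_rare_j
    gamete = candidates[0]
    return gamete >> 1, gamete & 1


@dataclass
class ScanReport:
    status: str  # "clean" | "cleaned" | "rejected"
    removed: list[tuple[str, int]]
    failing_pairs: list[tuple[int, int, str]]  # (pos_i, pos_j, partition)


def _partition_failures(haps: np.ndarray, positions: np.ndarray, error_freq: float):
    L = haps.shape[1]
    for i, j in itertools.combinations(range(L), 2):
        if four_gamete_pair(haps[:, i], haps[:, j], error_freq):
            yield i, j


def nonrecombining_scan(
    h: HaplotypeSet,
    wild_rows: list[int],
    dom_rows: list[int],
    error_freq: float = 0.01,
) -> tuple[HaplotypeSet, ScanReport]:
    """Screen a region for recombination; clean or reject it.

    All site pairs are tested within the wild and domesticate partitions
    separately.  Any failure inside the domesticate partition rejects
    the region.  Failures confined to the wild partition remove the wild
    haplotypes carrying the minority (fourth) gamete, iterating until
    the region is clean; the output passes a full re-scan in both
    partitions.
    """
    if not wild_rows or not dom_rows:
        raise ValidationError("both partitions must be non-empty")
    dom = h.take(dom_rows)
    if any(True for _ in _partition_failures(dom.haplotypes, dom.positions, error_freq)):
        return h, ScanReport(status="rejected", removed=[], failing_pairs=[
            (int(h.positions[i]), int(h.positions[j]), "domesticate")
            for i, j in _partition_failures(dom.haplotypes, dom.positions, error_freq)
        ])
    removed: list[tuple[str, int]] = []
    failing: list[tuple[int, int, str]] = []
    wild_set = set(wild_rows)
    current = h
    current_wild = sorted(wild_set)
    while True:
        wild = current.take(current_wild)
        fails = list(_partition_failures(wild.haplotypes, wild.positions, error_freq))
        if not fails:
            break
        drop_local = set()
        for i, j in fails:
            failing.append((int(current.positions[i]), int(current.positions[j]), "wild"))
            gi, gj = _fourth_gamete(wild.haplotypes[:, i], wild.haplotypes[:, j])
            hit = np.flatnonzero(
                (wild.haplotypes[:, i] == gi) & (wild.haplotypes[:, j] == gj)
            )
            drop_local.update(int(k) for k in hit)
        removed.extend(wild.carriers[k] for k in sorted(drop_local))
        drop_global = {current_wild[k] for k in drop_local}
        keep = [r for r in range(current.n_haplotypes) if r not in drop_global]
        # re-index the wild partition after removal
        old_wild = [r for r in current_wild if r not in drop_global]
        index_map = {old: new for new, old in enumerate(keep)}
        current = current.take(keep)
        current_wild = [index_map[r] for r in old_wild]
    status = "cleaned" if removed else "clean"
    return current, ScanReport(status=status, removed=removed, failing_pairs=failing)


# ----------------------------------------------------------------------
# network construction


@dataclass
class HaploNode:
    label: str
    string: str
    count: int
    members: list[tuple[str, int]]
    causal_status: str


@dataclass
class HaploNetwork:
    nodes: list[HaploNode]
    edges: list[tuple[str, str, int]]  # (label_i, label_j, hamming weight)

    def node_by_label(self) -> dict[str, HaploNode]:
        return {n.label: n for n in self.nodes}

    def graph(self) -> nx.Graph:
        G = nx.Graph()
        for n in self.nodes:
            G.add_node(n.label, count=n.count, causal_status=n.causal_status,
                       haplotype=n.string)
        for a, b, w in self.edges:
            G.add_edge(a, b, weight=w)
        return G

    def node_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (
                    n.label,
                    n.string,
                    n.count,
                    ";".join(f"{sid}.{hap}" for sid, hap in n.members),
                    n.causal_status,
                )
                for n in self.nodes
            ],
            columns=["label", "haplotype", "count", "members", "causal_status"],
        )

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph(), path)


def collapse_haplotypes(h: HaplotypeSet) -> list[HaploNode]:
    """Merge identical haplotypes (same allele string and causal status)
    into nodes, labelled by descending count then first occurrence."""
    strings = h.strings()
    order: dict[tuple[str, str], int] = {}
    members: dict[tuple[str, str], list[tuple[str, int]]] = {}
    for row, (string, status) in enumerate(zip(strings, h.causal_status)):
        key = (string, status)
        if key not in order:
            order[key] = row
        members.setdefault(key, []).append(h.carriers[row])
    keys = sorted(order, key=lambda k: (-len(members[k]), order[k]))
    return [
        HaploNode(
            label=roman(i + 1),
            string=key[0],
            count=len(members[key]),
            members=members[key],
            causal_status=key[1],
        )
        for i, key in enumerate(keys)
    ]


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def hamming_mst(nodes: list[HaploNode]) -> HaploNetwork:
    """Minimum spanning tree of the complete hamming graph over nodes.

    Kruskal with edges ordered by (weight, smaller node index, larger
    node index) in label order, giving a deterministic tree of minimal
    total weight.
    """
    if not nodes:
        raise ValidationError("need at least 1 node")
    n = len(nodes)
    edges = sorted(
        (
            (_hamming(nodes[i].string, nodes[j].string), i, j)
            for i in range(n)
            for j in range(i + 1, n)
        ),
    )
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    chosen: list[tuple[str, str, int]] = []
    for w, i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            chosen.append((nodes[i].label, nodes[j].label, int(w)))
            if len(chosen) == n - 1:
                break
    return HaploNetwork(nodes=nodes, edges=chosen)
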