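"""Geographic origin inference for causal domestication mutations.

The logic: a causal mutation arose once, on one ancestral haplotype, in
one place.  The derived haplotype closest (in mutational steps on the
haplotype network) to an ancestral haplotype is the putative founding
haplotype, and the geographic overlap between the founding derived
haplotype's range and its nearest ancestral haplotype's range marks the
likely region of origin.  Later derived haplotypes record range
expansion, not origin.

The overlap score per region is min(freq_ancestral, freq_derived)
(rewarding joint presence without letting one abundant haplotype
dominate); ``score_mode="product"`` multiplies the frequencies instead.
Sample sizes per haplotype are carried through so small-n caveats stay
visible; no confidence level is asserted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import SampleTable, ValidationError
from .haplonet import HaploNetwork, HaploNode

UNKNOWN_REGION = "unknown"


@dataclass
class GeoDistribution:
    label: str
    counts: dict[str, int]  # region/country -> carrier haplotype count
    frequency: dict[str, float]  # carriers / region total sampled
    coordinates: list[tuple[float, float]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    def regions(self) -> set[str]:
        return {r for r, c in self.counts.items() if c > 0 and r != UNKNOWN_REGION}


@dataclass
class OriginInference:
    locus_id: str
    derived_labels: list[str]
    ancestral_labels: list[str]
    founding_label: str
    scores: dict[str, float]
    top_regions: list[str]
    status: str  # "ok" | "disjoint — origin indeterminate"
    n_derived: int
    n_ancestral: int


def haplotype_geography(
    net: HaploNetwork,
    samples: SampleTable,
    region_totals: dict[str, int] | None = None,
) -> list[GeoDistribution]:
    """Per-node carrier counts and frequencies by region (country).

    Samples without geography are tallied under ``"unknown"`` and
    excluded from frequencies.  ``region_totals`` gives the number of
    sampled haplotypes per region used as the frequency denominator; by
    default it is derived from the network's own members.
    """
    country_of = samples.country_of()
    coords = {
        row["sample_id"]: (row["lat"], row["lon"])
        for _, row in samples.df.iterrows()
        if pd.notna(row["lat"]) and pd.notna(row["lon"])
    }
    if region_totals is None:
        region_totals = {}
        for node in net.nodes:
            for sid, _hap in node.members:
                region = country_of.get(sid) or UNKNOWN_REGION
                if pd.isna(region):
                    region = UNKNOWN_REGION
                region_totals[region] = region_totals.get(region, 0) + 1
    out = []
    for node in net.nodes:
        counts: dict[str, int] = {}
        node_coords = []
        for sid, _hap in node.members:
            region = country_of.get(sid) or UNKNOWN_REGION
            if pd.isna(region):
                region = UNKNOWN_REGION
            counts[region] = counts.get(region, 0) + 1
            if sid in coords:
                node_coords.append(coords[sid])
        frequency = {
            r: counts[r] / region_totals[r]
            for r in counts
            if r != UNKNOWN_REGION and region_totals.get(r, 0) > 0
        }
        out.append(
            GeoDistribution(
                label=node.label, counts=counts, frequency=frequency,
                coordinates=node_coords,
            )
        )
    return out


def nearest_ancestral(net: HaploNetwork) -> tuple[list[tuple[str, str, float]], str]:
    """Pair every derived node with its nearest ancestral node.

    Distances are path weights along the network's spanning tree.  Ties
    produce multiple pairs.  Returns the pair list and the label of the
    putative founding haplotype — the derived node at globally minimal
    distance to any ancestral node (earliest derived haplotype).
    """
    derived = [n.label for n in net.nodes if n.causal_status == "derived"]
    ancestral = [n.label for n in net.nodes if n.causal_status == "ancestral"]
    if not ancestral:
        raise ValidationError("no ancestral nodes: origin cannot be polarized")
    if not derived:
        raise ValidationError("no derived nodes in network")
    G = net.graph()
    pairs: list[tuple[str, str, float]] = []
    best_per_derived: dict[str, float] = {}
    for d in derived:
        lengths = {
            a: nx.shortest_path_length(G, d, a, weight="weight") for a in ancestral
        }
        dmin = min(lengths.values())
        best_per_derived[d] = dmin
        for a, dist in sorted(lengths.items()):
            if dist == dmin:
                pairs.append((d, a, float(dist)))
    founding = min(derived, key=lambda d: (best_per_derived[d], d))
    return pairs, founding


def infer_origin(
    anc: GeoDistribution,
    der: GeoDistribution,
    locus_id: str = "",
    score_mode: str = "min",
) -> OriginInference:
    """Score each region by the overlap of ancestral and derived ranges.

    score(r) = min(freq_anc(r), freq_der(r)) (or their product); the top
    region(s) are the argmax.  Zero overlap everywhere yields the
    explicit status "disjoint — origin indeterminate".
    """
    if not anc.counts or not der.counts:
        raise ValidationError("both geographic distributions must be non-empty")
    if score_mode not in ("min", "product"):
        raise ValidationError(f"unknown score_mode {score_mode!r}")
    regions = sorted(set(anc.frequency) | set(der.frequency))
    scores = {}
    for r in regions:
        fa = anc.frequency.get(r, 0.0)
        fd = der.frequency.get(r, 0.0)
        scores[r] = min(fa, fd) if score_mode == "min" else fa * fd
    positive = {r: v for r, v in scores.items() if v > 0}
    if not positive:
        return OriginInference(
            locus_id=locus_id, derived_labels=[der.label], ancestral_labels=[anc.label],
            founding_label=der.label, scores=scores, top_regions=[],
            status="disjoint — origin indeterminate",
            n_derived=der.n, n_ancestral=anc.n,
        )
    best = max(positive.values())
    top = sorted(r for r, v in positive.items() if v == best)
    return OriginInference(
        locus_id=locus_id, derived_labels=[der.label], ancestral_labels=[anc.label],
        founding_label=der.label, scores=scores, top_regions=top, status="ok",
        n_derived=der.n, n_ancestral=anc.n,
    )


def locus_origin(
    net: HaploNetwork,
    samples: SampleTable,
    locus_id: str = "",
    score_mode: str = "min",
) -> OriginInference:
    """End-to-end origin call for one locus network.

    Finds the founding derived haplotype and its nearest ancestral
    node(s); when several ancestral nodes tie, their geographic
    distributions are aggregated before scoring.
    """
    geo = {g.label: g for g in haplotype_geography(net, samples)}
    pairs, founding = nearest_ancestral(net)
    anc_labels = sorted({a for d, a, _w in pairs if d == founding})
    der_geo = geo[founding]
    if len(anc_labels) == 1:
        anc_geo = geo[anc_labels[0]]
    else:
        counts: dict[str, int] = {}
        for a in anc_labels:
            for r, c in geo[a].counts.items():
                counts[r] = counts.get(r, 0) + c
        freq: dict[str, float] = {}
        for a in anc_labels:
            for r, f in geo[a].frequency.items():
                freq[r] = freq.get(r, 0.0) + f
        anc_geo = GeoDistribution(label="+".join(anc_labels), counts=counts, frequency=freq)
    result = infer_origin(anc_geo, der_geo, locus_id=locus_id, score_mode=score_mode)
    result.ancestral_labels = anc_labels
    result.derived_labels = sorted(
        n.label for n in net.nodes if n.causal_status == "derived"
    )
    return result
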