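"""Synthetic datasets with the structure the analysis assumes.

The generator is a founder-haplotype pool model, not a coalescent: each
geographic cell (region) on a one-dimensional west-to-east axis holds a
pool of ``k`` wild founder haplotypes derived from a regional consensus;
regional consensuses form a stepping-stone chain along the axis.  Every
mutation event hits a previously unused site (infinite-sites), so the
wild genealogy is homoplasy-free and — absent recombination within a
chromosome — four-gamete violations never arise by construction.

Domesticates draw their haplotypes from a shared, bottlenecked
"domestication core" pool (``core_founders`` haplotypes sampled across
the regional wild pools) mixed with a small region-local component
(``local_fraction`` of draws come from ``b < k`` founders of the local
pool).  The shared core makes domesticate groups far less
differentiated from one another — and from a feral mosaic of
domesticate chromosomes — than any of them is from a regional wild
population, reproducing the feral/wild/domesticate Fst ordering the
analysis expects.  Each causal domestication locus (one SNP, two
whole-gene deletions by default) arises on a single
parent founder haplotype in one seeded origin region; the derived
haplotype adds the causal change plus a linked marker mutation, and the
parent founder is excluded from every domesticate pool so the ancestral
haplotype survives only in wild samples — mirroring the situation where
the progenitor haplotype of a swept allele persists only in the wild
species.  A domesticate in region ``r`` carries the derived haplotype
with probability ``d**|r - origin|`` (diffusion parameter ``d``); every
carrier is homozygous for the single derived founder haplotype across
the sweep interval, so carrier diversity inside the sweep is exactly
zero.  Gene deletions are additionally represented as missing genotypes
inside the deleted span and as zero median read depth.

Feral samples are per-chromosome mosaics: each chromosome is copied from
a random domesticate with probability ``1 - feral_admixture``, else from
a random wild sample.

Site placement is non-uniform: a block of sites is concentrated inside
each locus's focal (network) region so that local SNP density there
resembles resequencing data, while the genome-wide site count stays
small enough for fast simulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeMatrix, SampleTable, ValidationError

WEST_AFRICA_CELLS = ["Senegal", "Guinea", "Mali", "Nigeria", "Cameroon"]


@dataclass(frozen=True)
class LocusSpec:
    """A causal domestication locus seeded in one origin region."""

    locus_id: str
    chrom: str
    pos: int
    kind: str  # "snp" | "gene_deletion"
    origin_region: int
    sweep_halfwidth: int = 25_000
    gene_start: int | None = None  # deletions only, half-open
    gene_end: int | None = None
    focal_start: int = 0  # region used for haplotype networks
    focal_end: int = 0
    trait: str = "shattering"  # "shattering" | "architecture"


def default_loci() -> list[LocusSpec]:
    return [
        LocusSpec(
            locus_id="sh4like", chrom="chr1", pos=500_000, kind="snp",
            origin_region=2, sweep_halfwidth=25_000,
            focal_start=496_000, focal_end=503_000, trait="shattering",
        ),
        LocusSpec(
            locus_id="sh1like", chrom="chr2", pos=500_000, kind="gene_deletion",
            origin_region=0, sweep_halfwidth=25_000,
            gene_start=495_000, gene_end=505_000,
            focal_start=489_000, focal_end=495_000, trait="shattering",
        ),
        LocusSpec(
            locus_id="prog1like", chrom="chr3", pos=500_000, kind="gene_deletion",
            origin_region=4, sweep_halfwidth=25_000,
            gene_start=495_000, gene_end=505_000,
            focal_start=489_000, focal_end=495_000, trait="architecture",
        ),
    ]


def default_genes() -> list[tuple[str, str, int, int]]:
    """Depth-profiling intervals: each deletion target plus a control gene."""
    return [
        ("sh1like", "chr2", 495_000, 505_000),
        ("ctrl_chr2", "chr2", 450_000, 455_000),
        ("prog1like", "chr3", 495_000, 505_000),
        ("ctrl_chr3", "chr3", 450_000, 455_000),
    ]


@dataclass
class SimConfig:
    n_regions: int = 5
    n_wild_per_region: int = 10
    n_dom_per_group: int = 30
    n_feral: int = 15
    chrom_length: int = 1_000_000
    n_sites_per_chrom: int = 1_000
    n_focal_sites: int = 120
    founders_per_region: int = 8
    bottleneck_founders: int = 3
    core_founders: int = 4
    local_fraction: float = 0.25
    mu_region: float = 60.0  # mutations per stepping-stone step, per chrom
    mu_founder: float = 12.0  # mutations per founder haplotype, per chrom
    diffusion: float = 0.5
    feral_admixture: float = 0.25
    mean_coverage: float = 15.0
    rng_seed: int = 0
    loci: list[LocusSpec] = field(default_factory=default_loci)

    def __post_init__(self) -> None:
        if not 0.0 <= self.diffusion <= 1.0:
            raise ValidationError("diffusion must be in [0, 1]")
        if not 0.0 <= self.feral_admixture <= 1.0:
            raise ValidationError("feral_admixture must be in [0, 1]")
        if self.mean_coverage < 0:
            raise ValidationError("mean_coverage must be >= 0")
        if self.n_wild_per_region <= 0 or self.n_dom_per_group <= 0:
            raise ValidationError("referenced group sample sizes must be positive")
        if not 0 < self.bottleneck_founders < self.founders_per_region:
            raise ValidationError("need 0 < bottleneck_founders < founders_per_region")
        if self.core_founders <= 0:
            raise ValidationError("core_founders must be positive")
        if not 0.0 <= self.local_fraction <= 1.0:
            raise ValidationError("local_fraction must be in [0, 1]")
        for locus in self.loci:
            if not 0 <= locus.origin_region < self.n_regions:
                raise ValidationError(f"{locus.locus_id}: origin_region out of range")
            if locus.sweep_halfwidth < 0:
                raise ValidationError(f"{locus.locus_id}: sweep_halfwidth must be >= 0")
            if locus.kind not in ("snp", "gene_deletion"):
                raise ValidationError(f"{locus.locus_id}: unknown kind {locus.kind!r}")
            if locus.kind == "gene_deletion" and (
                locus.gene_start is None or locus.gene_end is None
            ):
                raise ValidationError(f"{locus.locus_id}: deletion locus needs a gene span")

    def chroms(self) -> list[str]:
        named = {l.chrom for l in self.loci}
        return sorted(named) if named else ["chr1"]

    def region_country(self, r: int) -> str:
        if self.n_regions == len(WEST_AFRICA_CELLS):
            return WEST_AFRICA_CELLS[r]
        return f"region-{r}"


@dataclass
class TruthRecord:
    """Generator ground truth for parameter-recovery tests."""

    origin_region: dict[str, int]
    carriers: dict[str, dict[str, bool]]  # locus_id -> sample_id -> carries derived
    deletions: dict[str, dict[str, bool]]  # gene_id -> sample_id -> deleted
    sweep_intervals: dict[str, tuple[str, int, int]]
    region_of_sample: dict[str, int]
    lineages: dict[str, dict[str, list[str]]]  # chrom -> sample -> [hap0, hap1]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "origin_region": self.origin_region,
            "carriers": self.carriers,
            "deletions": self.deletions,
            "sweep_intervals": {k: list(v) for k, v in self.sweep_intervals.items()},
            "region_of_sample": self.region_of_sample,
            "lineages": self.lineages,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            origin_region=d["origin_region"],
            carriers=d["carriers"],
            deletions=d["deletions"],
            sweep_intervals={k: tuple(v) for k, v in d["sweep_intervals"].items()},
            region_of_sample=d["region_of_sample"],
            lineages=d["lineages"],
        )


# ----------------------------------------------------------------------
# core generator


class _MutationPool:
    """Infinite-sites allocator: every mutation hits a fresh site."""

    def __init__(self, free_indices: np.ndarray, rng: np.random.Generator):
        self._pool = list(rng.permutation(free_indices))

    def draw(self, k: int) -> list[int]:
        if k > len(self._pool):
            raise ValidationError(
                "mutation budget exceeds available sites; increase n_sites_per_chrom"
            )
        return [self._pool.pop() for _ in range(int(k))]


def _chrom_sites(cfg: SimConfig, locus: LocusSpec | None, rng: np.random.Generator) -> np.ndarray:
    """Site positions: dense inside the locus focal region, sparse elsewhere."""
    reserved = set()
    if locus is not None:
        if locus.kind == "snp":
            reserved.add(locus.pos)
        n_focal = min(cfg.n_focal_sites, cfg.n_sites_per_chrom // 2)
        focal = rng.choice(
            np.arange(locus.focal_start, locus.focal_end), size=n_focal, replace=False
        )
        reserved.update(int(p) for p in focal)
    n_bg = cfg.n_sites_per_chrom - len(reserved)
    chosen: dict[int, None] = {}
    while len(chosen) < n_bg:
        draw = rng.integers(1, cfg.chrom_length + 1, size=2 * (n_bg - len(chosen)))
        for p in draw:
            p = int(p)
            if p not in reserved and p not in chosen:
                chosen[p] = None
                if len(chosen) == n_bg:
                    break
    positions = np.array(sorted(reserved | set(chosen)), dtype=np.int64)
    return positions


def simulate_dataset(cfg: SimConfig) -> tuple[GenotypeMatrix, SampleTable, TruthRecord]:
    """Generate genotypes, sample metadata and ground truth.

    Deterministic for a fixed config (including ``rng_seed``).
    """
    rng = np.random.default_rng(cfg.rng_seed)
    chroms = cfg.chroms()
    locus_by_chrom = {l.chrom: l for l in cfg.loci}
    if len(locus_by_chrom) != len(cfg.loci):
        raise ValidationError("at most one causal locus per chromosome")

    # ---- sample frame ------------------------------------------------
    sample_ids: list[str] = []
    groups: list[str] = []
    species: list[str] = []
    regions: list[int] = []
    for r in range(cfg.n_regions):
        for i in range(cfg.n_wild_per_region):
            sample_ids.append(f"W{r}-{i:02d}")
            groups.append(f"WILD{r}")
            species.append("wild")
            regions.append(r)
    for r in range(cfg.n_regions):
        for i in range(cfg.n_dom_per_group):
            sample_ids.append(f"D{r}-{i:02d}")
            groups.append(f"DOM{r}")
            species.append("domesticate")
            regions.append(r)
    feral_regions = rng.integers(0, cfg.n_regions, size=cfg.n_feral)
    for i in range(cfg.n_feral):
        sample_ids.append(f"F-{i:02d}")
        groups.append("FERAL")
        species.append("wild")  # mislabeled/feral samples present as wild
        regions.append(int(feral_regions[i]))

    n_samples = len(sample_ids)
    wild_rows = [i for i, s in enumerate(species[: n_samples - cfg.n_feral]) if s == "wild"]
    dom_rows = [
        i
        for i, g in enumerate(groups)
        if g.startswith("DOM")
    ]
    feral_rows = list(range(n_samples - cfg.n_feral, n_samples))

    truth = TruthRecord(
        origin_region={l.locus_id: l.origin_region for l in cfg.loci},
        carriers={l.locus_id: {} for l in cfg.loci},
        deletions={
            l.locus_id: {} for l in cfg.loci if l.kind == "gene_deletion"
        },
        sweep_intervals={
            l.locus_id: (l.chrom, l.pos - l.sweep_halfwidth, l.pos + l.sweep_halfwidth)
            for l in cfg.loci
        },
        region_of_sample=dict(zip(sample_ids, (int(r) for r in regions))),
        lineages={},
    )

    # carrier draws are per sample and locus, shared across the locus chromosome
    for locus in cfg.loci:
        p_by_region = {
            r: cfg.diffusion ** abs(r - locus.origin_region) for r in range(cfg.n_regions)
        }
        for i in dom_rows:
            p = p_by_region[regions[i]]
            truth.carriers[locus.locus_id][sample_ids[i]] = bool(rng.random() < p)
        for i in wild_rows:
            truth.carriers[locus.locus_id][sample_ids[i]] = False

    all_chrom, all_pos, all_geno = [], [], []
    for chrom in chroms:
        locus = locus_by_chrom.get(chrom)
        positions = _chrom_sites(cfg, locus, rng)
        m = len(positions)
        pos_index = {int(p): j for j, p in enumerate(positions)}

        # reserve the causal site and one linked marker site in the focal region
        causal_idx = linked_idx = None
        reserved = []
        if locus is not None:
            if locus.kind == "snp":
                causal_idx = pos_index[locus.pos]
                reserved.append(causal_idx)
            focal_mask = (positions >= locus.focal_start) & (positions < locus.focal_end)
            focal_candidates = np.flatnonzero(focal_mask)
            if causal_idx is not None:
                focal_candidates = focal_candidates[focal_candidates != causal_idx]
            linked_idx = int(rng.choice(focal_candidates))
            reserved.append(linked_idx)
        pool = _MutationPool(
            np.setdiff1d(np.arange(m), np.array(reserved, dtype=int)), rng
        )

        # stepping-stone consensus chain and per-region founder pools
        consensus = np.zeros((cfg.n_regions, m), dtype=np.int8)
        for r in range(1, cfg.n_regions):
            consensus[r] = consensus[r - 1]
            consensus[r, pool.draw(rng.poisson(cfg.mu_region))] ^= 1
        founders = np.zeros((cfg.n_regions, cfg.founders_per_region, m), dtype=np.int8)
        for r in range(cfg.n_regions):
            for j in range(cfg.founders_per_region):
                founders[r, j] = consensus[r]
                founders[r, j, pool.draw(rng.poisson(cfg.mu_founder))] ^= 1

        # derived haplotype: parent founder + causal change + linked marker
        derived = None
        parent_founder = None
        if locus is not None:
            parent_founder = int(rng.integers(cfg.founders_per_region))
            derived = founders[locus.origin_region, parent_founder].copy()
            if causal_idx is not None:
                derived[causal_idx] = 1
            derived[linked_idx] = 1
            sweep_mask = (positions >= locus.pos - locus.sweep_halfwidth) & (
                positions < locus.pos + locus.sweep_halfwidth
            )

        # domestication core pool: a bottlenecked sample across regional
        # wild pools, shared by every domesticate group; the parent
        # founder of the derived haplotype is never part of it
        core: list[tuple[int, int]] = []
        while len(core) < cfg.core_founders:
            r = int(rng.integers(cfg.n_regions))
            j = int(rng.integers(cfg.founders_per_region))
            if locus is not None and r == locus.origin_region and j == parent_founder:
                continue
            if (r, j) not in core:
                core.append((r, j))

        # region-local pools: thinned founder subsets, parent excluded
        dom_pool_idx = np.zeros((cfg.n_regions, cfg.bottleneck_founders), dtype=int)
        for r in range(cfg.n_regions):
            candidates = np.arange(cfg.founders_per_region)
            if locus is not None and r == locus.origin_region:
                candidates = candidates[candidates != parent_founder]
            dom_pool_idx[r] = rng.choice(
                candidates, size=cfg.bottleneck_founders, replace=False
            )

        geno = np.zeros((n_samples, 2, m), dtype=np.int8)
        lineage = {sid: ["", ""] for sid in sample_ids}
        for i in wild_rows:
            r = regions[i]
            for h in range(2):
                j = int(rng.integers(cfg.founders_per_region))
                geno[i, h] = founders[r, j]
                lineage[sample_ids[i]][h] = f"r{r}.f{j}"
        for i in dom_rows:
            r = regions[i]
            carries = locus is not None and truth.carriers[locus.locus_id][sample_ids[i]]
            for h in range(2):
                if rng.random() < cfg.local_fraction:
                    j = int(dom_pool_idx[r][rng.integers(cfg.bottleneck_founders)])
                    geno[i, h] = founders[r, j]
                    lineage[sample_ids[i]][h] = f"r{r}.f{j}"
                else:
                    cr, cj = core[int(rng.integers(len(core)))]
                    geno[i, h] = founders[cr, cj]
                    lineage[sample_ids[i]][h] = f"core.r{cr}.f{cj}"
                if carries:
                    geno[i, h, sweep_mask] = derived[sweep_mask]
                    lineage[sample_ids[i]][h] = f"derived:{locus.locus_id}"
        # feral mosaics: whole-chromosome copies
        for i in feral_rows:
            if rng.random() < 1.0 - cfg.feral_admixture:
                src = dom_rows[int(rng.integers(len(dom_rows)))]
            else:
                src = wild_rows[int(rng.integers(len(wild_rows)))]
            geno[i] = geno[src]
            lineage[sample_ids[i]] = list(lineage[sample_ids[src]])
            if locus is not None:
                truth.carriers[locus.locus_id][sample_ids[i]] = truth.carriers[
                    locus.locus_id
                ].get(sample_ids[src], False)

        # gene deletions: carriers lose all genotypes inside the span
        if locus is not None and locus.kind == "gene_deletion":
            gene_mask = (positions >= locus.gene_start) & (positions < locus.gene_end)
            for i, sid in enumerate(sample_ids):
                deleted = truth.carriers[locus.locus_id].get(sid, False)
                truth.deletions[locus.locus_id][sid] = bool(deleted)
                if deleted:
                    geno[i, :, gene_mask] = MISSING

        truth.lineages[chrom] = lineage
        all_chrom.append(np.full(m, chrom, dtype=object))
        all_pos.append(positions)
        all_geno.append(geno)

    positions = np.concatenate(all_pos)
    matrix = GenotypeMatrix(
        sample_ids=sample_ids,
        chrom=np.concatenate(all_chrom),
        pos=positions,
        ref=np.full(len(positions), "A", dtype=object),
        alt=np.full(len(positions), "T", dtype=object),
        genotypes=np.concatenate(all_geno, axis=2),
        phased=True,
    )

    lon = np.array([-16.0 + 7.0 * r for r in regions]) + rng.uniform(-2.5, 2.5, n_samples)
    lat = 10.0 + rng.uniform(-4.0, 4.0, n_samples)
    samples = SampleTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "species": species,
                "group": groups,
                "country": [cfg.region_country(r) for r in regions],
                "lat": np.round(lat, 5),
                "lon": np.round(lon, 5),
                "mean_coverage": cfg.mean_coverage,
            }
        )
    )
    return matrix, samples, truth


# ----------------------------------------------------------------------
# read depth and phenotype emulation


def simulate_depths(
    truth: TruthRecord,
    samples: SampleTable,
    genes: list[tuple[str, str, int, int]],
    mean_coverage: float | None = None,
    rng_seed: int = 0,
) -> "pd.DataFrame":
    """Median per-base Poisson read depth per (sample, gene).

    Deleted genes (per the truth record) have a median of exactly zero;
    present genes draw per-base depths from Poisson(mean coverage).
    Gene intervals must be non-overlapping.  Returns a depth DataFrame
    compatible with :class:`oryzagen.datatypes.DepthTable`.
    """
    from .datatypes import DepthTable

    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for _, chrom, start, end in genes:
        for s, e in by_chrom.get(chrom, []):
            if start < e and s < end:
                raise ValidationError("gene intervals must be non-overlapping")
        by_chrom.setdefault(chrom, []).append((start, end))

    rng = np.random.default_rng(rng_seed)
    rows = []
    for _, sample in samples.df.iterrows():
        sid = sample["sample_id"]
        cov = float(sample["mean_coverage"]) if mean_coverage is None else mean_coverage
        if cov < 0:
            raise ValidationError("mean coverage must be >= 0")
        for gene_id, chrom, start, end in genes:
            deleted = truth.deletions.get(gene_id, {}).get(sid, False)
            if deleted:
                med = 0.0
            else:
                med = float(np.median(rng.poisson(cov, size=end - start)))
            rows.append((sid, gene_id, chrom, start, end, med))
    return DepthTable(pd.DataFrame(rows, columns=["sample_id", "gene_id", "chrom", "start", "end", "median_depth"]))


def simulate_phenotypes(
    cfg: SimConfig, truth: TruthRecord, samples: SampleTable, rng_seed: int = 0
) -> pd.DataFrame:
    """Percent-shattering phenotypes driven by the shattering loci.

    Samples carrying both shattering mutations shatter <5%, single
    carriers 6-30%, non-carriers (and wild plants) 55-95%.  A simple
    additive-threshold model sufficient to exercise the trait analyses.
    """
    rng = np.random.default_rng(rng_seed)
    shattering_loci = [l.locus_id for l in cfg.loci if l.trait == "shattering"]
    rows = []
    for sid in samples.sample_ids:
        n_mut = sum(truth.carriers[l].get(sid, False) for l in shattering_loci)
        if n_mut >= 2:
            pct = rng.uniform(0.0, 4.0)
        elif n_mut == 1:
            pct = rng.uniform(6.0, 30.0)
        else:
            pct = rng.uniform(55.0, 95.0)
        rows.append((sid, round(float(pct), 3)))
    return pd.DataFrame(rows, columns=["sample_id", "percent_shattering"])
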