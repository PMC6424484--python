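"""Shared in-memory data model for the pipeline.

The substrate of every statistic is a matrix of biallelic genotypes over
samples x sites (:class:`GenotypeMatrix`), accompanied by per-sample
metadata (:class:`SampleTable`) and per-gene read-depth medians
(:class:`DepthTable`).  Genotypes are stored at haplotype resolution as an
``(n_samples, 2, n_sites)`` int8 array with ``-1`` marking a missing
allele; unphased data uses the same layout but haplotype order within a
genotype carries no meaning.  Missing genotypes are never imputed;
downstream statistics use pairwise-available data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

SAMPLE_COLUMNS = ["sample_id", "species", "group", "country", "lat", "lon", "mean_coverage"]
DEPTH_COLUMNS = ["sample_id", "gene_id", "chrom", "start", "end", "median_depth"]


class ValidationError(ValueError):
    """Input data violates a documented invariant."""


@dataclass
class GenotypeMatrix:
    """Samples x biallelic sites with 1-based VCF positions.

    Parameters
    ----------
    sample_ids
        Ordered sample identifiers.
    chrom, pos
        Contig name and 1-based coordinate per site, sorted by
        ``(chrom, pos)`` and strictly increasing within a contig.
    ref, alt
        Single-character reference and alternate base per site.
    genotypes
        ``(n_samples, 2, n_sites)`` int8 array of alt-allele indicators
        per haplotype; ``-1`` is missing.
    phased
        Whether haplotype order within each genotype is meaningful.
    """

    sample_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray
    phased: bool = False

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n, m = len(self.sample_ids), len(self.pos)
        if self.genotypes.shape != (n, 2, m):
            raise ValidationError(
                f"genotypes shape {self.genotypes.shape} != ({n}, 2, {m})"
            )
        if not (len(self.chrom) == len(self.ref) == len(self.alt) == m):
            raise ValidationError("per-site arrays have inconsistent lengths")
        # strictly increasing positions within each contig
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not np.all(np.diff(p) > 0):
                raise ValidationError(f"positions not strictly increasing on {c}")
        if np.any(self.ref == self.alt):
            raise ValidationError("ref and alt alleles identical at some site")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def dosage(self) -> np.ndarray:
        """Unphased alt-allele dosage ``(n_samples, n_sites)`` float array.

        A genotype with any missing allele has dosage ``nan``.
        """
        g = self.genotypes
        d = g.sum(axis=1).astype(float)
        d[np.any(g == MISSING, axis=1)] = np.nan
        return d

    def haplotypes(self) -> np.ndarray:
        """``(2 * n_samples, n_sites)`` haplotype view (sample-major)."""
        return self.genotypes.reshape(self.n_samples * 2, self.n_sites)

    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per site: (# alt alleles, # called alleles) over all haplotypes."""
        h = self.haplotypes()
        called = h != MISSING
        return (h == 1).sum(axis=0), called.sum(axis=0)

    def take_samples(self, ids) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing}")
        rows = [index[s] for s in ids]
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in rows],
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            genotypes=self.genotypes[rows],
            phased=self.phased,
        )

    def take_sites(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        return GenotypeMatrix(
            sample_ids=self.sample_ids,
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            genotypes=self.genotypes[:, :, idx],
            phased=self.phased,
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.alt, other.alt)
            and np.array_equal(self.genotypes, other.genotypes)
            and self.phased == other.phased
        )


@dataclass
class SampleTable:
    """Per-sample species/group/geography/coverage metadata."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SAMPLE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"sample table missing columns: {missing}")
        if self.df["sample_id"].duplicated().any():
            dups = self.df.loc[self.df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        lat = pd.to_numeric(self.df["lat"], errors="coerce")
        lon = pd.to_numeric(self.df["lon"], errors="coerce")
        if ((lat < -90) | (lat > 90)).any():
            raise ValidationError("latitude outside [-90, 90]")
        if ((lon < -180) | (lon > 180)).any():
            raise ValidationError("longitude outside [-180, 180]")
        bad = set(self.df["species"]) - {"wild", "domesticate"}
        if bad:
            raise ValidationError(f"unknown species labels: {sorted(bad)}")
        self.df = self.df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.df["sample_id"].tolist()

    def group_of(self) -> dict[str, str]:
        return dict(zip(self.df["sample_id"], self.df["group"]))

    def country_of(self) -> dict[str, str]:
        return dict(zip(self.df["sample_id"], self.df["country"]))

    def species_of(self) -> dict[str, str]:
        return dict(zip(self.df["sample_id"], self.df["species"]))

    def ids_in_group(self, group: str) -> list[str]:
        return self.df.loc[self.df["group"] == group, "sample_id"].tolist()

    def ids_of_species(self, species: str) -> list[str]:
        return self.df.loc[self.df["species"] == species, "sample_id"].tolist()


@dataclass
class DepthTable:
    """Per-sample median read depth over named gene intervals.

    Intervals are half-open ``[start, end)``; one row per (sample, gene).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DEPTH_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"depth table missing columns: {missing}")
        if (self.df["start"] >= self.df["end"]).any():
            raise ValidationError("depth intervals must satisfy start < end")
        if (self.df["median_depth"] < 0).any():
            raise ValidationError("median_depth must be >= 0")
        if self.df.duplicated(subset=["sample_id", "gene_id"]).any():
            raise ValidationError("duplicate (sample, gene) depth rows")
        self.df = self.df.reset_index(drop=True)

    def median_for(self, sample_id: str, gene_id: str) -> float | None:
        rows = self.df[(self.df["sample_id"] == sample_id) & (self.df["gene_id"] == gene_id)]
        if rows.empty:
            return None
        return float(rows["median_depth"].iloc[0])
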