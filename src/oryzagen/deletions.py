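"""Read-depth presence/absence genotyping of candidate gene deletions.

A sample's deletion status is decided by comparing the median read depth
over the candidate gene to the median over a control gene outside the
deleted region: a zero (or near-zero, ratio <= threshold) target median
with an adequately covered control means the gene is deleted.  A control
median below the minimum gate yields no call — low overall coverage
cannot distinguish a deletion from missing data.

SNP deserts — long runs with no site passing the quality filters — are
used to localise candidate deleted regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import DepthTable, GenotypeMatrix, SampleTable, ValidationError

log = logging.getLogger(__name__)


@dataclass
class DeletionCall:
    sample_id: str
    gene_id: str
    target_median: float
    control_median: float
    call: str  # "deleted" | "present" | "no_call"
    ratio: float  # nan when control_median == 0


def call_deletions(
    depths: DepthTable,
    target_gene: str,
    control_gene: str,
    ratio_threshold: float = 0.1,
    control_min_depth: float = 1.0,
) -> list[DeletionCall]:
    """Genotype the target gene's deletion for every sample in the table.

    call = no_call when the control median fails the gate (or a gene row
    is missing); deleted when the target median is 0 or the
    target/control ratio <= ratio_threshold; present otherwise.
    """
    sample_ids = list(dict.fromkeys(depths.df["sample_id"]))
    calls = []
    for sid in sample_ids:
        t = depths.median_for(sid, target_gene)
        c = depths.median_for(sid, control_gene)
        if t is None or c is None:
            log.warning("sample %s missing a depth row; no_call", sid)
            calls.append(
                DeletionCall(sid, target_gene, np.nan if t is None else t,
                             np.nan if c is None else c, "no_call", np.nan)
            )
            continue
        ratio = t / c if c > 0 else np.nan
        if c < control_min_depth:
            call = "no_call"
        elif t == 0 or (np.isfinite(ratio) and ratio <= ratio_threshold):
            call = "deleted"
        else:
            call = "present"
        calls.append(DeletionCall(sid, target_gene, t, c, call, ratio))
    return calls


def deletion_frequency(
    calls: list[DeletionCall], samples: SampleTable
) -> pd.DataFrame:
    """Per-group deletion frequency: deleted / (deleted + present).

    no_call samples are excluded from the denominator; groups with zero
    callable samples are omitted with a warning.  Percentages are
    rounded to the nearest integer.
    """
    group_of = samples.group_of()
    counts: dict[str, dict[str, int]] = {}
    for call in calls:
        g = group_of.get(call.sample_id)
        if g is None:
            continue
        c = counts.setdefault(g, {"deleted": 0, "present": 0, "no_call": 0})
        c[call.call] += 1
    rows = []
    for g in sorted(counts):
        c = counts[g]
        callable_n = c["deleted"] + c["present"]
        if callable_n == 0:
            log.warning("group %s has zero callable samples; omitted", g)
            continue
        pct = int(round(100.0 * c["deleted"] / callable_n))
        rows.append((g, c["deleted"], c["present"], c["no_call"], pct))
    return pd.DataFrame(
        rows, columns=["group", "deleted", "present", "no_call", "deletion_pct"]
    )


@dataclass
class DesertInterval:
    chrom: str
    left_passing_pos: int
    right_passing_pos: int

    @property
    def length(self) -> int:
        return self.right_passing_pos - self.left_passing_pos


def snp_desert_regions(
    g: GenotypeMatrix, passing_mask: np.ndarray, min_gap_bp: int
) -> list[DesertInterval]:
    """Maximal gaps between consecutive passing sites of length >= min_gap.

    Returns each gap with its flanking passing-site coordinates, per
    chromosome.  An empty mask is an error.
    """
    passing_mask = np.asarray(passing_mask, dtype=bool)
    if passing_mask.shape != (g.n_sites,):
        raise ValidationError("passing mask must align to sites")
    if not passing_mask.any():
        raise ValidationError("no passing sites in mask")
    out = []
    for chrom in pd.unique(g.chrom):
        idx = np.flatnonzero((g.chrom == chrom) & passing_mask)
        pos = g.pos[idx]
        for left, right in zip(pos[:-1], pos[1:]):
            if right - left >= min_gap_bp:
                out.append(DesertInterval(str(chrom), int(left), int(right)))
    return out
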