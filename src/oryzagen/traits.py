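"""Panicle threshability scoring and genotype-phenotype concordance.

Percent shattering is converted to the Standard Evaluation System (SES)
panicle threshability score on the 1/3/5/7/9 scale: <1% -> 1, 1-5% -> 3,
6-15% -> 5, 26-50% -> 7, 51-100% -> 9.  The 16-25% band is not printed
on that scale; following the SES convention that assigns 6-25% to the
middle score, it maps to 5, keeping the scale monotone.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ValidationError


@dataclass
class ThreshabilityRecord:
    sample_id: str
    percent_shattering: float
    ses_score: int


def ses_score(percent_shattering: float) -> int:
    """SES panicle threshability score for a percent-shattering value."""
    p = float(percent_shattering)
    if not 0.0 <= p <= 100.0:
        raise ValidationError("percent shattering must be in [0, 100]")
    if p < 1.0:
        return 1
    if p <= 5.0:
        return 3
    if p <= 25.0:
        return 5
    if p <= 50.0:
        return 7
    return 9


def score_records(df: pd.DataFrame) -> list[ThreshabilityRecord]:
    """Score a table with columns sample_id, percent_shattering."""
    return [
        ThreshabilityRecord(row["sample_id"], float(row["percent_shattering"]),
                            ses_score(row["percent_shattering"]))
        for _, row in df.iterrows()
    ]


# ----------------------------------------------------------------------
# group comparisons


def mwu_exact_p(x, y) -> float:
    """Two-sided exact Mann-Whitney p by enumeration (tie-safe).

    Enumerates all assignments of the pooled values to the two groups
    and computes the probability of a U statistic at least as extreme
    (in |U - n1 n2 / 2|) as observed.  U is evaluated through the
    rank-sum identity U = W - n1(n1+1)/2 with midranks for ties, so
    each assignment costs one sum over precomputed ranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    w_center = n1 * (n1 + n2 + 1) / 2.0  # E[W]; |W - E[W]| == |U - n1 n2/2|
    w_obs = float(ranks[:n1].sum())
    dev = abs(w_obs - w_center)
    extreme = 0
    total = comb(n1 + n2, n1)
    rank_list = ranks.tolist()
    for ix in itertools.combinations(range(n1 + n2), n1):
        w = 0.0
        for i in ix:
            w += rank_list[i]
        if abs(w - w_center) >= dev - 1e-12:
            extreme += 1
    return extreme / total


def mann_whitney_p(x, y, exact_max_n: int = 20) -> float:
    """Two-sided Mann-Whitney p: exact enumeration for combined n <= 20,
    tie-corrected normal approximation (scipy) otherwise."""
    if len(x) + len(y) <= exact_max_n:
        return mwu_exact_p(x, y)
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue)


def pairwise_mwu(
    scores_by_group: dict[str, list[float]], correction: str = "bonferroni"
) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney tests between groups.

    Returns a square p-value matrix (corrected p capped at 1); empty
    groups are omitted with a warning.
    """
    if correction not in ("bonferroni", "none"):
        raise ValidationError(f"unknown correction {correction!r}")
    groups = {g: v for g, v in scores_by_group.items() if len(v) > 0}
    dropped = set(scores_by_group) - set(groups)
    if dropped:
        import logging

        logging.getLogger(__name__).warning("empty groups omitted: %s", sorted(dropped))
    names = sorted(groups)
    n_pairs = comb(len(names), 2)
    mat = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for i, gi in enumerate(names):
        for j in range(i + 1, len(names)):
            gj = names[j]
            p = mann_whitney_p(groups[gi], groups[gj])
            if correction == "bonferroni":
                p = min(1.0, p * n_pairs)
            mat.loc[gi, gj] = mat.loc[gj, gi] = p
    return mat


# ----------------------------------------------------------------------
# genotype-phenotype concordance


def concordance_table(
    sh1_status: dict[str, str],
    sh4_status: dict[str, str],
    scores: dict[str, int],
    group_of: dict[str, str],
) -> pd.DataFrame:
    """Cross-tabulate (sh1 status x sh4 status x score band) per group.

    Flags groups where an identical genotype combination yields more
    than one score band — the signature of additional unmodelled
    shattering loci.
    """
    rows = []
    samples = sorted(set(sh1_status) & set(sh4_status) & set(scores))
    for sid in samples:
        rows.append(
            (
                group_of.get(sid, "unknown"),
                sh1_status[sid],
                sh4_status[sid],
                scores[sid],
            )
        )
    df = pd.DataFrame(rows, columns=["group", "sh1_status", "sh4_status", "ses_score"])
    table = (
        df.groupby(["group", "sh1_status", "sh4_status", "ses_score"])
        .size()
        .reset_index(name="count")
    )
    flags = (
        df.groupby(["group", "sh1_status", "sh4_status"])["ses_score"]
        .nunique()
        .reset_index(name="n_score_bands")
    )
    flags["discordant"] = flags["n_score_bands"] > 1
    return table.merge(flags[["group", "sh1_status", "sh4_status", "discordant"]],
                       on=["group", "sh1_status", "sh4_status"])
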