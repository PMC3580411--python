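"""Rank-based association of telomere status with genomic burden.

Tumors called as telomere ``gain`` are compared against the pooled
``loss``/``no_change`` group on structural-variation and non-silent
mutation counts with the Mann-Whitney rank-sum test.  Exact enumeration
is used for small tie-free comparisons (total n <= 20), otherwise the
tie-corrected normal approximation.  A comparison with an empty group is
reported as NA rather than an error, matching how a cohort with no gains
(e.g. hematopoietic malignancies) should be summarized.  No
multiple-testing correction is applied; raw p-values are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, wilcoxon

from .mixture import GAIN, LOSS, NO_CHANGE

EXACT_MAX_N = 20
CALLS = (GAIN, LOSS, NO_CHANGE)


@dataclass(frozen=True)
class CohortSample:
    """One tumor with its telomere call and burden annotations."""

    pair_id: str
    call: str
    sv_count: int = 0
    nonsilent_mutation_count: int = 0
    age_years: float | None = None
    disease_group: str = "other"

    def __post_init__(self) -> None:
        if self.call not in CALLS:
            raise ValueError(f"unknown call {self.call!r}")
        if self.sv_count < 0 or self.nonsilent_mutation_count < 0:
            raise ValueError("burden counts must be non-negative")


@dataclass(frozen=True)
class RankSumResult:
    """Mann-Whitney U and p; ``is_na`` when a group was empty."""

    u: float
    p_value: float
    n_x: int
    n_y: int
    method: str  # "exact" | "asymptotic" | "na"

    @property
    def is_na(self) -> bool:
        return self.method == "na"


_NA_RESULT_NOTE = "NA"


def rank_sum_test(x: Sequence[float], y: Sequence[float],
                  alternative: str = "two_sided") -> RankSumResult:
    """Mann-Whitney rank-sum test of two independent samples.

    Uses exact enumeration when the pooled sample is small (<= 20) and
    tie-free, else the tie-corrected normal approximation with continuity
    correction.  Empty input on either side yields an NA result.
    """
    alt = {"two_sided": "two-sided", "greater": "greater", "less": "less"}
    if alternative not in alt:
        raise ValueError(f"unknown alternative {alternative!r}")
    xa, ya = np.asarray(x, float), np.asarray(y, float)
    if len(xa) == 0 or len(ya) == 0:
        return RankSumResult(math.nan, math.nan, len(xa), len(ya), "na")
    pooled = np.concatenate([xa, ya])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = (len(pooled) <= EXACT_MAX_N) and not has_ties
    method = "exact" if exact else "asymptotic"
    res = mannwhitneyu(xa, ya, alternative=alt[alternative], method=method)
    return RankSumResult(float(res.statistic), float(res.pvalue),
                         len(xa), len(ya), method)


def signed_rank_test(x: Sequence[float], y: Sequence[float],
                     alternative: str = "two_sided") -> RankSumResult:
    """Paired Wilcoxon signed-rank variant, for matched observations."""
    alt = {"two_sided": "two-sided", "greater": "greater", "less": "less"}
    xa, ya = np.asarray(x, float), np.asarray(y, float)
    if len(xa) == 0 or len(xa) != len(ya):
        return RankSumResult(math.nan, math.nan, len(xa), len(ya), "na")
    res = wilcoxon(xa, ya, alternative=alt[alternative])
    return RankSumResult(float(res.statistic), float(res.pvalue),
                         len(xa), len(ya), "signed_rank")


def cohort_frame(cohort: Sequence[CohortSample]) -> pd.DataFrame:
    return pd.DataFrame([{
        "pair_id": s.pair_id, "call": s.call, "sv_count": s.sv_count,
        "nonsilent_mutation_count": s.nonsilent_mutation_count,
        "age_years": s.age_years, "disease_group": s.disease_group,
    } for s in cohort])


def burden_by_status(cohort: Sequence[CohortSample], burden: str = "sv",
                     groups: Sequence[str] | None = None) -> dict:
    """Median burden per telomere-status group and the gain-vs-rest test.

    ``burden`` selects structural variations (``sv``) or non-silent
    mutations (``mutation``).  ``groups`` optionally restricts to disease
    groups.  The p-value compares the gain group against loss and
    no_change pooled; an empty side yields p = NA.
    """
    col = {"sv": "sv_count", "mutation": "nonsilent_mutation_count"}.get(burden)
    if col is None:
        raise ValueError("burden must be 'sv' or 'mutation'")
    df = cohort_frame(cohort)
    if groups is not None:
        df = df[df["disease_group"].isin(groups)]
    medians = {c: (float(df.loc[df["call"] == c, col].median())
                   if (df["call"] == c).any() else math.nan)
               for c in CALLS}
    gains = df.loc[df["call"] == GAIN, col].to_numpy()
    rest = df.loc[df["call"] != GAIN, col].to_numpy()
    test = rank_sum_test(gains, rest, alternative="two_sided")
    return {
        "burden": burden,
        "n": {c: int((df["call"] == c).sum()) for c in CALLS},
        "median": medians,
        "median_gain": medians[GAIN],
        "median_other": (float(df.loc[df["call"] != GAIN, col].median())
                         if len(rest) else math.nan),
        "u": test.u,
        "p_value": _NA_RESULT_NOTE if test.is_na else test.p_value,
    }


def status_fractions(cohort: Sequence[CohortSample],
                     group_by: str = "disease_group") -> pd.DataFrame:
    """Per-group counts and percentages of gain / loss / no_change calls.

    Percentages within a group sum to 100 before rounding.
    """
    df = cohort_frame(cohort)
    if df.empty:
        raise ValueError("empty cohort")
    rows = []
    for group, sub in df.groupby(group_by, sort=True):
        total = len(sub)
        for c in CALLS:
            k = int((sub["call"] == c).sum())
            rows.append({group_by: group, "call": c, "n": k,
                         "total": total, "percent": 100.0 * k / total})
    return pd.DataFrame(rows)
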