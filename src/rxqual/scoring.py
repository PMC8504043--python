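"""Fulfilment scores and univariate cohort comparisons.

Two scores summarise criterion outcomes:

* the **prescription-Fscore** — per prescription, met / applicable criteria;
* the **criteria-Fscore** — per criterion and cohort, prescriptions meeting
  the criterion / prescriptions where it applies.

Because a proportion in [0, 1] can sit exactly on the boundary, scores
entering the beta regression are first squeezed into the open interval via
the standard transformation ``(y·(N−1) + 0.5)/N`` with N the total number of
observations.

Cohort comparisons follow the study's univariate analyses: Mann–Whitney U
(normal approximation with tie correction, effect size r = |z|/√n) for
score distributions, and Pearson chi-squared on 2×2 met/not-met tables for
individual criteria.  The chi-squared default applies no continuity
correction; a switch is exposed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .criteria import AssessmentResult, CriterionOutcome
from .prescriptions import sample_sd

__all__ = [
    "FulfilmentScore",
    "CriterionSummary",
    "MannWhitneyResult",
    "ChiSquaredResult",
    "UndefinedScoreError",
    "prescription_fscore",
    "criteria_fscore",
    "criterion_summaries",
    "transform_to_open_interval",
    "inverse_transform",
    "compare_fscores",
    "compare_criterion",
    "round_percent",
]


class UndefinedScoreError(ValueError):
    """No applicable criteria: the fulfilment score has an empty denominator."""


@dataclass(frozen=True)
class FulfilmentScore:
    met: int
    applicable: int

    def __post_init__(self) -> None:
        if self.applicable <= 0:
            raise UndefinedScoreError("fulfilment score needs ≥1 applicable criterion")
        if not 0 <= self.met <= self.applicable:
            raise ValueError("met must satisfy 0 ≤ met ≤ applicable")

    @property
    def value(self) -> float:
        return self.met / self.applicable


@dataclass(frozen=True)
class CriterionSummary:
    criterion: int
    cohort: str
    met: int
    applicable: int

    @property
    def criteria_fscore(self) -> float:
        return self.met / self.applicable


@dataclass(frozen=True)
class MannWhitneyResult:
    u_statistic: float
    z: float
    p_value: float
    effect_size_r: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    n_a: int
    n_b: int


@dataclass(frozen=True)
class ChiSquaredResult:
    statistic: float
    p_value: float
    degenerate: bool = False


def prescription_fscore(a: AssessmentResult) -> FulfilmentScore:
    """Met/applicable ratio for one assessed prescription."""
    met = sum(o is CriterionOutcome.MET for o in a.outcomes)
    not_met = sum(o is CriterionOutcome.NOT_MET for o in a.outcomes)
    if met + not_met == 0:
        raise UndefinedScoreError(
            f"prescription {a.prescription_id!r}: every criterion not applicable"
        )
    return FulfilmentScore(met=met, applicable=met + not_met)


def criteria_fscore(met: int, applicable: int) -> float:
    """Cohort-level fulfilment proportion for one criterion."""
    if applicable < 1:
        raise UndefinedScoreError("criteria_fscore needs applicable ≥ 1")
    if not 0 <= met <= applicable:
        raise ValueError("met must satisfy 0 ≤ met ≤ applicable")
    return met / applicable


def criterion_summaries(
    results: Sequence[AssessmentResult], cohort: str
) -> list[CriterionSummary]:
    """Per-criterion met/applicable counts over a cohort.

    Criteria applicable nowhere in the cohort are omitted.
    """
    n_criteria = 20
    met = [0] * n_criteria
    applicable = [0] * n_criteria
    for r in results:
        for i, o in enumerate(r.outcomes):
            if o is CriterionOutcome.NOT_APPLICABLE:
                continue
            applicable[i] += 1
            if o is CriterionOutcome.MET:
                met[i] += 1
    return [
        CriterionSummary(criterion=i + 1, cohort=cohort, met=met[i], applicable=applicable[i])
        for i in range(n_criteria)
        if applicable[i] > 0
    ]


def transform_to_open_interval(score: float, n_total: int) -> float:
    """Map a proportion in [0,1] strictly inside (0,1): ``(y·(N−1)+0.5)/N``."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score must lie in [0,1], got {score}")
    if n_total < 2:
        raise ValueError("n_total must be ≥ 2")
    return (score * (n_total - 1) + 0.5) / n_total


def inverse_transform(value: float, n_total: int) -> float:
    """Algebraic inverse of :func:`transform_to_open_interval`."""
    return (value * n_total - 0.5) / (n_total - 1)


def compare_fscores(
    group_a: Sequence[float], group_b: Sequence[float]
) -> MannWhitneyResult:
    """Mann–Whitney U comparison of two score samples.

    Uses the normal approximation with tie correction.  The U statistic is
    reported for group A (small U means group A ranks low).  The effect size
    is r = |z|/√(n_a + n_b).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    n_a, n_b = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    r_a = ranks[:n_a].sum()
    u_a = r_a - n_a * (n_a + 1) / 2.0
    mu = n_a * n_b / 2.0
    n = n_a + n_b
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all values identical
        z = 0.0
    else:
        z = (u_a - mu) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return MannWhitneyResult(
        u_statistic=float(u_a),
        z=float(z),
        p_value=float(min(p, 1.0)),
        effect_size_r=float(abs(z) / math.sqrt(n)),
        mean_a=float(a.mean()),
        sd_a=sample_sd(a.tolist()),
        mean_b=float(b.mean()),
        sd_b=sample_sd(b.tolist()),
        n_a=int(n_a),
        n_b=int(n_b),
    )


def compare_criterion(
    met_a: int,
    applicable_a: int,
    met_b: int,
    applicable_b: int,
    continuity_correction: bool = False,
) -> ChiSquaredResult:
    """Pearson chi-squared on the 2×2 met/not-met table of two cohorts.

    A table with a zero margin (e.g. the criterion met by nobody, or by
    everybody, in both cohorts) is degenerate: the result carries p = 1 and
    the ``degenerate`` flag instead of an error.
    """
    for name, v in (("met_a", met_a), ("applicable_a", applicable_a),
                    ("met_b", met_b), ("applicable_b", applicable_b)):
        if v < 0:
            raise ValueError(f"{name} must be nonnegative")
    if applicable_a < 1 or applicable_b < 1:
        raise ValueError("both applicable counts must be ≥ 1")
    table = np.array(
        [[met_a, applicable_a - met_a], [met_b, applicable_b - met_b]], dtype=float
    )
    if (table.sum(axis=0) == 0).any():
        return ChiSquaredResult(statistic=0.0, p_value=1.0, degenerate=True)
    stat, p, _, _ = stats.chi2_contingency(table, correction=continuity_correction)
    return ChiSquaredResult(statistic=float(stat), p_value=float(p))


def round_percent(proportion: float, decimals: int = 1) -> float:
    """Percentage rounded half away from zero, matching tabular reporting."""
    x = proportion * 100.0 * 10**decimals
    return math.copysign(math.floor(abs(x) + 0.5), x) / 10**decimals
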