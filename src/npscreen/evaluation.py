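"""Ranking-quality and classification metrics for screening experiments.

The relative ranking position (RRP) of a true candidate ranked ``r`` among
``N`` candidates is ``(r - 1) / (N - 1)``: 0 for a perfect top rank, 1 for
the bottom rank, and 0.5 in expectation for a uniformly random ranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "ConfusionCounts",
    "RankOutcome",
    "confusion_metrics",
    "mean_rrp",
    "ranking_proportion",
    "rrp",
]


@dataclass(frozen=True)
class RankOutcome:
    """Rank of the true candidate within a candidate list."""

    rank: int
    candidate_count: int

    def __post_init__(self) -> None:
        if self.rank < 1 or self.candidate_count < 1:
            raise ValueError("rank and candidate_count must be >= 1")
        if self.rank > self.candidate_count:
            raise ValueError("rank cannot exceed candidate_count")


def rrp(outcome: RankOutcome) -> float:
    """Relative ranking position, (rank - 1) / (candidate_count - 1).

    A sole candidate (candidate_count = 1) is necessarily rank 1 and scores 0.
    """
    if outcome.candidate_count == 1:
        return 0.0
    return (outcome.rank - 1) / (outcome.candidate_count - 1)


def mean_rrp(outcomes: Sequence[RankOutcome]) -> float:
    if not outcomes:
        raise ValueError("mean_rrp requires at least one outcome")
    return sum(rrp(o) for o in outcomes) / len(outcomes)


def ranking_proportion(
    outcomes: Sequence[RankOutcome], k_max: int
) -> list[tuple[int, float]]:
    """Fraction of outcomes with rank <= k, for k = 1..k_max.

    A non-decreasing step curve, invariant to outcome order.
    """
    if not outcomes:
        raise ValueError("ranking_proportion requires at least one outcome")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    n = len(outcomes)
    return [
        (k, sum(1 for o in outcomes if o.rank <= k) / n) for k in range(1, k_max + 1)
    ]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


def confusion_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity, precision and F1 from confusion counts.

    A metric whose denominator is zero is reported as NaN (undefined), not 0.
    """
    nan = float("nan")
    sensitivity = c.tp / (c.tp + c.fn) if c.tp + c.fn > 0 else nan
    specificity = c.tn / (c.tn + c.fp) if c.tn + c.fp > 0 else nan
    precision = c.tp / (c.tp + c.fp) if c.tp + c.fp > 0 else nan
    if (
        math.isnan(precision)
        or math.isnan(sensitivity)
        or precision + sensitivity == 0
    ):
        f1 = nan
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    return {
        "sensitivity": sensitivity,
        "specificity": specificity,
        "precision": precision,
        "f1": f1,
    }
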