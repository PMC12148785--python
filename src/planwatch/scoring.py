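"""Protocol-fulfilment score, community percentile score, and inspector stats.

The protocol score is the percent of evaluated PTV + Main-OAR constraints
(standard and extra alike) whose mandatory limit is met; YELLOW therefore
counts as fulfilled. The community score for one metric is the integer
percent (floor) of comparable library plans whose value is strictly worse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .exceptions import ValidationError
from .protocols import ConstraintGroup, DoseConstraint, Comparator, PlanEvaluation, Status


class WorseDirection(str, Enum):
    GREATER_IS_WORSE = "GREATER_IS_WORSE"
    SMALLER_IS_WORSE = "SMALLER_IS_WORSE"


@dataclass
class InspectorStats:
    n: int
    minimum: float | None = None
    maximum: float | None = None
    mean: float | None = None
    sd: float | None = None
    hist_edges: np.ndarray | None = None
    hist_counts: np.ndarray | None = None
    cb_score: int | None = None
    above_mean: bool | None = None
    above_mean_plus_sd: bool | None = None


_SCORED_GROUPS = (ConstraintGroup.PTV, ConstraintGroup.MAIN_OAR)


def bw_score(evaluation: PlanEvaluation) -> int:
    """Percent of evaluated PTV + Main-OAR constraints fulfilled (0-100)."""
    in_scope = [
        r for r in evaluation.results
        if r.constraint.group in _SCORED_GROUPS and r.status != Status.NOT_EVALUATED
    ]
    if not in_scope:
        raise ValidationError(
            "no evaluated PTV or Main-OAR constraints; protocol score undefined"
        )
    fulfilled = sum(1 for r in in_scope if r.status in (Status.GREEN, Status.YELLOW))
    return int(round(100.0 * fulfilled / len(in_scope)))


def worse_direction(c: DoseConstraint) -> WorseDirection:
    """Which way a value degrades: LE limits worsen upward, GE downward."""
    if c.comparator == Comparator.LE:
        return WorseDirection.GREATER_IS_WORSE
    return WorseDirection.SMALLER_IS_WORSE


def cb_score(
    value: float, direction: WorseDirection, library_values: list[float] | np.ndarray
) -> int | None:
    """floor(100 x fraction of library values strictly worse than *value*).

    Ties count as not-worse. Returns None for an empty library (the caller
    reports "no comparable plans").
    """
    values = np.asarray(library_values, dtype=float)
    if values.size == 0:
        return None
    if direction == WorseDirection.GREATER_IS_WORSE:
        n_worse = int(np.sum(values > value))
    else:
        n_worse = int(np.sum(values < value))
    return math.floor(100.0 * n_worse / values.size)


def inspector_stats(
    values: list[float] | np.ndarray,
    query_value: float,
    direction: WorseDirection,
) -> InspectorStats:
    """Summary statistics + histogram + community score for one metric."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return InspectorStats(n=0)
    stats = InspectorStats(
        n=int(arr.size),
        minimum=float(arr.min()),
        maximum=float(arr.max()),
        mean=float(arr.mean()),
        cb_score=cb_score(query_value, direction, arr),
    )
    n_bins = int(np.clip(math.ceil(math.sqrt(arr.size)), 5, 20))
    counts, edges = np.histogram(arr, bins=n_bins)
    stats.hist_edges, stats.hist_counts = edges, counts
    if arr.size >= 2:
        stats.sd = float(arr.std(ddof=1))
        if direction == WorseDirection.GREATER_IS_WORSE:
            stats.above_mean = bool(query_value > stats.mean)
            stats.above_mean_plus_sd = bool(query_value > stats.mean + stats.sd)
        else:
            stats.above_mean = bool(query_value < stats.mean)
            stats.above_mean_plus_sd = bool(query_value < stats.mean - stats.sd)
    return stats
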