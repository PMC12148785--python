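"""Chronological-series change detection.

A metric's export-ordered values are split into BEFORE / AFTER groups at a
change index. Two one-tailed Mann-Whitney-Wilcoxon U-tests are run: one on
the raw values (level shift) and one on their squared deviations from the
group mean (dispersion change). The squared-deviation transform is

    qdev(x) = (f(x) - <f>)^2

with <f> the arithmetic mean over the chosen scope (per-group by default:
comparing per-group deviations is what tests a reduction in dispersion).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats as sps

from .exceptions import ValidationError


class Alternative(str, Enum):
    AFTER_LOWER = "AFTER_LOWER"
    AFTER_HIGHER = "AFTER_HIGHER"


class MeanScope(str, Enum):
    PER_GROUP = "PER_GROUP"
    WHOLE = "WHOLE"


@dataclass
class ChronoSeries:
    """Metric values in export order with the first index of the AFTER group."""

    values: np.ndarray
    change_index: int
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError("chronological series must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("chronological series contains non-finite values")
        if not 0 < self.change_index < len(self.values):
            raise ValidationError(
                f"change_index {self.change_index} outside (0, {len(self.values)})"
            )

    @property
    def before(self) -> np.ndarray:
        return self.values[: self.change_index]

    @property
    def after(self) -> np.ndarray:
        return self.values[self.change_index:]


@dataclass
class MWWResult:
    u_statistic: float
    p_one_tail: float
    n_before: int
    n_after: int
    alternative: Alternative


@dataclass
class ChangeReport:
    values_test: MWWResult
    qdev_test: MWWResult
    before_mean: float
    before_sd: float
    after_mean: float
    after_sd: float


def qdev(series: ChronoSeries, mean_scope: MeanScope = MeanScope.PER_GROUP) -> ChronoSeries:
    """Squared deviation of each value from the scope mean."""
    if mean_scope == MeanScope.WHOLE:
        out = (series.values - series.values.mean()) ** 2
    else:
        before, after = series.before, series.after
        if len(before) < 2 or len(after) < 2:
            raise ValidationError(
                "per-group squared deviations need >= 2 points per group"
            )
        out = np.concatenate([
            (before - before.mean()) ** 2,
            (after - after.mean()) ** 2,
        ])
    return ChronoSeries(out, series.change_index, label=f"qdev({series.label})")


def mww_utest(
    before: np.ndarray, after: np.ndarray, alternative: Alternative
) -> MWWResult:
    """One-tailed MWW U-test of AFTER against BEFORE.

    Exact permutation p-value when both samples are small (combined n <= 12)
    and tie-free; otherwise the normal approximation with tie and continuity
    corrections. The reported U counts (after, before) pairs won by AFTER.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if len(before) < 1 or len(after) < 1:
        raise ValidationError("both groups need at least one value")
    pooled = np.concatenate([before, after])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (no_ties and len(pooled) <= 12) else "asymptotic"
    scipy_alt = "greater" if alternative == Alternative.AFTER_HIGHER else "less"
    res = sps.mannwhitneyu(after, before, alternative=scipy_alt, method=method)
    return MWWResult(
        u_statistic=float(res.statistic),
        p_one_tail=float(min(res.pvalue, 1.0)),
        n_before=len(before),
        n_after=len(after),
        alternative=alternative,
    )


def change_detection(
    series: ChronoSeries,
    alternative: Alternative,
    mean_scope: MeanScope = MeanScope.PER_GROUP,
) -> ChangeReport:
    """Run both the raw-value and squared-deviation tests at the change point.

    *alternative* applies to the raw values (AFTER_LOWER for metrics where
    greater is worse). The dispersion test always asks whether squared
    deviations decreased (AFTER_LOWER).
    """
    before, after = series.before, series.after
    values_test = mww_utest(before, after, alternative)
    q = qdev(series, mean_scope)
    qdev_test = mww_utest(q.before, q.after, Alternative.AFTER_LOWER)
    return ChangeReport(
        values_test=values_test,
        qdev_test=qdev_test,
        before_mean=float(before.mean()),
        before_sd=float(before.std(ddof=1)) if len(before) > 1 else 0.0,
        after_mean=float(after.mean()),
        after_sd=float(after.std(ddof=1)) if len(after) > 1 else 0.0,
    )
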