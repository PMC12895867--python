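"""Time-to-onset distributions and nonparametric group comparisons.

Onset is the number of whole days from the start of therapy with the
primary-suspect drug (THER.START_DT) to the event date (DEMO.EVENT_DT).
Intervals are computed only when both dates are complete to the day and the
event does not precede the start; anything else is excluded with an explicit
reason (missing, partial_precision, negative_interval) rather than imputed —
spontaneous-report dates are too unreliable for imputation to be the
default, though a first-of-month mode exists for sensitivity analyses.

Group comparisons use the Mann-Whitney U test for two groups and the
Kruskal-Wallis test for more, with midranks for ties; cumulative incidence
is the empirical CDF of observed onsets per group (no censoring model).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .faers_io import PartialDate, SafetyReport

EXCLUSION_REASONS = ("missing", "partial_precision", "negative_interval")

#: closed integer day ranges, labelled as printed in descriptive tables
ONSET_BINS: tuple[tuple[int, float, str], ...] = (
    (0, 30, "0-30d"),
    (31, 60, "31-60d"),
    (61, 90, "61-90d"),
    (91, 180, "91-180d"),
    (181, 365, "181-365d"),
    (366, math.inf, ">365d"),
)
BIN_LABELS = tuple(label for _, _, label in ONSET_BINS)


@dataclass(frozen=True)
class OnsetResult:
    """Either a whole-day onset interval or an exclusion with its reason."""

    days: int | None
    reason: str | None = None

    @property
    def included(self) -> bool:
        return self.days is not None


@dataclass
class OnsetSample:
    group_label: str
    days: list[int] = field(default_factory=list)


@dataclass
class RankTestResult:
    statistic: float
    p_value: float
    n_per_group: list[int]
    tie_corrected: bool
    method: str = ""


def _complete(date: PartialDate, impute_partial: bool) -> PartialDate | None:
    if date.precision == "day":
        return date
    if impute_partial and date.precision == "month":
        return PartialDate(date.year, date.month, 1, "day")
    return None


def onset_days(report: SafetyReport, impute_partial: bool = False) -> OnsetResult:
    """Days from therapy start to event for one report, or an exclusion.

    Exclusion reasons: ``missing`` (either date absent), ``partial_precision``
    (a date known only to month or year), ``negative_interval`` (event
    before start — an input error).  With ``impute_partial=True``,
    month-precision dates are completed to the first of the month before
    the same rules apply (off by default).
    """
    start, event = report.therapy_start, report.event_date
    if start.precision == "none" or event.precision == "none":
        return OnsetResult(None, "missing")
    s = _complete(start, impute_partial)
    e = _complete(event, impute_partial)
    if s is None or e is None:
        return OnsetResult(None, "partial_precision")
    delta = (e.to_date() - s.to_date()).days
    if delta < 0:
        return OnsetResult(None, "negative_interval")
    return OnsetResult(delta)


def bin_onset(days: int) -> str:
    """Bin label for a non-negative whole-day onset."""
    if days < 0:
        raise ValueError("onset days must be non-negative")
    for lo, hi, label in ONSET_BINS:
        if lo <= days <= hi:
            return label
    raise AssertionError("unreachable")  # pragma: no cover


def bin_counts(days: Iterable[int]) -> dict[str, int]:
    counts = {label: 0 for label in BIN_LABELS}
    for d in days:
        counts[bin_onset(d)] += 1
    return counts


def median_iqr(
    days: Sequence[float], convention: str = "linear"
) -> tuple[float, float, float] | None:
    """Median and quartiles of an onset sample; None for an empty sample.

    ``convention='linear'`` uses linear interpolation of order statistics
    (the numpy default); ``'tukey'`` uses inclusive hinges (median of each
    half, the median itself included when n is odd).  The printed tables'
    convention is not knowable from the tables alone, so it is a switch.
    """
    values = np.asarray(days, dtype=float)
    if values.size == 0:
        return None
    med = float(np.median(values))
    if convention == "linear":
        q1, q3 = (float(q) for q in np.percentile(values, [25, 75]))
    elif convention == "tukey":
        v = np.sort(values)
        n = v.size
        half = (n + 1) // 2  # inclusive: odd n keeps the median in both halves
        q1 = float(np.median(v[:half]))
        q3 = float(np.median(v[n - half:]))
    else:
        raise ValueError(f"unknown quartile convention {convention!r}")
    return med, q1, q3


def _all_tied(*groups: Sequence[float]) -> bool:
    pooled = [v for g in groups for v in g]
    return len(set(pooled)) <= 1


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> RankTestResult:
    """Two-sided Mann-Whitney U test.

    The statistic is U for the first sample (rank-sum orientation, midranks
    for ties).  For samples of at most 8 per group without ties the exact
    permutation null is enumerated; otherwise the normal approximation with
    tie-corrected variance and continuity correction is used.  Degenerate
    input with every pooled value identical returns p = 1.
    """
    x, y = list(x), list(y)
    if not x or not y:
        raise ValueError("both samples must be non-empty")
    if _all_tied(x, y):
        return RankTestResult(len(x) * len(y) / 2.0, 1.0, [len(x), len(y)], True, "degenerate")
    has_ties = len(set(x) | set(y)) < len(x) + len(y)
    exact = max(len(x), len(y)) <= 8 and not has_ties
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return RankTestResult(
        float(res.statistic), float(min(res.pvalue, 1.0)),
        [len(x), len(y)], not exact, "exact" if exact else "normal_approx",
    )


def kruskal_wallis(groups: Sequence[Sequence[float]], labels: Sequence[str] | None = None) -> RankTestResult:
    """Kruskal-Wallis H test across k ≥ 2 groups with midranks and tie
    correction; p from the chi-square tail with k−1 degrees of freedom."""
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs at least two groups")
    labels = list(labels) if labels is not None else [str(i) for i in range(len(groups))]
    for lab, g in zip(labels, groups):
        if len(g) == 0:
            raise ValueError(f"group {lab!r} is empty")
    if _all_tied(*groups):
        return RankTestResult(0.0, 1.0, [len(g) for g in groups], True, "degenerate")
    h, p = stats.kruskal(*groups)
    return RankTestResult(float(h), float(p), [len(g) for g in groups], True, "chi2")


def cumulative_incidence(samples: Sequence[OnsetSample]) -> pd.DataFrame:
    """Empirical cumulative incidence per group.

    For each group and each observed onset day t, the percentage of that
    group's events with onset ≤ t.  Monotone nondecreasing, terminal value
    100%.  Long-format frame with columns group, day, cum_pct.
    """
    rows = []
    for sample in samples:
        if not sample.days:
            raise ValueError(f"group {sample.group_label!r} has no onsets")
        days = np.sort(np.asarray(sample.days))
        uniq, counts = np.unique(days, return_counts=True)
        cum = np.cumsum(counts) / days.size * 100.0
        for d, c in zip(uniq, cum):
            rows.append({"group": sample.group_label, "day": int(d), "cum_pct": float(c)})
    return pd.DataFrame(rows, columns=["group", "day", "cum_pct"])
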