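"""Group summaries and the study's inferential workflow.

Distributions are summarized as median with Tukey hinges (the box-plot
convention of the source workflow).  Two-group comparisons are gated by a
Shapiro–Wilk normality test per group: when both groups look normal an
unpaired two-tailed Welch t test is used, otherwise a two-tailed Wilcoxon
rank-sum test (exact enumeration for small samples).  Families of three or
more groups use Tukey's HSD with studentized-range adjustment.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import DomainError

#: Combined sample size up to which the rank-sum null is enumerated exactly.
EXACT_RANKSUM_MAX_N = 12

T_TEST = "t_unpaired_two_tailed"
WILCOXON = "wilcoxon_rank_sum_two_tailed"
TUKEY_HSD = "tukey_hsd"


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    median: float
    iqr_low: float
    iqr_high: float

    def __post_init__(self) -> None:
        if not self.iqr_low <= self.median <= self.iqr_high:
            raise DomainError("hinges must bracket the median")


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    groups: tuple[str, ...]
    normality_p: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise DomainError("p_value must lie in [0, 1]")


def tukey_hinges(values: Sequence[float]) -> tuple[float, float, float]:
    """(lower hinge, median, upper hinge) per Tukey's fourths.

    Hinge depth is ``(floor((n+1)/2) + 1) / 2``; half-integer depths average
    adjacent order statistics.  For {1,2,3,4,5} this gives hinges 2 and 4.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n == 0:
        raise DomainError("cannot summarize an empty sample")
    median = float(np.median(x))
    depth = (math.floor((n + 1) / 2) + 1) / 2.0
    lo_idx = depth - 1  # zero-based, possibly half-integer
    low = float((x[math.floor(lo_idx)] + x[math.ceil(lo_idx)]) / 2.0)
    high = float((x[n - 1 - math.floor(lo_idx)] + x[n - 1 - math.ceil(lo_idx)]) / 2.0)
    return low, median, high


def summarize(values: Sequence[float], label: str = "") -> GroupSummary:
    """Median and Tukey hinges of one group."""
    low, median, high = tukey_hinges(values)
    return GroupSummary(label=label, n=len(values), median=median,
                        iqr_low=low, iqr_high=high)


def shapiro_p(values: Sequence[float]) -> float:
    """Shapiro–Wilk p-value; degenerate (constant) samples report 0."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise DomainError("Shapiro-Wilk needs n >= 3")
    if np.ptp(x) == 0:
        return 0.0
    return float(sps.shapiro(x).pvalue)


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-tailed Wilcoxon rank-sum (Mann–Whitney U) test.

    Uses the exact null distribution when the combined sample size is at most
    :data:`EXACT_RANKSUM_MAX_N` (ties evaluated against the tie-free null,
    which is conservative) and the normal approximation with continuity
    correction above that.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    method = "exact" if a.size + b.size <= EXACT_RANKSUM_MAX_N else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return TestResult(WILCOXON, float(res.statistic), float(res.pvalue), ("a", "b"))


def compare_two_groups(
    a: Sequence[float],
    b: Sequence[float],
    labels: tuple[str, str] = ("a", "b"),
    alpha_normality: float = 0.05,
) -> TestResult:
    """Normality-gated two-group comparison.

    Both groups must pass Shapiro–Wilk at ``alpha_normality`` for the Welch
    t path; otherwise the Wilcoxon rank-sum path is taken.  The result
    records the per-group normality p-values so the path is auditable.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 3 or b.size < 3:
        raise DomainError("each group needs n >= 3 for the normality gate")
    norm_p = (shapiro_p(a), shapiro_p(b))
    if min(norm_p) > alpha_normality:
        res = sps.ttest_ind(a, b, equal_var=False)
        return TestResult(T_TEST, float(res.statistic), float(res.pvalue),
                          labels, norm_p)
    ranksum = wilcoxon_rank_sum(a, b)
    return TestResult(WILCOXON, ranksum.statistic, ranksum.p_value, labels, norm_p)


def tukey_hsd(groups: Mapping[str, Sequence[float]]) -> list[TestResult]:
    """All-pairs Tukey HSD over three or more labelled groups."""
    if len(groups) < 3:
        raise DomainError(
            "Tukey HSD needs >= 3 groups; use compare_two_groups for two"
        )
    labels = list(groups)
    samples = [np.asarray(groups[label], float) for label in labels]
    for label, sample in zip(labels, samples):
        if sample.size < 2:
            raise DomainError(f"group {label!r} needs n >= 2")
    res = sps.tukey_hsd(*samples)
    out = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            out.append(
                TestResult(
                    TUKEY_HSD,
                    float(res.statistic[i, j]),
                    float(res.pvalue[i, j]),
                    (labels[i], labels[j]),
                )
            )
    return out


def dampening_ratio(
    treated: GroupSummary | Sequence[float],
    control: GroupSummary | Sequence[float],
) -> float:
    """Treated-to-control ratio of group medians, in percent.

    Quantifies e.g. the reduction of the native b-wave in ReaChR-expressing
    animals: medians 58.09 µV vs 107.86 µV give 53.9 %.
    """
    if not isinstance(treated, GroupSummary):
        treated = summarize(treated, "treated")
    if not isinstance(control, GroupSummary):
        control = summarize(control, "control")
    if control.median <= 0:
        raise DomainError("control median must be > 0")
    return 100.0 * treated.median / control.median
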