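"""Replica-level aggregation and significance tests.

Two replica-level comparisons are provided, mirroring how multi-replica MD
occupancies are usually evaluated:

* a two-sided Mann-Whitney U test on the per-replica occupancy percentages
  (exact enumeration for small tie-free groups, tie-corrected normal
  approximation with continuity correction otherwise);
* a one-sided pooled-variance Student's t test on 0/1 "reached the active
  state" indicators, testing whether group A reaches more often than group B.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import AggregationError, DegenerateTestError, ParameterError
from .state_model import StateSeries, summarize_replica

__all__ = [
    "SystemSummary",
    "TestResult",
    "summarize_system",
    "mann_whitney_u",
    "indicator_t_test",
    "compare_systems",
    "significance_stars",
]

#: p-value thresholds for star annotations, most significant first.
STAR_LEVELS: tuple[tuple[float, str], ...] = (
    (0.0001, "****"),
    (0.001, "***"),
    (0.01, "**"),
    (0.05, "*"),
)


@dataclass(frozen=True)
class SystemSummary:
    system_label: str
    n_replicas: int
    frequencies_pct: tuple[float, ...]
    n_reached: int

    def __post_init__(self) -> None:
        if len(self.frequencies_pct) != self.n_replicas:
            raise AggregationError(
                f"{len(self.frequencies_pct)} frequencies for "
                f"{self.n_replicas} replicas"
            )
        if not 0 <= self.n_reached <= self.n_replicas:
            raise AggregationError(
                f"n_reached {self.n_reached} outside [0, {self.n_replicas}]"
            )

    @property
    def mean_frequency_pct(self) -> float:
        return float(np.mean(self.frequencies_pct))


@dataclass(frozen=True)
class TestResult:
    test_name: str
    sidedness: str
    statistic: float
    p_value: float
    group_sizes: tuple[int, int]
    stars: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ParameterError(f"p-value out of [0, 1]: {self.p_value}")


def significance_stars(p_value: float) -> str:
    """Map a p-value to its star annotation ('n.s.' when p > 0.05)."""
    for threshold, stars in STAR_LEVELS:
        if p_value <= threshold:
            return stars
    return "n.s."


def summarize_system(series_list: Sequence[StateSeries]) -> SystemSummary:
    """Collect per-replica occupancies and reached counts for one system."""
    if not series_list:
        raise AggregationError("need at least one replica series")
    labels = {s.system_label for s in series_list}
    if len(labels) != 1:
        raise AggregationError(
            f"mixed system labels in one aggregation: {sorted(labels)}"
        )
    summaries = [summarize_replica(s) for s in series_list]
    return SystemSummary(
        system_label=series_list[0].system_label,
        n_replicas=len(summaries),
        frequencies_pct=tuple(s.frequency_pct for s in summaries),
        n_reached=sum(s.reached_active for s in summaries),
    )


def mann_whitney_u(a: Sequence[float], b: Sequence[float],
                   use_continuity: bool = True) -> TestResult:
    """Two-sided Mann-Whitney U test on two samples.

    The exact null distribution is used when both groups are tie-free and the
    smaller one has <= 8 values; otherwise the normal approximation with tie
    correction (and optional continuity correction) is applied.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if np.ptp(pooled) == 0:
        # all values identical: no evidence either way
        return TestResult("mann_whitney_two_sided", "two_sided",
                          float(a.size * b.size / 2.0), 1.0,
                          (a.size, b.size), "n.s.")
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) \
        else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=use_continuity)
    p = float(min(res.pvalue, 1.0))
    return TestResult("mann_whitney_two_sided", "two_sided",
                      float(res.statistic), p, (a.size, b.size),
                      significance_stars(p))


def indicator_t_test(n_a: int, k_a: int, n_b: int, k_b: int,
                     sidedness: str = "one_sided") -> TestResult:
    """Pooled-variance Student's t test on binary reached-state indicators.

    Equivalent to a classical two-sample t test on vectors of ``k`` ones and
    ``n - k`` zeros per group, with df = n_a + n_b - 2.  One-sided tests the
    direction group A > group B.
    """
    for n, k, tag in ((n_a, k_a, "a"), (n_b, k_b, "b")):
        if not 0 <= k <= n:
            raise ParameterError(f"group {tag}: k={k} outside [0, n={n}]")
    if n_a < 2 or n_b < 2:
        raise ParameterError("both groups need n >= 2")
    if sidedness not in ("one_sided", "two_sided"):
        raise ParameterError(f"unknown sidedness '{sidedness}'")

    mean_a, mean_b = k_a / n_a, k_b / n_b
    # sum of squared deviations of a 0/1 vector with k ones: k (n-k) / n
    ss_a = k_a * (n_a - k_a) / n_a
    ss_b = k_b * (n_b - k_b) / n_b
    df = n_a + n_b - 2
    pooled_var = (ss_a + ss_b) / df
    if pooled_var == 0.0:
        raise DegenerateTestError(
            "zero pooled variance: every indicator identical within both "
            f"groups (k_a={k_a}/{n_a}, k_b={k_b}/{n_b})"
        )
    se = np.sqrt(pooled_var * (1.0 / n_a + 1.0 / n_b))
    t = (mean_a - mean_b) / se
    if sidedness == "one_sided":
        p = float(sps.t.sf(t, df))
    else:
        p = float(2.0 * sps.t.sf(abs(t), df))
    p = min(p, 1.0)
    return TestResult("student_t_pooled", sidedness, float(t), p,
                      (n_a, n_b), significance_stars(p))


def compare_systems(summary_a: SystemSummary, summary_b: SystemSummary,
                    use_continuity: bool = True) -> list[TestResult]:
    """Run both replica-level tests between two systems.

    Emits the two-sided Mann-Whitney U on per-replica occupancies and the
    one-sided indicator t test (direction A > B) on reached counts.  A
    degenerate indicator test (no variance because the reached counts are
    identical and extreme in both groups) is reported as t = 0, p = 1.
    """
    mw = mann_whitney_u(summary_a.frequencies_pct, summary_b.frequencies_pct,
                        use_continuity=use_continuity)
    try:
        tt = indicator_t_test(summary_a.n_replicas, summary_a.n_reached,
                              summary_b.n_replicas, summary_b.n_reached,
                              sidedness="one_sided")
    except DegenerateTestError:
        tt = TestResult("student_t_pooled", "one_sided", 0.0, 1.0,
                        (summary_a.n_replicas, summary_b.n_replicas), "n.s.")
    return [mw, tt]
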