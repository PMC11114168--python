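"""Normality screening and the Mann-Whitney comparison plan.

Segment scores from the six treatment events are compared with the
two-sample, two-sided Mann-Whitney U-test: one pooled comparison of all
MA segments against all VA segments, plus the eight pairwise MA-event
vs. VA-event comparisons.  A Kolmogorov-Smirnov screen against a fitted
normal motivates the nonparametric choice (segment scores are almost
never normal).

The exact U-test enumerates every assignment of the pooled values to the
two groups, which handles ties correctly; large samples use the normal
approximation with tie and continuity corrections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .core import BandDefinition
from .spectral import SegmentScores

__all__ = [
    "TestResult",
    "ComparisonPlan",
    "ComparisonTable",
    "default_plan",
    "ks_normality",
    "mann_whitney_u",
    "run_comparison_plan",
]

#: Largest pooled sample size for which exact enumeration is used in
#: ``auto`` mode (C(16, 8) = 12,870 assignments).
EXACT_LIMIT = 16


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    statistic: float
    p_value: float
    n1: int
    n2: int
    method: str
    degenerate: bool = False

    def decision(self, alpha: float = 0.05) -> str:
        return "ns" if self.p_value >= alpha else "sig"


def ks_normality(sample: Sequence[float], mode: str = "ks") -> TestResult:
    """Kolmogorov-Smirnov screen of a sample against normality.

    ``mode='ks'`` compares the ECDF with a normal CDF parameterized by
    the sample mean and standard deviation and takes the p-value from
    the Kolmogorov distribution.  Estimating the parameters from the
    same sample inflates that p-value (the Lilliefors problem);
    ``mode='lilliefors'`` applies the corrected reference distribution
    instead.  A zero-variance sample is flagged degenerate with p = 0.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 5:
        raise ValueError(f"need at least 5 observations, got {x.size}")
    std = x.std(ddof=1)
    if std == 0:
        return TestResult(1.0, 0.0, x.size, 0, mode, degenerate=True)
    if mode == "ks":
        d, p = sps.kstest(x, "norm", args=(x.mean(), std))
    elif mode == "lilliefors":
        from statsmodels.stats.diagnostic import lilliefors

        d, p = lilliefors(x, dist="norm")
    else:
        raise ValueError(f"unknown KS mode {mode!r}")
    return TestResult(float(d), float(p), x.size, 0, mode)


def _u_statistic(ranks: np.ndarray, n1: int) -> float:
    """U of the first sample from midranks of the pooled values."""
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)


def _exact_mwu(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided exact p by enumerating all group assignments (handles
    ties through midranks)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1, n = x.size, pooled.size
    mu = x.size * y.size / 2.0
    u_obs = _u_statistic(ranks, n1)
    dev_obs = abs(u_obs - mu)
    hits = total = 0
    offset = n1 * (n1 + 1) / 2.0
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - offset
        total += 1
        if abs(u - mu) >= dev_obs - 1e-9:
            hits += 1
    return u_obs, hits / total


def _approx_mwu(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Normal approximation with tie and continuity corrections."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1, n2, n = x.size, y.size, pooled.size
    u1 = _u_statistic(ranks, n1)
    mu = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return u1, 1.0
    big = max(u1, n1 * n2 - u1)
    z = (big - mu - 0.5) / math.sqrt(var)
    return u1, float(min(1.0, 2.0 * sps.norm.sf(z)))


def mann_whitney_u(x: Sequence[float], y: Sequence[float],
                   mode: str = "auto") -> TestResult:
    """Two-sample, two-sided Mann-Whitney U-test.

    ``mode='exact'`` enumerates all rank assignments; ``'approx'`` uses
    the tie- and continuity-corrected normal approximation; ``'auto'``
    picks exact for pooled sizes up to 16.  The reported U belongs to
    the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if mode == "auto":
        mode = "exact" if x.size + y.size <= EXACT_LIMIT else "approx"
    if mode == "exact":
        u, p = _exact_mwu(x, y)
        method = "exact"
    elif mode == "approx":
        u, p = _approx_mwu(x, y)
        method = "normal-approximation"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return TestResult(u, p, x.size, y.size, method)


@dataclass(frozen=True)
class Comparison:
    label: str
    ma_events: tuple[str, ...]
    va_events: tuple[str, ...]


@dataclass(frozen=True)
class ComparisonPlan:
    """The nine-comparison plan: pooled MA_T vs VA_T, then each MA event
    against each VA event, in table column order."""

    comparisons: tuple[Comparison, ...]

    def __post_init__(self) -> None:
        if len(self.comparisons) != 9:
            raise ValueError("the comparison plan has exactly 9 entries")

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.comparisons]

    @property
    def pairwise_labels(self) -> list[str]:
        return [c.label for c in self.comparisons
                if len(c.ma_events) == 1]


def default_plan() -> ComparisonPlan:
    comparisons = [Comparison("MA_T vs VA_T", ("MA1", "MA2"),
                              ("VA1", "VA2", "VA3", "VA4"))]
    for ma in ("MA1", "MA2"):
        for va in ("VA1", "VA2", "VA3", "VA4"):
            comparisons.append(Comparison(f"{ma} vs {va}", (ma,), (va,)))
    return ComparisonPlan(tuple(comparisons))


@dataclass
class ComparisonTable:
    """Per-subject, per-band test results for the nine-comparison plan."""

    rows: dict[tuple[str, str, str], TestResult] = field(default_factory=dict)
    alpha: float = 0.05

    def add(self, subject: str, band: str,
            results: Mapping[str, TestResult]) -> None:
        for label, result in results.items():
            self.rows[(subject, band, label)] = result

    def p_value(self, subject: str, band: str, label: str) -> float:
        return self.rows[(subject, band, label)].p_value

    def decision(self, subject: str, band: str, label: str) -> str:
        return self.rows[(subject, band, label)].decision(self.alpha)

    def to_frame(self, band: str = "raw"):
        """One row per subject, one p-value column per comparison."""
        import pandas as pd

        subjects = sorted({s for s, b, _ in self.rows if b == band})
        labels = default_plan().labels
        records = []
        for subject in subjects:
            row: dict[str, object] = {"subject": subject}
            for label in labels:
                res = self.rows.get((subject, band, label))
                if res is not None:
                    row[label] = res.p_value
            records.append(row)
        return pd.DataFrame.from_records(records)


def _score_values(scores: SegmentScores | Sequence[float]) -> np.ndarray:
    if isinstance(scores, SegmentScores):
        return np.asarray(scores.S, dtype=float)
    return np.asarray(scores, dtype=float)


def run_comparison_plan(scores: Mapping[str, SegmentScores | Sequence[float]],
                        plan: ComparisonPlan | None = None,
                        mode: str = "auto") -> dict[str, TestResult]:
    """Run all nine comparisons on one subject's per-event segment scores.

    ``scores`` maps each of the six treatment event names to that
    event's segment-score list; pooled comparisons concatenate the
    constituent events' scores.
    """
    plan = plan or default_plan()
    needed = {name for c in plan.comparisons
              for name in (*c.ma_events, *c.va_events)}
    for name in sorted(needed):
        if name not in scores:
            raise ValueError(f"missing segment scores for event {name!r}")
        if _score_values(scores[name]).size < 2:
            raise ValueError(f"event {name!r} has fewer than 2 segments")
    results: dict[str, TestResult] = {}
    for comp in plan.comparisons:
        ma = np.concatenate([_score_values(scores[e]) for e in comp.ma_events])
        va = np.concatenate([_score_values(scores[e]) for e in comp.va_events])
        results[comp.label] = mann_whitney_u(ma, va, mode=mode)
    return results
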