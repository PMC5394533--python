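"""Shared statistical primitives for group comparisons.

Two-sample t-tests (pooled-variance and Welch), a t statistic recomputed
from printed summary moments (mean ± SEM), Benjamini–Hochberg step-up
adjustment, and the social-interaction quotient used in behavioral
phenotyping. All tests are two-sided.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "GroupSummary",
    "TTestResult",
    "ZeroVarianceWarning",
    "student_t_test",
    "welch_t_test",
    "t_from_summary",
    "bh_adjust",
    "si_quotient",
]


class ZeroVarianceWarning(UserWarning):
    """Both groups are internally constant; t is reported as ±inf, p as 0."""


@dataclass(frozen=True)
class GroupSummary:
    """A group described by its printed moments: mean ± SEM with sample size n."""

    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if not math.isfinite(self.mean) or not math.isfinite(self.sem):
            raise ValueError("mean and sem must be finite")
        if self.sem < 0:
            raise ValueError(f"sem must be >= 0, got {self.sem}")
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    flavor: str  # "student" | "welch"


def _validate_two_groups(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1:
        raise ValueError("groups must be 1-D sequences of values")
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in input")
    if np.ptp(np.concatenate([a, b])) == 0:
        raise ValueError("all values identical across both groups; t undefined")
    return a, b


def _degenerate(a: np.ndarray, b: np.ndarray, df: float, flavor: str) -> TTestResult:
    # Both groups constant but their means differ: the infinite-t contract.
    warnings.warn(
        "zero within-group variance in both groups; reporting t = ±inf, p = 0",
        ZeroVarianceWarning,
        stacklevel=3,
    )
    t = math.inf if a.mean() > b.mean() else -math.inf
    return TTestResult(t=t, df=df, p=0.0, flavor=flavor)


def student_t_test(a, b) -> TTestResult:
    """Pooled-variance two-sample t-test, df = |a| + |b| - 2, two-sided p."""
    a, b = _validate_two_groups(a, b)
    df = a.size + b.size - 2
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return _degenerate(a, b, df, "student")
    res = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(t=float(res.statistic), df=float(df), p=float(res.pvalue), flavor="student")


def welch_t_test(a, b) -> TTestResult:
    """Unequal-variance two-sample t-test with Welch–Satterthwaite df, two-sided p."""
    a, b = _validate_two_groups(a, b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        return _degenerate(a, b, float(a.size + b.size - 2), "welch")
    wa, wb = va / a.size, vb / b.size
    df = (wa + wb) ** 2 / (
        (wa**2 / (a.size - 1) if va > 0 else 0.0) + (wb**2 / (b.size - 1) if vb > 0 else 0.0)
    )
    res = stats.ttest_ind(a, b, equal_var=False)
    return TTestResult(t=float(res.statistic), df=float(df), p=float(res.pvalue), flavor="welch")


def t_from_summary(sa: GroupSummary, sb: GroupSummary) -> float:
    """t recomputed from printed group moments: (mean_a - mean_b) / sqrt(sem_a^2 + sem_b^2).

    Returns t only: printed summary moments carry the difference and its
    standard error but published p-values are not always recoverable from
    them, so no p is attached. Antisymmetric in argument order.
    """
    if sa.sem == 0 and sb.sem == 0:
        raise ValueError("both SEMs are zero; t undefined")
    return (sa.mean - sb.mean) / math.hypot(sa.sem, sb.sem)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    Output order matches input order; values are monotone non-decreasing in
    the rank order of the inputs and capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1-D sequence")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


def si_quotient(duration_target: float, duration_empty: float) -> float:
    """Social-interaction quotient: time investigating the aggressor cage
    divided by time investigating the empty cage."""
    if duration_target < 0 or duration_empty < 0:
        raise ValueError("durations must be >= 0")
    if duration_empty == 0:
        raise ValueError("duration_empty is zero; quotient undefined")
    return duration_target / duration_empty
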