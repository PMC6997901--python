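"""Cross-participant comparison of distances and areas.

Because every participant contributes their own distance or area, the
per-participant values form ordinary samples and any two-sample test applies.
The default is Welch's unequal-variance t-test (two n=25 groups then have
df <= 48); the pooled-variance Student test and the paired test are also
built in, and ``compare`` accepts an arbitrary callable for anything else.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .exceptions import InsufficientDataError
from .geometry import GeometryStat

TestName = Literal["welch_t", "student_t", "paired_t"]


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of a two-sample comparison of per-participant statistics."""

    test_name: str
    statistic: float
    df: float
    p_value: float
    mean_a: float
    mean_b: float
    ci_low: float
    ci_high: float
    paired: bool
    alpha: float = 0.05

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if self.ci_low > self.ci_high:
            raise ValueError("confidence interval bounds out of order")

    def report(self) -> str:
        """Compact report string, e.g. ``[t(47.87) = -0.87, p = 0.389]``."""
        p = "p < 0.001" if self.p_value < 0.001 else f"p = {self.p_value:.3f}"
        return f"[t({self.df:.2f}) = {self.statistic:.2f}, {p}]"

    def __str__(self) -> str:
        return self.report()

    def to_dict(self) -> dict:
        return {
            "test": self.test_name,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "mean_a": self.mean_a,
            "mean_b": self.mean_b,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "paired": self.paired,
            "report": self.report(),
        }


def _values(sample) -> np.ndarray:
    vals = [s.value if isinstance(s, GeometryStat) else float(s) for s in sample]
    return np.asarray(vals, dtype=float)


def compare(
    stats_a: Sequence,
    stats_b: Sequence,
    test: TestName | Callable = "welch_t",
    alpha: float = 0.05,
) -> ComparisonResult:
    """Two-sided two-sample comparison of per-participant geometry statistics.

    Parameters
    ----------
    stats_a, stats_b
        Sequences of :class:`~mdsinfer.geometry.GeometryStat` or plain numbers.
    test
        ``"welch_t"`` (default, unequal variances), ``"student_t"`` (pooled
        variance), ``"paired_t"`` (matched participants, equal lengths), or a
        callable ``f(a_values, b_values) -> ComparisonResult`` plugging in any
        other procedure.
    alpha
        Significance level; the reported CI of the mean difference has
        coverage ``1 - alpha``.
    """
    a, b = _values(stats_a), _values(stats_b)
    if callable(test):
        return test(a, b)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError(
            f"need at least 2 values per group, got {len(a)} and {len(b)}"
        )
    if test == "paired_t":
        if len(a) != len(b):
            raise InsufficientDataError(
                f"paired test needs equal group sizes, got {len(a)} and {len(b)}"
            )
        diff = a - b
        if np.allclose(diff.std(ddof=1), 0.0) and np.allclose(diff.mean(), 0.0):
            # all differences zero: define t = 0, p = 1 rather than 0/0
            n = len(a)
            return ComparisonResult(
                "paired_t", 0.0, float(n - 1), 1.0,
                float(a.mean()), float(b.mean()), 0.0, 0.0, True, alpha,
            )
        res = sps.ttest_rel(a, b)
        paired = True
    elif test in ("welch_t", "student_t"):
        res = sps.ttest_ind(a, b, equal_var=(test == "student_t"))
        paired = False
    else:
        raise ValueError(f"unknown test {test!r}")

    ci = res.confidence_interval(confidence_level=1.0 - alpha)
    return ComparisonResult(
        test_name=test,
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        paired=paired,
        alpha=alpha,
    )


def adjust_pvalues(
    results: Sequence[ComparisonResult | float],
    method: Literal["bonferroni", "holm"] = "holm",
) -> np.ndarray:
    """Multiple-comparison adjusted p-values for a family of comparisons."""
    pvals = [r.p_value if isinstance(r, ComparisonResult) else float(r) for r in results]
    return multipletests(pvals, method=method)[1]
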