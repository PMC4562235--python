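"""Normality-gated test battery for choice-proportion data.

The analysis convention for these assays: check each vector of per-trial
proportions (or scores) with a Shapiro-Wilk test at alpha = 0.05; if
normality is not rejected use t-tests, otherwise fall back to the
rank-based equivalents (Wilcoxon signed-rank for one-sample location,
Mann-Whitney/Wilcoxon rank-sum for two samples, Kruskal-Wallis across
lines).  All p-values are two-sided.  Families of post-hoc comparisons are
corrected with Holm's step-down Bonferroni procedure.

The Wilcoxon signed-rank statistic is reported as V, the sum of ranks of
positive differences (the convention of R's ``wilcox.test``).  Differences
exactly at the null value are handled by Pratt's method — kept while
ranking, dropped from the rank sums — because proportions from discrete
counts land on the null with non-negligible probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import (
    ConfigurationError,
    DegenerateDataError,
    InsufficientDataError,
    ValidationError,
)

__all__ = [
    "TestResult",
    "normality_gate",
    "one_sample_location_test",
    "two_sample_test",
    "kruskal_wallis",
    "holm_adjust",
]


@dataclass(frozen=True)
class TestResult:
    """A named two-sided test: statistic, optional df, p-value, null value, n."""

    test_name: str
    statistic: float
    p_value: float
    null_value: float
    n: int
    df: Optional[float] = None
    sided: str = "two_sided"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")


def normality_gate(values: Sequence[float], alpha: float = 0.05) -> str:
    """Route a vector to ``"parametric"`` or ``"nonparametric"`` analysis.

    Shapiro-Wilk at ``alpha``; rejection (p < alpha) routes nonparametric.
    A constant vector cannot be tested and routes nonparametric with a
    warning rather than failing the pipeline.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise InsufficientDataError(f"normality gate needs n >= 3, got {x.size}")
    if np.ptp(x) == 0:
        warnings.warn("constant vector: normality untestable, using nonparametric path", stacklevel=2)
        return "nonparametric"
    w, p = stats.shapiro(x)
    return "nonparametric" if p < alpha else "parametric"


def _signed_rank_V(d: np.ndarray) -> float:
    """Sum of ranks of positive differences, zeros ranked then dropped (Pratt)."""
    ranks = stats.rankdata(np.abs(d))
    return float(ranks[d > 0].sum())


def one_sample_location_test(
    values: Sequence[float],
    null_value: float,
    method: str = "auto",
    gate_alpha: float = 0.05,
) -> TestResult:
    """One-sample location test against ``null_value`` (two-sided).

    ``method="auto"`` applies the normality gate and picks the t-test or the
    Wilcoxon signed-rank test accordingly; ``"t"`` and ``"wilcoxon"`` force a
    branch.  The Wilcoxon statistic is V (sum of positive-difference ranks,
    Pratt zero handling).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InsufficientDataError(f"one-sample test needs n >= 2, got {x.size}")
    d = x - null_value
    if np.all(d == 0):
        raise DegenerateDataError("all values equal the null value; test undefined")
    if method == "auto":
        method = "t" if normality_gate(x, alpha=gate_alpha) == "parametric" else "wilcoxon"
    if method == "t":
        res = stats.ttest_1samp(x, popmean=null_value)
        return TestResult(
            test_name="one_sample_t",
            statistic=float(res.statistic),
            df=float(x.size - 1),
            p_value=float(res.pvalue),
            null_value=null_value,
            n=int(x.size),
        )
    if method == "wilcoxon":
        v = _signed_rank_V(d)
        res = stats.wilcoxon(d, zero_method="pratt", alternative="two-sided")
        return TestResult(
            test_name="wilcoxon_signed_rank",
            statistic=v,
            p_value=float(res.pvalue),
            null_value=null_value,
            n=int(x.size),
        )
    raise ConfigurationError(f"unknown method {method!r}")


def two_sample_test(
    a: Sequence[float],
    b: Sequence[float],
    method: str = "auto",
    equal_var: bool = True,
    gate_alpha: float = 0.05,
) -> TestResult:
    """Two-sample comparison of per-trial proportions (two-sided).

    ``method="auto"`` routes to the pooled t-test unless the normality gate
    rejects for either sample, in which case the Mann-Whitney rank-sum test
    is used.  ``equal_var=False`` switches the t branch to Welch.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError(f"two-sample test needs n >= 2 per sample ({x.size}, {y.size})")
    if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
        raise DegenerateDataError("both samples constant and identical; test undefined")
    if method == "auto":
        gates = {normality_gate(x, alpha=gate_alpha), normality_gate(y, alpha=gate_alpha)}
        method = "mannwhitney" if "nonparametric" in gates else "t"
    if method == "t":
        res = stats.ttest_ind(x, y, equal_var=equal_var)
        if equal_var:
            df = float(x.size + y.size - 2)
        else:
            df = float(res.df)
        return TestResult(
            test_name="two_sample_t" if equal_var else "welch_t",
            statistic=float(res.statistic),
            df=df,
            p_value=float(res.pvalue),
            null_value=0.0,
            n=int(x.size + y.size),
        )
    if method == "mannwhitney":
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        return TestResult(
            test_name="mann_whitney",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            null_value=0.0,
            n=int(x.size + y.size),
        )
    raise ConfigurationError(f"unknown method {method!r}")


def kruskal_wallis(groups: Mapping[str, Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H across labelled groups, tie-corrected, chi-square p.

    A completely tied dataset (every value identical) carries no rank
    information; it is reported as H = 0, p = 1 rather than an error.
    """
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrays) < 2:
        raise InsufficientDataError(f"Kruskal-Wallis needs >= 2 groups, got {len(arrays)}")
    if any(a.size < 1 for a in arrays):
        raise InsufficientDataError("every group needs >= 1 value")
    k = len(arrays)
    n_total = int(sum(a.size for a in arrays))
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return TestResult(
            test_name="kruskal_wallis", statistic=0.0, df=float(k - 1),
            p_value=1.0, null_value=0.0, n=n_total,
        )
    h, p = stats.kruskal(*arrays)
    return TestResult(
        test_name="kruskal_wallis", statistic=float(h), df=float(k - 1),
        p_value=float(p), null_value=0.0, n=n_total,
    )


def holm_adjust(p_values: Sequence[float], method: str = "holm") -> list[float]:
    """Step-down Bonferroni (Holm) adjusted p-values; ``method="bonferroni"``
    gives the single-step correction instead."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    if method not in ("holm", "bonferroni"):
        raise ConfigurationError(f"unknown correction {method!r}")
    _, adjusted, _, _ = multipletests(p, method=method)
    return [float(q) for q in adjusted]
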