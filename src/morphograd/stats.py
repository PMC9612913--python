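"""Two-sample statistics for comparing embryo measurements across conditions.

A toolkit for comparing a condition group against a
reference (wild-type) group: equal- and unequal-variance two-tailed t tests,
a two-tailed variance-ratio F test, the Shapiro-Wilk normality test, the
Wilcoxon rank-sum test with midranks and tie-corrected normal approximation,
and Hedges-bias-corrected Cohen's d.

Sign convention for the effect size: d is computed as condition minus
reference, so a condition that lowers the measured quantity yields d < 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "TwoGroupData",
    "TestResult",
    "EffectSizeResult",
    "t_test",
    "f_test_variance",
    "shapiro_wilk",
    "wilcoxon_rank_sum",
    "cohens_d_hedges",
]


@dataclass(frozen=True)
class TwoGroupData:
    """Reference (wild-type) vs condition (treatment) measurement samples."""

    reference_values: np.ndarray
    condition_values: np.ndarray
    reference_label: str = "reference"
    condition_label: str = "condition"

    def __post_init__(self) -> None:
        r = np.asarray(self.reference_values, dtype=float)
        c = np.asarray(self.condition_values, dtype=float)
        object.__setattr__(self, "reference_values", r)
        object.__setattr__(self, "condition_values", c)
        if not (np.all(np.isfinite(r)) and np.all(np.isfinite(c))):
            raise ValueError("values must be finite")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    df: float = float("nan")
    degenerate: bool = False


@dataclass(frozen=True)
class EffectSizeResult:
    """Hedges-corrected Cohen's d plus the companion test's p-value."""

    d: float
    p_value: float
    test_used: str


def _require_n(data: TwoGroupData, n_min: int = 2) -> tuple[np.ndarray, np.ndarray]:
    r, c = data.reference_values, data.condition_values
    if len(r) < n_min or len(c) < n_min:
        raise ValueError(f"each group needs n >= {n_min}")
    return r, c


def t_test(data: TwoGroupData, equal_variance: bool = True) -> TestResult:
    """Two-tailed two-sample t test.

    ``equal_variance=True``: pooled-variance Student's t with
    df = n1 + n2 - 2; otherwise Welch's t with Satterthwaite df.
    """
    r, c = _require_n(data)
    if np.var(r, ddof=1) == 0 and np.var(c, ddof=1) == 0:
        if r.mean() == c.mean():
            return TestResult(statistic=0.0, p_value=1.0, df=len(r) + len(c) - 2)
        return TestResult(
            statistic=float("inf"), p_value=0.0, df=len(r) + len(c) - 2, degenerate=True
        )
    res = sps.ttest_ind(c, r, equal_var=equal_variance)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue), df=float(res.df))


def f_test_variance(data: TwoGroupData) -> TestResult:
    """Two-tailed variance-ratio F test (as in R's var.test).

    F = s_condition^2 / s_reference^2 with (n_c - 1, n_r - 1) degrees of
    freedom; the two-tailed p doubles the smaller tail.
    """
    r, c = _require_n(data)
    s2r = float(np.var(r, ddof=1))
    s2c = float(np.var(c, ddof=1))
    if s2r == 0:
        raise ValueError("zero variance in denominator (reference) group")
    F = s2c / s2r
    d1, d2 = len(c) - 1, len(r) - 1
    cdf = sps.f.cdf(F, d1, d2)
    p = float(min(1.0, 2.0 * min(cdf, 1.0 - cdf)))
    return TestResult(statistic=F, p_value=p, df=float(d1))


def shapiro_wilk(values: np.ndarray) -> TestResult:
    """Shapiro-Wilk normality test (Royston's algorithm)."""
    v = np.asarray(values, dtype=float)
    if not 3 <= len(v) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(v) == 0:
        raise ValueError("constant input")
    res = sps.shapiro(v)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue))


def wilcoxon_rank_sum(data: TwoGroupData, continuity: bool = True) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test, tie-corrected normal approximation.

    Ties receive midranks; the null variance carries the tie correction

        var(W) = n1 n2 / 12 * [(N + 1) - sum(t^3 - t) / (N (N - 1))]

    and the two-tailed p uses a continuity-corrected normal approximation —
    appropriate when ties make the exact distribution unavailable.  The
    statistic returned is the rank sum W of the condition group.
    """
    r, c = data.reference_values, data.condition_values
    if len(r) == 0 or len(c) == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(c), len(r)
    pooled = np.concatenate([c, r])
    ranks = sps.rankdata(pooled)  # midranks for ties
    W = float(ranks[:n1].sum())
    N = n1 + n2
    mu = n1 * (N + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var == 0:
        return TestResult(statistic=W, p_value=1.0, degenerate=True)
    diff = W - mu
    cc = 0.5 if continuity else 0.0
    z = (abs(diff) - cc) / np.sqrt(var)
    z = max(z, 0.0)
    p = float(min(1.0, 2.0 * sps.norm.sf(z)))
    return TestResult(statistic=W, p_value=p)


def _hedges_j(n_total: int, exact: bool = False) -> float:
    """Small-sample bias correction J.

    Default is the 1 - 3/(4 N - 9) approximation used by common effect-size
    calculators; ``exact=True`` uses the gamma-function form with
    df = N - 2.
    """
    if exact:
        df = n_total - 2
        from scipy.special import gammaln

        return float(
            np.exp(gammaln(df / 2) - np.log(np.sqrt(df / 2)) - gammaln((df - 1) / 2))
        )
    return 1.0 - 3.0 / (4.0 * n_total - 9.0)


def cohens_d_hedges(
    data: TwoGroupData, equal_variance: bool = True, exact_correction: bool = False
) -> EffectSizeResult:
    """Hedges-bias-corrected Cohen's d with its companion t-test p-value.

    d_raw = (mean_condition - mean_reference) / s_pooled, multiplied by
    J = 1 - 3 / (4 (n1 + n2) - 9).  Swapping the groups flips the sign.
    """
    r, c = _require_n(data)
    n1, n2 = len(c), len(r)
    s_pooled = np.sqrt(
        ((n1 - 1) * np.var(c, ddof=1) + (n2 - 1) * np.var(r, ddof=1)) / (n1 + n2 - 2)
    )
    if s_pooled == 0:
        raise ValueError("zero pooled standard deviation")
    d_raw = (c.mean() - r.mean()) / s_pooled
    d = _hedges_j(n1 + n2, exact=exact_correction) * d_raw
    t_res = t_test(data, equal_variance=equal_variance)
    test_used = "t_equal_var" if equal_variance else "t_welch"
    return EffectSizeResult(d=float(d), p_value=t_res.p_value, test_used=test_used)
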