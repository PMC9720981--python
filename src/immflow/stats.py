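"""Group-comparison machinery: normality screening, t tests, one-way ANOVA
with Bonferroni post hoc contrasts, and univariate OLS regressions.

Conventions: all tests are two-sided with alpha = 0.05.  The normality screen
is a Lilliefors-style Kolmogorov-Smirnov test (normal parameters estimated
from the sample).  The two-group default is the ordinary pooled-variance
Student t test; Welch is available for unequal variances.  Bonferroni
adjustment is ``min(1, m * p)`` over the m requested contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "ALPHA",
    "ComparisonResult",
    "RegressionResult",
    "DegenerateDataError",
    "normality_check",
    "two_group_test",
    "two_group_test_from_summary",
    "anova_bonferroni",
    "univariate_regression",
    "sepsis_percent",
]

ALPHA = 0.05


class DegenerateDataError(ValueError):
    """Input on which the requested statistic is undefined."""


@dataclass(frozen=True)
class ComparisonResult:
    groups: tuple[str, ...]
    ns: tuple[int, ...]
    statistic_name: str  # "t" or "F"
    statistic: float
    p_value: float
    method: str
    adjusted_p: float | None = None


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    p_value: float
    n: int


def normality_check(values, alpha: float = ALPHA) -> tuple[float, float, bool]:
    """Lilliefors KS test against a normal with estimated mean/SD.

    Returns ``(statistic, p_value, normal_flag)`` with ``normal_flag = (p >
    alpha)``, i.e. True when normality is *not* rejected.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError(f"need n >= 4 for the normality screen, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateDataError("constant input: normality test undefined")
    stat, p = lilliefors(x, dist="norm", pvalmethod="table")
    return float(stat), float(p), bool(p > alpha)


def two_group_test(
    a, b, variant: str = "student", labels: tuple[str, str] = ("a", "b")
) -> ComparisonResult:
    """Two-sided two-sample t test (pooled-variance Student or Welch)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        raise DegenerateDataError("zero variance in both groups with equal means")
    if variant not in ("student", "welch"):
        raise ValueError(f"variant must be 'student' or 'welch', got {variant!r}")
    t, p = sps.ttest_ind(a, b, equal_var=(variant == "student"))
    return ComparisonResult(
        groups=labels, ns=(a.size, b.size), statistic_name="t",
        statistic=float(t), p_value=float(p), method=f"t_test_{variant}",
    )


def two_group_test_from_summary(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    variant: str = "student", labels: tuple[str, str] = ("a", "b"),
) -> ComparisonResult:
    """t test from printed summary statistics (mean, SD, n per group)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    t, p = sps.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=(variant == "student")
    )
    return ComparisonResult(
        groups=labels, ns=(n1, n2), statistic_name="t",
        statistic=float(t), p_value=float(p), method=f"t_test_{variant}_summary",
    )


def anova_bonferroni(
    groups: dict[str, np.ndarray],
    contrasts: list[tuple[str, str]] | None = None,
) -> tuple[ComparisonResult, list[ComparisonResult]]:
    """One-way ANOVA omnibus F plus Bonferroni-adjusted pairwise t tests.

    ``contrasts`` lists the requested group pairs (default: every pair);
    each pairwise p is adjusted as ``min(1, m * p)`` for m contrasts.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {name!r} has n = {arr.size} < 2")
    names = list(arrays)
    f, p = sps.f_oneway(*arrays.values())
    omnibus = ComparisonResult(
        groups=tuple(names), ns=tuple(arrays[k].size for k in names),
        statistic_name="F", statistic=float(f), p_value=float(p),
        method="anova_oneway",
    )
    if contrasts is None:
        contrasts = [
            (names[i], names[j])
            for i in range(len(names)) for j in range(i + 1, len(names))
        ]
    m = len(contrasts)
    results = []
    for g1, g2 in contrasts:
        if g1 not in arrays or g2 not in arrays:
            raise KeyError(f"contrast ({g1}, {g2}) names an unknown group")
        r = two_group_test(arrays[g1], arrays[g2], variant="student", labels=(g1, g2))
        results.append(
            ComparisonResult(
                groups=r.groups, ns=r.ns, statistic_name="t",
                statistic=r.statistic, p_value=r.p_value,
                adjusted_p=min(1.0, m * r.p_value), method="anova_bonferroni",
            )
        )
    return omnibus, results


def univariate_regression(x, y) -> RegressionResult:
    """Ordinary least squares of y on x; p from the F test of the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y lengths differ")
    n = x.size
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    if np.ptp(x) == 0:
        raise DegenerateDataError("constant predictor: regression undefined")
    fit = sps.linregress(x, y)
    r2 = float(fit.rvalue ** 2)
    if r2 >= 1.0:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = r2 / (1.0 - r2) * (n - 2)
        p = float(fit.pvalue)
    return RegressionResult(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=r2, f_statistic=float(f_stat), p_value=p, n=n,
    )


def sepsis_percent(n_sepsis: int, n_recruited: int, decimals: int = 1) -> float:
    """Percentage of recruited patients with at least one septic episode."""
    if n_recruited <= 0 or not (0 <= n_sepsis <= n_recruited):
        raise ValueError(f"invalid counts: {n_sepsis}/{n_recruited}")
    return round(100.0 * n_sepsis / n_recruited, decimals)
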