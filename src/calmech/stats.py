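"""Group summaries and two-group comparisons for the functional metrics.

Mirrors the reporting style of the imaging analysis: values as mean +/- SD
with n, SEM alongside, D'Agostino-Pearson omnibus normality check before a
two-sided Student t-test, and significance stars at the conventional
0.05 / 0.01 / 0.001 levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "summarize_group",
    "test_normality",
    "normality_test",
    "compare_groups",
    "significance_stars",
]

#: Minimum sample size for the D'Agostino-Pearson test (kurtosis z-score
#: validity limit).
NORMALITY_MIN_N = 20


@dataclass
class GroupSummary:
    n: int
    mean: float
    sd: float                   # n-1 denominator; 0 and flagged when n == 1
    sem: float
    median: float
    q25: float
    q75: float
    sd_defined: bool = True


@dataclass
class ComparisonResult:
    test_name: str
    statistic: float
    p_value: float
    stars: str
    normality_p: tuple[float | None, float | None] = (None, None)

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


def summarize_group(values) -> GroupSummary:
    """Sample mean, SD (ddof=1), SEM and linear-interpolation quartiles."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty group")
    sd_defined = x.size > 1
    sd = float(x.std(ddof=1)) if sd_defined else 0.0
    q25, med, q75 = np.percentile(x, [25, 50, 75])
    return GroupSummary(
        n=int(x.size), mean=float(x.mean()), sd=sd,
        sem=sd / np.sqrt(x.size) if sd_defined else 0.0,
        median=float(med), q25=float(q25), q75=float(q75),
        sd_defined=sd_defined,
    )


def test_normality(values) -> tuple[float, float]:
    """D'Agostino-Pearson K^2 omnibus test (skewness + kurtosis z-scores).

    Returns ``(K2, p)`` with p from a chi-square with 2 df.  Requires
    n >= 20 for the asymptotic z-scores to be valid.
    """
    x = np.asarray(values, dtype=float)
    if x.size < NORMALITY_MIN_N:
        raise ValueError(
            f"D'Agostino-Pearson test needs n >= {NORMALITY_MIN_N} "
            f"(got n = {x.size})"
        )
    if x.std() == 0:
        raise ValueError("zero-variance sample: normality test undefined")
    stat, p = sps.normaltest(x)
    return float(stat), float(p)


#: Alias that avoids pytest collecting the operation as a test when it is
#: imported into a test module.
normality_test = test_normality


def significance_stars(p: float) -> str:
    """Conventional star string: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups(a, b, welch: bool = False,
                   check_normality: bool = True) -> ComparisonResult:
    """Two-sided two-sample t-test (pooled-variance Student by default).

    Zero pooled variance with equal means returns t = 0, p = 1 by
    convention.  Normality p-values are attached per group when the sample
    sizes permit the omnibus test.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both groups need n >= 2")
    norm_p: list[float | None] = [None, None]
    if check_normality:
        for i, g in enumerate((x, y)):
            if g.size >= NORMALITY_MIN_N and g.std() > 0:
                norm_p[i] = test_normality(g)[1]
    if x.std() == 0 and y.std() == 0:
        if x.mean() == y.mean():
            t, p = 0.0, 1.0
        else:
            t, p = np.inf if x.mean() > y.mean() else -np.inf, 0.0
    else:
        t, p = sps.ttest_ind(x, y, equal_var=not welch)
    name = "Welch t-test" if welch else "Student t-test"
    return ComparisonResult(
        test_name=name, statistic=float(t), p_value=float(p),
        stars=significance_stars(float(p)),
        normality_p=(norm_p[0], norm_p[1]),
    )
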