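"""Group-level statistics for condition comparisons.

Independent two-sample t-tests (pooled-variance Student by default, Welch
available) computable either from raw per-run samples or from published
summary statistics (mean, SD, n); Bonferroni adjustment; and type-II
factorial ANOVA for two or three crossed factors via OLS model comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "TTestResult",
    "ttest_pooled",
    "ttest_from_samples",
    "bonferroni",
    "anova_type2",
]


@dataclass(frozen=True)
class GroupSummary:
    """Mean, sample SD (ddof=1) and size of one group of runs."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise ValueError("n must be >= 2")

    @classmethod
    def from_samples(cls, x: np.ndarray) -> "GroupSummary":
        x = np.asarray(x, dtype=float)
        return cls(mean=float(x.mean()), sd=float(x.std(ddof=1)), n=x.size)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    infinite: bool = False  # both SDs zero but means differ


def ttest_pooled(a: GroupSummary, b: GroupSummary, welch: bool = False) -> TTestResult:
    """Independent two-sample t-test from group summaries.

    Pooled (Student) variant: s_p^2 = ((n_a-1)s_a^2 + (n_b-1)s_b^2) /
    (n_a+n_b-2), t = (m_a - m_b) / (s_p sqrt(1/n_a + 1/n_b)),
    df = n_a + n_b - 2.  Welch variant uses per-group variances with
    Satterthwaite df.  Two-sided p.
    """
    if a.n + b.n < 3:
        raise ValueError("need n_a + n_b >= 3")
    diff = a.mean - b.mean
    if a.sd == 0 and b.sd == 0:
        if diff == 0:
            return TTestResult(t=0.0, df=a.n + b.n - 2, p=1.0)
        return TTestResult(t=math.inf if diff > 0 else -math.inf,
                           df=a.n + b.n - 2, p=0.0, infinite=True)
    va, vb = a.sd**2, b.sd**2
    if welch:
        sea, seb = va / a.n, vb / b.n
        se = math.sqrt(sea + seb)
        df = (sea + seb) ** 2 / (sea**2 / (a.n - 1) + seb**2 / (b.n - 1))
    else:
        df = a.n + b.n - 2
        sp2 = ((a.n - 1) * va + (b.n - 1) * vb) / df
        se = math.sqrt(sp2 * (1 / a.n + 1 / b.n))
    t = diff / se
    p = 2 * sps.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=float(df), p=float(p))


def ttest_from_samples(x: np.ndarray, y: np.ndarray, welch: bool = False) -> TTestResult:
    """Same test computed from raw per-run metric vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    return ttest_pooled(GroupSummary.from_samples(x), GroupSummary.from_samples(y), welch=welch)


def bonferroni(p_values: np.ndarray, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values: min(1, p * m).

    ``m`` defaults to the family size = number of p-values supplied."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("family size m must be >= number of p-values")
    return np.minimum(1.0, p * m)


def anova_type2(
    table: pd.DataFrame,
    response: str,
    factors: list[str],
    interactions: bool = True,
) -> pd.DataFrame:
    """Type-II factorial ANOVA on a tidy long table.

    Fits an OLS model with sum-to-zero coded categorical factors (all
    interactions up to the full order when ``interactions``) and returns the
    type-II table: each term is tested against the model containing every
    term that does not involve it, respecting marginality.  Aliased /
    rank-deficient terms come back with NaN F and p rather than an error,
    mirroring how confounded designs are usually reported.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    if len(factors) < 2 or len(factors) > 3:
        raise ValueError("anova_type2 supports 2 or 3 factors")
    for f in [response, *factors]:
        if f not in table.columns:
            raise ValueError(f"column {f!r} missing from table")
    for f in factors:
        if table[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs at least 2 levels")
    terms = [f"C({f}, Sum)" for f in factors]
    if interactions:
        formula = f"{response} ~ {'*'.join(terms)}"
    else:
        formula = f"{response} ~ {'+'.join(terms)}"
    model = ols(formula, data=table).fit()
    if model.df_resid < 1:
        raise ValueError("residual degrees of freedom < 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        aov = sm.stats.anova_lm(model, typ=2)
    aov = aov.rename(
        columns={"sum_sq": "sum_sq", "df": "df", "F": "F", "PR(>F)": "p"}
    )
    aov.index = [i.replace(", Sum)", ")") for i in aov.index]
    return aov
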