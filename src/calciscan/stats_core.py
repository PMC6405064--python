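"""Statistical kernels: paired t, normality tests, one-way ANOVA,
Kruskal-Wallis, Tukey HSD, and OLS with mean-response confidence bands.

Every test returns a :class:`TestResult` carrying the statistic, degrees
of freedom, two-sided p-value and sample sizes, serializable to JSON.
All tests are two-sided at alpha = 0.05 unless stated otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from calciscan.errors import ValidationError

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    df: float | tuple[float, ...]
    p_value: float
    n: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValidationError(f"p_value out of [0,1]: {self.p_value}")

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA

    def to_dict(self) -> dict:
        df = self.df if np.isscalar(self.df) else list(self.df)
        return {"test": self.test_name, "statistic": self.statistic,
                "df": df, "p_value": self.p_value, "n": list(self.n)}


@dataclass(frozen=True)
class PairwiseResult:
    """One Tukey-HSD pairwise comparison at family alpha = 0.05."""

    group_a: str
    group_b: str
    statistic: float
    p_value: float
    significant: bool

    def to_dict(self) -> dict:
        return {"pair": [self.group_a, self.group_b],
                "statistic": self.statistic, "p_value": self.p_value,
                "significant": self.significant}


def _asarray1d(x, name: str = "sample") -> np.ndarray:
    a = np.asarray(x, dtype=np.float64).ravel()
    if not np.all(np.isfinite(a)):
        raise ValidationError(f"{name} contains non-finite values")
    return a


def paired_t_test(x, y) -> TestResult:
    """Two-sided Student t on per-pair differences, df = n - 1."""
    x, y = _asarray1d(x, "x"), _asarray1d(y, "y")
    if x.size != y.size:
        raise ValidationError(f"paired samples differ in length: {x.size} vs {y.size}")
    if x.size < 2:
        raise ValidationError("need at least 2 pairs")
    d = x - y
    n = d.size
    if np.ptp(d) == 0:  # zero-variance differences: t undefined
        if d[0] == 0:
            return TestResult("paired_t", 0.0, n - 1, 1.0, (n, n))
        logger.warning("paired_t: identical nonzero differences; reporting p=0")
        return TestResult("paired_t", math.inf if d[0] > 0 else -math.inf,
                          n - 1, 0.0, (n, n))
    t, p = sps.ttest_rel(x, y)
    return TestResult("paired_t", float(t), n - 1, float(p), (n, n))


def shapiro_wilk(x) -> TestResult:
    """Shapiro-Wilk normality test (Royston approximation via scipy)."""
    x = _asarray1d(x)
    if x.size < 3:
        raise ValidationError("Shapiro-Wilk needs n >= 3")
    if np.ptp(x) == 0:
        raise ValidationError("constant sample")
    w, p = sps.shapiro(x)
    return TestResult("shapiro_wilk", float(w), x.size - 1, float(p), (x.size,))


def ks_normality(x) -> TestResult:
    """Lilliefors-corrected Kolmogorov-Smirnov test against a normal with
    sample-estimated moments (table/approximation p-values)."""
    from statsmodels.stats.diagnostic import lilliefors

    x = _asarray1d(x)
    if x.size < 5:
        raise ValidationError("KS normality needs n >= 5")
    if np.ptp(x) == 0:
        raise ValidationError("constant sample")
    d, p = lilliefors(x, dist="norm")
    return TestResult("ks_lilliefors", float(d), float(x.size),
                      float(min(max(p, 0.0), 1.0)), (x.size,))


def _check_groups(groups, min_n: int) -> list[np.ndarray]:
    gs = [_asarray1d(g, f"group {i}") for i, g in enumerate(groups)]
    if len(gs) < 2:
        raise ValidationError("need at least 2 groups")
    for i, g in enumerate(gs):
        if g.size < min_n:
            raise ValidationError(f"group {i} has n={g.size} < {min_n}")
    return gs


def anova_oneway(groups) -> TestResult:
    """Classical one-way ANOVA: F = MS_between / MS_within."""
    gs = _check_groups(groups, 2)
    k, ns = len(gs), tuple(g.size for g in gs)
    big_n = sum(ns)
    pooled = np.concatenate(gs)
    if np.ptp(pooled) == 0:  # all observations identical
        return TestResult("anova_oneway", 0.0, (k - 1, big_n - k), 1.0, ns)
    grand = pooled.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df1, df2 = k - 1, big_n - k
    if ss_within == 0:
        return TestResult("anova_oneway", math.inf, (df1, df2), 0.0, ns)
    f = (ss_between / df1) / (ss_within / df2)
    p = float(sps.f.sf(f, df1, df2))
    return TestResult("anova_oneway", float(f), (df1, df2), p, ns)


def kruskal_wallis(groups) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with chi-square (k-1) p-value."""
    gs = _check_groups(groups, 1)
    if sum(g.size for g in gs) < 5:
        raise ValidationError("Kruskal-Wallis needs total N >= 5")
    ns = tuple(g.size for g in gs)
    if np.ptp(np.concatenate(gs)) == 0:
        return TestResult("kruskal_wallis", 0.0, len(gs) - 1, 1.0, ns)
    h, p = sps.kruskal(*gs)
    return TestResult("kruskal_wallis", float(h), len(gs) - 1, float(p), ns)


def tukey_hsd(groups, labels=None) -> list[PairwiseResult]:
    """Studentized-range pairwise comparisons at family alpha = 0.05."""
    gs = _check_groups(groups, 2)
    labels = labels or [str(i) for i in range(len(gs))]
    if len(labels) != len(gs):
        raise ValidationError("labels/groups length mismatch")
    if np.ptp(np.concatenate(gs)) == 0:
        return [PairwiseResult(labels[i], labels[j], 0.0, 1.0, False)
                for i in range(len(gs)) for j in range(i + 1, len(gs))]
    res = sps.tukey_hsd(*gs)
    out = []
    for i in range(len(gs)):
        for j in range(i + 1, len(gs)):
            p = float(res.pvalue[i, j])
            out.append(PairwiseResult(labels[i], labels[j],
                                      float(res.statistic[i, j]), p, p < ALPHA))
    return out


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of y on x with a 95% mean-response confidence band."""

    slope: float
    intercept: float
    r_squared: float
    n: int
    residual_sd: float
    x_mean: float
    sxx: float

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=np.float64)

    def ci_band(self, x, level: float = 0.95):
        """Lower/upper bounds for the mean response at each x."""
        x = np.asarray(x, dtype=np.float64)
        tcrit = sps.t.ppf(0.5 + level / 2, self.n - 2)
        se = self.residual_sd * np.sqrt(1.0 / self.n +
                                        (x - self.x_mean) ** 2 / self.sxx)
        yhat = self.predict(x)
        return yhat - tcrit * se, yhat + tcrit * se

    def to_dict(self) -> dict:
        return {"slope": self.slope, "intercept": self.intercept,
                "r_squared": self.r_squared, "n": self.n}


def ols(x, y) -> RegressionResult:
    """Simple least squares with closed-form slope/intercept/R^2."""
    x, y = _asarray1d(x, "x"), _asarray1d(y, "y")
    if x.size != y.size:
        raise ValidationError("x and y differ in length")
    n = x.size
    if n < 3:
        raise ValidationError("OLS needs n >= 3")
    sxx = ((x - x.mean()) ** 2).sum()
    if sxx == 0:
        raise ValidationError("var(x) = 0")
    slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    ss_res = (resid ** 2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return RegressionResult(slope=float(slope), intercept=float(intercept),
                            r_squared=float(min(max(r2, 0.0), 1.0)), n=n,
                            residual_sd=float(np.sqrt(ss_res / (n - 2))),
                            x_mean=float(x.mean()), sxx=float(sxx))


def normality_gate(datasets, *, alpha: float = ALPHA) -> tuple[bool, list[dict]]:
    """Both KS (Lilliefors) and Shapiro-Wilk must pass for *every* dataset
    for the parametric branch to be taken.  Returns (all_normal, details)."""
    details = []
    all_normal = True
    for i, d in enumerate(datasets):
        sw = shapiro_wilk(d)
        ks = ks_normality(d)
        ok = sw.p_value > alpha and ks.p_value > alpha
        all_normal &= ok
        details.append({"dataset": i, "normal": ok,
                        "shapiro_wilk": sw.to_dict(), "ks": ks.to_dict()})
    return all_normal, details
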