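"""Structure-activity correlation statistics.

The graded endpoint (percent inhibition of Aβ42 self-aggregation) is
related to docking binding energy by a Pearson product-moment correlation,
with normality of the inputs checked by the D'Agostino-Pearson omnibus K²
test.  When the same endpoint is correlated with two different predictors
(e.g. binding energies of monomeric vs dimeric forms), the two dependent
correlations are compared with Steiger's (1980) z for overlapping
correlations sharing one variable.

p-values are carried at full precision; truncation such as "p < 0.0001"
belongs in report text, not in returned numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "SummaryStat",
    "pearson",
    "dagostino_pearson",
    "compare_dependent_r",
    "mean_sem",
]

#: Below this sample size the skewness/kurtosis z-approximations in the
#: omnibus normality test are unreliable.
NORMALITY_MIN_N = 20


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if not (-1.0 <= self.r <= 1.0):
            raise ValueError(f"|r| must be <= 1, got {self.r}")
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"p must lie in (0, 1], got {self.p}")
        if self.n < 3:
            raise ValueError("correlation needs n >= 3")


@dataclass(frozen=True)
class SummaryStat:
    """Mean ± SEM summary; sem is None when n = 1 (undefined, not zero)."""

    mean: float
    sem: float | None
    n: int


def pearson(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with its two-sided p-value.

    The p-value comes from the exact t-transform r√((n−2)/(1−r²)) with
    n − 2 degrees of freedom.  Requires n ≥ 3 and nonzero variance in both
    vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be equal-length vectors, got {x.shape} and {y.shape}")
    n = len(x)
    if n < 3:
        raise ValueError(f"need n >= 3 for a correlation, got n = {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y; correlation undefined")
    res = sps.pearsonr(x, y)
    p = float(res.pvalue)
    return CorrelationResult(r=float(res.statistic), p=min(max(p, np.finfo(float).tiny), 1.0), n=n)


def dagostino_pearson(x) -> tuple[float, float]:
    """D'Agostino-Pearson omnibus normality test.

    K² = Z²_skew + Z²_kurt using D'Agostino's z-approximations for sample
    skewness and kurtosis, referred to a χ² distribution with 2 degrees of
    freedom.  Returns (K², p).  Refuses n < 20, where the approximations
    degrade.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("input must be a 1-d vector")
    if len(x) < NORMALITY_MIN_N:
        raise ValueError(
            f"the omnibus normality test needs n >= {NORMALITY_MIN_N}, got n = {len(x)}"
        )
    k2, p = sps.normaltest(x)
    return float(k2), float(p)


def compare_dependent_r(r1: float, r2: float, r12: float, n: int) -> tuple[float, float]:
    """Steiger's z-test for two dependent correlations sharing one variable.

    Compares r1 = corr(X1, Y) against r2 = corr(X2, Y) measured on the same
    n cases, where ``r12`` = corr(X1, X2) captures the dependence.  Uses
    Steiger's (1980) modification of the Dunn–Clark z with the mean
    correlation plugged into the covariance term.  Returns (z, two-sided p);
    swapping r1 and r2 negates z and leaves p unchanged.
    """
    for name, r in (("r1", r1), ("r2", r2), ("r12", r12)):
        if not (-1.0 < r < 1.0):
            raise ValueError(f"{name} must lie strictly within (-1, 1), got {r}")
    if n < 4:
        raise ValueError(f"need n >= 4, got {n}")
    z1 = math.atanh(r1)
    z2 = math.atanh(r2)
    rm2 = (r1 * r1 + r2 * r2) / 2.0
    f = min((1.0 - r12) / (2.0 * (1.0 - rm2)), 1.0)
    h = (1.0 - f * rm2) / (1.0 - rm2)
    z = (z1 - z2) * math.sqrt((n - 3) / (2.0 * (1.0 - r12) * h))
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def mean_sem(values) -> SummaryStat:
    """Arithmetic mean and standard error of the mean (sample sd / √n)."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) == 0:
        raise ValueError("need a non-empty 1-d vector")
    n = len(values)
    mean = float(values.mean())
    if n == 1:
        return SummaryStat(mean=mean, sem=None, n=1)
    sem = float(values.std(ddof=1) / math.sqrt(n))
    return SummaryStat(mean=mean, sem=sem, n=n)
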