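"""Small statistical kernel shared by the analysis stages.

Everything here is a closed form: the pooled-variance two-sample t test,
ordinary least squares for a single predictor, the Pearson product-moment
correlation, and the sample mean/SD. Downstream modules import from here so
there is exactly one definition of each statistic in the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "TTestResult",
    "two_sample_ttest_equal_var",
    "linear_fit",
    "pearson_r",
    "mean_sd",
]


@dataclass(frozen=True)
class TTestResult:
    """Pooled-variance two-sample t test outcome.

    Attributes
    ----------
    t_statistic : float
        Signed t statistic (positive when ``mean(a) > mean(b)``).
    degrees_of_freedom : int
        ``n1 + n2 - 2``.
    p_two_tail : float
        Two-tailed p value from the central t distribution.
    """

    t_statistic: float
    degrees_of_freedom: int
    p_two_tail: float


def _t_sf_two_tail(t: float, df: int) -> float:
    # 2*P(|T| >= t) via the regularized incomplete beta function:
    # P(|T| >= t) = I_{df/(df+t^2)}(df/2, 1/2) / 2
    if df <= 0:
        raise ValueError("degrees of freedom must be positive")
    x = df / (df + t * t)
    return float(special.betainc(df / 2.0, 0.5, x))


def two_sample_ttest_equal_var(a, b) -> TTestResult:
    """Two-sample t test assuming equal variances, two-tailed.

    Parameters
    ----------
    a, b : array-like
        Numeric samples with at least two observations each.

    Raises
    ------
    ValueError
        If either sample has fewer than two points or the pooled variance
        is zero (degenerate samples).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least 2 observations")
    df = n1 + n2 - 2
    v1 = a.var(ddof=1)
    v2 = b.var(ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    if sp2 <= 0:
        # identical constant samples: no evidence of difference
        if math.isclose(a.mean(), b.mean()):
            return TTestResult(0.0, df, 1.0)
        raise ValueError("pooled variance is zero with unequal means")
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return TTestResult(float(t), df, _t_sf_two_tail(t, df))


def linear_fit(x, y) -> tuple[float, float]:
    """Ordinary least squares ``y = slope * x + intercept``.

    Closed-form normal equations for the single-predictor case. ``x`` must
    contain at least two distinct values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise ValueError("at least 2 points required")
    xm = x.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0.0:
        raise ValueError("x values are constant; slope undefined")
    slope = float(((x - xm) * (y - y.mean())).sum() / sxx)
    intercept = float(y.mean() - slope * xm)
    return slope, intercept


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation coefficient.

    Returns ``nan`` when either vector has zero variance (the correlation
    is then undefined and callers report the value as missing).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("at least 3 points required")
    dx = x - x.mean()
    dy = y - y.mean()
    denom = math.sqrt(float((dx * dx).sum()) * float((dy * dy).sum()))
    if denom == 0.0:
        return float("nan")
    r = float((dx * dy).sum() / denom)
    return max(-1.0, min(1.0, r))


def mean_sd(x) -> tuple[float, float]:
    """Arithmetic mean and sample (n-1) standard deviation.

    With a single observation the SD is returned as ``nan``.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    m = float(x.mean())
    sd = float(x.std(ddof=1)) if x.size >= 2 else float("nan")
    return m, sd
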