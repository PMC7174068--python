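"""Method-comparison statistics: Deming regression, Pearson correlation,
Bland-Altman agreement, and the all-pairs comparison matrix.

Deming regression is the appropriate line fit when *both* TMB measurements
carry error (every method counts a finite, noisy number of variants), unlike
ordinary least squares which attenuates the slope.  With error-variance
ratio lambda = var_y/var_x and (n-1)-denominator sample moments s_xx, s_yy,
s_xy, the slope has the closed form

    b = [s_yy - lambda*s_xx + sqrt((s_yy - lambda*s_xx)^2 + 4*lambda*s_xy^2)]
        / (2*s_xy)

and the intercept is ybar - b*xbar.  lambda defaults to 1 (orthogonal
regression); slope confidence intervals use a leave-one-out jackknife with
a normal approximation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "DemingFit",
    "BlandAltmanSummary",
    "DegenerateFitError",
    "deming_fit",
    "pearson",
    "bland_altman",
    "comparison_matrix",
]


class DegenerateFitError(ValueError):
    """Raised when a regression or correlation is undefined for the data."""


@dataclass(frozen=True)
class DemingFit:
    slope: float
    intercept: float
    lam: float
    pearson_r: float
    n: int
    slope_ci: tuple[float, float]
    ci_method: str = "jackknife-normal"


@dataclass(frozen=True)
class BlandAltmanSummary:
    """Agreement summary of differences d = y - x."""

    mean_bias: float
    loa_low: float
    loa_high: float
    n: int


def _deming_slope(x: np.ndarray, y: np.ndarray, lam: float) -> float:
    s_xx = np.var(x, ddof=1)
    s_yy = np.var(y, ddof=1)
    s_xy = np.cov(x, y, ddof=1)[0, 1]
    if s_xy == 0.0:
        raise DegenerateFitError("zero covariance: Deming fit is degenerate")
    d = s_yy - lam * s_xx
    return (d + np.sqrt(d * d + 4.0 * lam * s_xy * s_xy)) / (2.0 * s_xy)


def deming_fit(
    x: np.ndarray, y: np.ndarray, lam: float = 1.0, ci: bool = True
) -> DemingFit:
    """Errors-in-variables straight-line fit of y on x.

    Parameters
    ----------
    lam
        Ratio of error variances var_y / var_x; 1 gives orthogonal
        regression.
    ci
        Compute the 95% jackknife slope CI (skippable in hot loops).

    Raises
    ------
    DegenerateFitError
        If x is constant or the cross-covariance vanishes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if np.ptp(x) == 0:
        raise DegenerateFitError("x is constant")
    slope = _deming_slope(x, y, lam)
    intercept = float(np.mean(y) - slope * np.mean(x))
    r = pearson(x, y)

    slope_ci = (np.nan, np.nan)
    if ci:
        # Leave-one-out slopes from downdated sums; O(n) total.
        sx, sy = x.sum(), y.sum()
        sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
        m = n - 1
        mx = (sx - x) / m
        my = (sy - y) / m
        s_xx = (sxx - x * x - m * mx * mx) / (m - 1)
        s_yy = (syy - y * y - m * my * my) / (m - 1)
        s_xy = (sxy - x * y - m * mx * my) / (m - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = s_yy - lam * s_xx
            loo = (d + np.sqrt(d * d + 4.0 * lam * s_xy * s_xy)) / (2.0 * s_xy)
        loo = loo[np.isfinite(loo)]
        if len(loo) >= 2:
            se = np.sqrt((len(loo) - 1) / len(loo) * np.sum((loo - loo.mean()) ** 2))
            slope_ci = (slope - 1.959964 * se, slope + 1.959964 * se)
    return DemingFit(
        slope=float(slope),
        intercept=intercept,
        lam=float(lam),
        pearson_r=float(r),
        n=n,
        slope_ci=(float(slope_ci[0]), float(slope_ci[1])),
    )


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; errors on constant input rather than NaN."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateFitError("correlation undefined for constant input")
    return float(scipy.stats.pearsonr(x, y).statistic)


def bland_altman(x: np.ndarray, y: np.ndarray) -> BlandAltmanSummary:
    """Mean bias and 1.96-SD limits of agreement of d = y - x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 2:
        raise ValueError("need equal-length vectors of at least 2 points")
    d = y - x
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanSummary(
        mean_bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd, n=len(d)
    )


def comparison_matrix(tmb: pd.DataFrame, lam: float = 1.0, ci: bool = True) -> pd.DataFrame:
    """Deming fit and Pearson r for every ordered method pair.

    ``tmb`` is a samples x methods frame (e.g. ``TMBMatrix.tmb``).  The
    diagonal is the identity fit.  Per-pair failures (constant columns,
    zero covariance) are recorded in the ``error`` column instead of
    aborting the whole grid.

    Returns a tidy frame: x_method, y_method, n, slope, slope_ci_low,
    slope_ci_high, intercept, pearson_r, error.
    """
    methods = list(tmb.columns)
    if len(methods) < 2:
        raise ValueError("need at least 2 methods")
    rows = []
    for xm, ym in itertools.product(methods, methods):
        row: dict[str, object] = {"x_method": xm, "y_method": ym, "n": len(tmb)}
        if xm == ym:
            row.update(
                slope=1.0, slope_ci_low=1.0, slope_ci_high=1.0,
                intercept=0.0, pearson_r=1.0, error="",
            )
        else:
            try:
                fit = deming_fit(tmb[xm].to_numpy(), tmb[ym].to_numpy(), lam=lam, ci=ci)
                row.update(
                    slope=fit.slope,
                    slope_ci_low=fit.slope_ci[0],
                    slope_ci_high=fit.slope_ci[1],
                    intercept=fit.intercept,
                    pearson_r=fit.pearson_r,
                    error="",
                )
            except (DegenerateFitError, ValueError) as exc:
                row.update(
                    slope=np.nan, slope_ci_low=np.nan, slope_ci_high=np.nan,
                    intercept=np.nan, pearson_r=np.nan, error=str(exc),
                )
        rows.append(row)
    return pd.DataFrame(rows)
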