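"""Critical social density estimation from per-frame (violations, density) data.

The critical social density rho_c is the density below which the chance of
any social-distancing violation in the region of interest is pushed near
zero.  It is estimated by regressing the per-frame social density rho
(dependent variable, 1/m^2) on the per-frame violation count v
(independent variable) with ordinary least squares,

    rho = beta_0 + beta_1 * v + eps,    eps ~ Normal(0, sigma^2),

and taking the lower bound of the 95% prediction interval of rho at v = 0:

    rho_c = max(0, beta_0 - t_{n-2, (1+level)/2} * s * sqrt(1 + 1/n + v_bar^2 / S_vv)),

where s^2 = RSS / (n - 2) is the residual variance and S_vv the centered
sum of squares of v.  The trivial bound rho_c = 0 always suppresses
violations but is useless; the prediction-interval lower bound is the
largest density still statistically consistent with a violation-free frame.
A skewness diagnostic of the density sample supports the normality
assumption (a near-symmetric rho distribution).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "FitError",
    "RegressionFit",
    "CriticalDensityResult",
    "fit_density_violation_regression",
    "prediction_interval",
    "critical_density",
    "sample_skewness",
    "estimate_critical_density",
]


class FitError(ValueError):
    """The density-on-violations regression cannot be fitted."""


@dataclass(frozen=True)
class RegressionFit:
    """Ordinary-least-squares fit of density on violation count.

    Attributes
    ----------
    beta0 : float
        Intercept (1/m^2): the expected density of a violation-free frame.
    beta1 : float
        Slope (1/m^2 per violation).
    s : float
        Residual standard deviation, sqrt(RSS / (n_obs - 2)).
    n_obs : int
        Number of frames entering the fit.
    v_bar : float
        Mean violation count.
    s_vv : float
        Centered sum of squares of the violation counts.
    """

    beta0: float
    beta1: float
    s: float
    n_obs: int
    v_bar: float
    s_vv: float

    def predict(self, v_star: float) -> float:
        """Fitted mean density at a violation count."""
        return self.beta0 + self.beta1 * v_star


@dataclass(frozen=True)
class CriticalDensityResult:
    """Critical density with its defining prediction interval and diagnostics."""

    rho_c: float
    pi_lower: float
    pi_upper: float
    level: float
    fit: RegressionFit
    skewness_rho: float = math.nan


def fit_density_violation_regression(v, rho) -> RegressionFit:
    """Fit rho = beta0 + beta1 * v + eps by ordinary least squares.

    Parameters
    ----------
    v : array_like
        Per-frame violation counts (the regressor).
    rho : array_like
        Per-frame social densities, 1/m^2 (the response).

    Raises
    ------
    FitError
        Fewer than 3 finite observations, or zero variance in v.
    """
    v = np.asarray(v, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if v.shape != rho.shape or v.ndim != 1:
        raise FitError("v and rho must be matched 1-d arrays")
    keep = np.isfinite(v) & np.isfinite(rho)
    v, rho = v[keep], rho[keep]
    n = len(v)
    if n < 3:
        raise FitError(f"need at least 3 observations, got {n}")
    v_bar = v.mean()
    s_vv = float(np.sum((v - v_bar) ** 2))
    if s_vv <= 0.0:
        raise FitError("violation counts are constant: slope is unidentifiable")
    beta1 = float(np.sum((v - v_bar) * (rho - rho.mean())) / s_vv)
    beta0 = float(rho.mean() - beta1 * v_bar)
    rss = float(np.sum((rho - beta0 - beta1 * v) ** 2))
    # an exactly linear relation leaves only rounding noise in the residuals;
    # snap it to zero so the zero-noise limit collapses cleanly
    tss = float(np.sum((rho - rho.mean()) ** 2))
    if rss <= 1e-24 * max(tss, np.finfo(float).tiny):
        rss = 0.0
    s = math.sqrt(rss / (n - 2))
    return RegressionFit(beta0=beta0, beta1=beta1, s=s, n_obs=n,
                         v_bar=float(v_bar), s_vv=s_vv)


def prediction_interval(
    fit: RegressionFit, v_star: float = 0.0, level: float = 0.95
) -> tuple[float, float]:
    """Two-sided prediction interval for a single new density at ``v_star``.

    The interval is symmetric about the fitted mean,
    ``yhat +- t_{n-2,(1+level)/2} * s * sqrt(1 + 1/n + (v* - v_bar)^2/S_vv)``,
    and collapses to a point when the fit is exact (s = 0).
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    yhat = fit.predict(v_star)
    if fit.s == 0.0:
        return (yhat, yhat)
    t_crit = sps.t.ppf(0.5 * (1.0 + level), fit.n_obs - 2)
    half = t_crit * fit.s * math.sqrt(
        1.0 + 1.0 / fit.n_obs + (v_star - fit.v_bar) ** 2 / fit.s_vv
    )
    return (yhat - half, yhat + half)


def critical_density(
    fit: RegressionFit, level: float = 0.95, skewness_rho: float = math.nan
) -> CriticalDensityResult:
    """Critical density: lower prediction-interval bound at v = 0, clamped at 0.

    A negative density bound (possible for small samples or large residual
    spread) is clamped to zero, the physically meaningful floor.
    """
    lower, upper = prediction_interval(fit, v_star=0.0, level=level)
    return CriticalDensityResult(
        rho_c=max(0.0, lower),
        pi_lower=lower,
        pi_upper=upper,
        level=level,
        fit=fit,
        skewness_rho=skewness_rho,
    )


def sample_skewness(values) -> float:
    """Adjusted Fisher-Pearson sample skewness of a density series.

    A value near zero supports the normal-error assumption behind the
    prediction interval.

    Raises
    ------
    FitError
        Fewer than 3 values or a constant series (skewness undefined).
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 3:
        raise FitError("skewness needs at least 3 values")
    if np.ptp(x) == 0.0:
        raise FitError("skewness is undefined for a constant series")
    return float(sps.skew(x, bias=False))


def estimate_critical_density(v, rho, level: float = 0.95) -> CriticalDensityResult:
    """Convenience wrapper: fit the regression and derive rho_c in one call.

    All frames with a defined density enter the fit, including violation-free
    ones; the skewness diagnostic of rho is attached to the result.
    """
    fit = fit_density_violation_regression(v, rho)
    try:
        skew = sample_skewness(np.asarray(rho, dtype=float))
    except FitError:
        skew = math.nan
    return critical_density(fit, level=level, skewness_rho=skew)
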