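"""HC3 and HC4 heteroskedasticity-consistent covariance estimators.

Both are sandwich estimators

    cov = (X'X)^-1 X' diag[w_i] X (X'X)^-1

with per-case weights built from squared residuals and leverages:

    HC3: w_i = r_i^2 / (1 - h_ii)^2
    HC4: w_i = r_i^2 / (1 - h_ii)^delta_i,  delta_i = min(4, n*h_ii/p)

HC4 escalates the leverage discount for high-leverage cases (up to a fourth
power) and coincides with HC3 wherever delta_i = 2.  Test statistics built
from these SEs are referred to a t distribution with n - p degrees of
freedom, the same reference the classical test uses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ols_core import InferenceResult, OLSFit, t_inference

__all__ = ["SandwichCov", "hc_covariance", "hc_inference"]

_LEVERAGE_TOL = 1e-12


class ExactLeverageError(ValueError):
    """A leverage of 1 makes the HC weight undefined."""


@dataclass
class SandwichCov:
    estimator: str  # "HC3" or "HC4"
    cov: np.ndarray
    delta: np.ndarray | None = None  # HC4 exponents, None for HC3


def hc_covariance(fit: OLSFit, estimator: str = "HC3") -> SandwichCov:
    """Compute the HC3 or HC4 sandwich covariance of the OLS coefficients."""
    estimator = estimator.upper()
    if estimator not in ("HC3", "HC4"):
        raise ValueError(f"unsupported estimator {estimator!r}")
    h = fit.leverage
    if np.any(h > 1.0 - _LEVERAGE_TOL):
        raise ExactLeverageError(
            "a leverage value is (numerically) 1; the HC weight blows up"
        )
    r2 = fit.residuals**2
    delta = None
    if estimator == "HC3":
        w = r2 / (1.0 - h) ** 2
    else:
        delta = np.minimum(4.0, fit.n * h / fit.p)
        w = r2 / (1.0 - h) ** delta
    meat = (fit.X * w[:, None]).T @ fit.X
    cov = fit.xtx_inv @ meat @ fit.xtx_inv
    return SandwichCov(estimator=estimator, cov=cov, delta=delta)


def hc_inference(
    fit: OLSFit,
    cov: SandwichCov,
    k: int = 1,
    alpha: float = 0.05,
    beta_true: float | None = None,
) -> InferenceResult:
    """t test and CI for coefficient k using a sandwich SE, t(n-p) reference."""
    var_k = float(cov.cov[k, k])
    if var_k <= 0 or not np.isfinite(var_k):
        raise ValueError(f"non-positive sandwich variance {var_k!r} for k={k}")
    return t_inference(
        float(fit.beta_hat[k]),
        float(np.sqrt(var_k)),
        fit.df_resid,
        method=cov.estimator,
        coef_index=k,
        alpha=alpha,
        beta_true=beta_true,
    )
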