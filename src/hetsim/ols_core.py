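"""OLS estimation and classical t-based inference for a single sample."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["OLSFit", "InferenceResult", "fit_ols", "classical_inference"]


class SingularDesignError(np.linalg.LinAlgError):
    """X'X is numerically singular; the fit is undefined."""


class DegenerateFitError(RuntimeError):
    """Residual variance is zero; t-based inference is undefined."""


@dataclass
class OLSFit:
    """Least-squares fit: estimates, residuals, leverages and (X'X)^-1.

    (X'X)^-1 is materialized (not only an implicit factorization) because the
    classical and sandwich covariance formulas both consume it directly.
    """

    X: np.ndarray
    y: np.ndarray
    beta_hat: np.ndarray
    residuals: np.ndarray
    fitted: np.ndarray
    leverage: np.ndarray
    rss: float
    sigma2_hat: float
    xtx_inv: np.ndarray

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def df_resid(self) -> int:
        return self.n - self.p


@dataclass
class InferenceResult:
    """One method's decision record for one coefficient.

    ``se``, ``t_stat`` and ``p_value`` are None for methods that do not
    define them (e.g. bootstrap CIs); ``ci_low``/``ci_high`` are None for
    p-value-only methods.  ``reject`` is the alpha-level two-sided decision,
    ``covers`` whether the CI contains the true coefficient (None without a
    CI).  ``flagged`` marks degenerate corrections (e.g. clamped BCa bias).
    """

    method: str
    coef_index: int
    estimate: float
    se: float | None = None
    t_stat: float | None = None
    p_value: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    reject: bool = False
    covers: bool | None = None
    flagged: bool = False


def fit_ols(X: np.ndarray, y: np.ndarray) -> OLSFit:
    """Fit y = X beta by least squares via a QR decomposition.

    Leverages are row norms of Q; beta solves R beta = Q'y.  Raises
    SingularDesignError when the design is rank-deficient, so callers in the
    bootstrap path can decide between redrawing and aborting.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise SingularDesignError(f"need n > p (got n={n}, p={p})")
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    if diag.min() <= 1e-10 * max(diag.max(), 1.0):
        raise SingularDesignError("X'X is numerically singular")
    beta_hat = np.linalg.solve(R, Q.T @ y)
    fitted = X @ beta_hat
    residuals = y - fitted
    leverage = np.einsum("ij,ij->i", Q, Q)
    rss = float(residuals @ residuals)
    rinv = np.linalg.solve(R, np.eye(p))
    xtx_inv = rinv @ rinv.T
    return OLSFit(
        X=X,
        y=y,
        beta_hat=beta_hat,
        residuals=residuals,
        fitted=fitted,
        leverage=leverage,
        rss=rss,
        sigma2_hat=rss / (n - p),
        xtx_inv=xtx_inv,
    )


def t_inference(
    estimate: float,
    se: float,
    df: int,
    *,
    method: str,
    coef_index: int,
    alpha: float = 0.05,
    beta_true: float | None = None,
) -> InferenceResult:
    """Two-sided t test and symmetric CI given an estimate and its SE."""
    if se <= 0 or not np.isfinite(se):
        raise DegenerateFitError(f"standard error {se!r} is not positive")
    t = estimate / se
    p = 2.0 * stats.t.sf(abs(t), df)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    lo, hi = estimate - tcrit * se, estimate + tcrit * se
    return InferenceResult(
        method=method,
        coef_index=coef_index,
        estimate=estimate,
        se=se,
        t_stat=t,
        p_value=p,
        ci_low=lo,
        ci_high=hi,
        reject=bool(p < alpha),
        covers=None if beta_true is None else bool(lo <= beta_true <= hi),
    )


def classical_inference(
    fit: OLSFit,
    k: int = 1,
    alpha: float = 0.05,
    beta_true: float | None = None,
) -> InferenceResult:
    """Classical OLS inference: SE^2 = sigma2_hat * [(X'X)^-1]_kk, t(n-p) reference."""
    se = float(np.sqrt(fit.sigma2_hat * fit.xtx_inv[k, k]))
    return t_inference(
        float(fit.beta_hat[k]),
        se,
        fit.df_resid,
        method="classical",
        coef_index=k,
        alpha=alpha,
        beta_true=beta_true,
    )
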