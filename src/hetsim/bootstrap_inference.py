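"""Pairs and wild bootstrap engines and their three inference modes.

Resampling schemes
------------------
* **pairs** — whole cases ``(x_i, y_i)`` are drawn with replacement and the
  model refit on each resample; the design matrix varies across draws.
* **wild** — the design matrix is fixed at the original ``X`` and bootstrap
  outcomes are built from the fitted values plus sign-randomized transformed
  residuals:

      y*_i = X_i beta_hat + r_i / (1 - h_ii) * v*_i,

  with ``v*_i`` Rademacher (+1/-1 each with probability 0.5).  The
  ``1/(1 - h_ii)`` transform is the deleted-residual (HC3-style) flavour.

Inference modes on the B bootstrap coefficients
-----------------------------------------------
* **bootstrap p-value** — ``p = (#{t*_b^2 >= t^2} + 1) / (B + 1)`` where
  ``t*_b = (beta*_b - beta_hat) / SE*_b`` and ``t`` is the original
  classical test statistic.  By default ``SE*_b`` is the conventional OLS
  standard error computed *within* the b-th bootstrap sample (the
  studentized, bootstrap-t convention); a pooled variant that divides every
  draw by the one sample SD of the B bootstrap coefficients is available as
  ``denominator="pooled"``.
* **percentile CI** — order statistics of the bootstrap coefficients at
  2.5%/97.5%, read with the (B+1)q plotting-position (Weibull) interpolation
  by default; the dialect is swappable because different software interpolates
  differently (an O(1/B) effect).
* **BCa CI** — Efron's bias-corrected and accelerated interval: the bias
  term z0 comes from the fraction of bootstrap coefficients below the
  original estimate, the acceleration from the jackknife skewness of
  leave-one-out estimates, and the two corrected percentile levels are read
  from the same bootstrap distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ols_core import OLSFit, SingularDesignError, fit_ols

__all__ = [
    "BootstrapDistribution",
    "BCaInterval",
    "pairs_resample",
    "wild_resample",
    "bootstrap_p_value",
    "percentile_ci",
    "bca_ci",
    "jackknife_slopes",
]

PERCENTILE_METHOD = "weibull"  # plotting position (B+1)q, linear interpolation


class DegenerateDistributionError(RuntimeError):
    """All bootstrap coefficients identical; scale-based inference undefined."""


class DegenerateResampleError(RuntimeError):
    """Pairs resampling kept producing singular designs past the redraw cap."""


@dataclass
class BootstrapDistribution:
    """B bootstrap coefficients for one coefficient of one fitted sample."""

    scheme: str  # "pairs" or "wild"
    B: int
    beta_star: np.ndarray  # length B
    original_estimate: float  # beta_hat_k of the source fit
    original_t: float  # classical t statistic of the source fit
    se_star: np.ndarray | None = None  # per-draw classical SEs (p-value mode)

    def __post_init__(self) -> None:
        if len(self.beta_star) != self.B:
            raise ValueError("beta_star length must equal B")
        if self.se_star is not None and len(self.se_star) != self.B:
            raise ValueError("se_star length must equal B")


@dataclass
class BCaInterval:
    low: float
    high: float
    z0: float
    accel: float
    flagged: bool = False  # clamped bias term or percentile fallback


def _classical_t(fit: OLSFit, k: int) -> float:
    se = math.sqrt(fit.sigma2_hat * fit.xtx_inv[k, k])
    return float(fit.beta_hat[k]) / se if se > 0 else math.inf


def pairs_resample(
    X: np.ndarray,
    y: np.ndarray,
    B: int,
    rng: np.random.Generator,
    *,
    k: int = 1,
    fit: OLSFit | None = None,
    redraw_cap: int = 100,
) -> BootstrapDistribution:
    """Case resampling: draw n rows with replacement, refit, B times.

    Fits are batched through the normal equations (p is small).  Resamples
    with a numerically singular X'X are redrawn, up to ``redraw_cap`` times
    per slot; continuous designs make this a measure-zero event in practice.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if fit is None:
        fit = fit_ols(X, y)
    idx = rng.integers(0, n, size=(B, n))
    beta_star = np.empty(B)
    se_star = np.empty(B)
    pending = np.arange(B)
    scale = float(np.trace(X.T @ X) / p)  # reference magnitude for det test
    for _ in range(redraw_cap + 1):
        Xb = X[idx[pending]]  # (m, n, p)
        yb = y[idx[pending]]
        xtx = np.einsum("bni,bnj->bij", Xb, Xb)
        xty = np.einsum("bni,bn->bi", Xb, yb)
        det = np.linalg.det(xtx)
        good = det > (1e-12 * scale) ** p
        if np.any(good):
            sel = pending[good]
            xtx_inv = np.linalg.inv(xtx[good])
            beta = np.einsum("bij,bj->bi", xtx_inv, xty[good])
            resid = yb[good] - np.einsum("bni,bi->bn", Xb[good], beta)
            s2 = np.einsum("bn,bn->b", resid, resid) / (n - p)
            beta_star[sel] = beta[:, k]
            se_star[sel] = np.sqrt(s2 * xtx_inv[:, k, k])
        pending = pending[~good]
        if pending.size == 0:
            break
        idx[pending] = rng.integers(0, n, size=(pending.size, n))
    else:
        raise DegenerateResampleError(
            f"{pending.size} resample slots stayed singular after "
            f"{redraw_cap} redraws (n={n}, p={p})"
        )
    return BootstrapDistribution(
        scheme="pairs",
        B=B,
        beta_star=beta_star,
        original_estimate=float(fit.beta_hat[k]),
        original_t=_classical_t(fit, k),
        se_star=se_star,
    )


def wild_resample(
    fit: OLSFit,
    B: int,
    rng: np.random.Generator,
    *,
    k: int = 1,
) -> BootstrapDistribution:
    """Wild bootstrap with Rademacher weights on deleted residuals.

    X never changes, so each draw's coefficients are a single linear map of
    the sign pattern; all B draws are computed in one matrix product.
    """
    h = fit.leverage
    if np.any(h > 1.0 - 1e-12):
        raise ValueError("a leverage value is (numerically) 1")
    r_t = fit.residuals / (1.0 - h)  # deleted residuals
    v = rng.integers(0, 2, size=(B, fit.n)) * 2.0 - 1.0
    e = v * r_t  # bootstrap noise added to the fitted values
    # beta* = beta_hat + (X'X)^-1 X' e; refit residual = e - H e
    A = fit.xtx_inv @ fit.X.T  # p x n
    delta = e @ A.T  # B x p coefficient perturbations
    beta_star = fit.beta_hat[k] + delta[:, k]
    resid = e - delta @ fit.X.T
    s2 = np.einsum("bn,bn->b", resid, resid) / fit.df_resid
    se_star = np.sqrt(s2 * fit.xtx_inv[k, k])
    return BootstrapDistribution(
        scheme="wild",
        B=B,
        beta_star=beta_star,
        original_estimate=float(fit.beta_hat[k]),
        original_t=_classical_t(fit, k),
        se_star=se_star,
    )


def bootstrap_p_value(
    dist: BootstrapDistribution, *, denominator: str = "per_resample"
) -> float:
    """Two-sided bootstrap p-value with the +1 continuity convention.

    p = (#{t*_b^2 >= t^2} + 1) / (B + 1), bounded in [1/(B+1), 1], where t
    is the original classical statistic and t*_b = (beta*_b - beta_hat) /
    SE*_b.  ``denominator="per_resample"`` (default) studentizes each draw
    by its own refit's conventional SE — the bootstrap-t convention, which
    lets the resampled t* distribution inherit the original statistic's
    scale inflation.  ``denominator="pooled"`` divides every draw by the one
    sample SD of the B bootstrap coefficients instead.
    """
    scale = max(1.0, abs(dist.original_estimate))
    if denominator == "per_resample":
        if dist.se_star is None:
            raise ValueError(
                "distribution carries no per-resample SEs; use "
                "denominator='pooled' or rebuild with a resampler"
            )
        if np.any(dist.se_star <= 1e-12 * scale):
            raise DegenerateDistributionError(
                "a bootstrap refit has zero residual variance; t* is undefined"
            )
        se = dist.se_star
    elif denominator == "pooled":
        sd = float(np.std(dist.beta_star, ddof=1))
        if sd <= 1e-12 * scale:
            raise DegenerateDistributionError(
                "all bootstrap coefficients are identical; t* is undefined"
            )
        se = sd
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    t_star = (dist.beta_star - dist.original_estimate) / se
    count = int(np.sum(t_star**2 >= dist.original_t**2))
    return (count + 1) / (dist.B + 1)


def percentile_ci(
    dist: BootstrapDistribution,
    level: float = 0.95,
    *,
    method: str = PERCENTILE_METHOD,
) -> tuple[float, float]:
    """Equal-tailed percentile interval from the bootstrap coefficients."""
    alpha = 1.0 - level
    lo, hi = np.quantile(
        dist.beta_star, [alpha / 2.0, 1.0 - alpha / 2.0], method=method
    )
    return float(lo), float(hi)


def jackknife_slopes(fit: OLSFit, k: int = 1) -> np.ndarray:
    """Leave-one-out estimates of coefficient k via the rank-one downdate.

    beta(-i)_k = beta_hat_k - [(X'X)^-1 x_i]_k * r_i / (1 - h_ii),
    algebraically identical to refitting without case i.
    """
    h = fit.leverage
    if np.any(h > 1.0 - 1e-12):
        raise ValueError("a leverage value is (numerically) 1")
    a_k = fit.X @ fit.xtx_inv[k]
    return fit.beta_hat[k] - a_k * fit.residuals / (1.0 - h)


def bca_ci(
    dist: BootstrapDistribution,
    fit: OLSFit,
    level: float = 0.95,
    *,
    k: int = 1,
    method: str = PERCENTILE_METHOD,
) -> BCaInterval:
    """Efron's bias-corrected and accelerated percentile interval.

    When every bootstrap coefficient falls on one side of the original
    estimate, the bias fraction is clamped half a count from the edge and
    the interval flagged rather than erroring, so long simulation runs keep
    going while degenerate replications stay countable.  A zero jackknife
    spread (no acceleration information) falls back to the plain percentile
    interval, also flagged.
    """
    B = dist.B
    frac = np.mean(dist.beta_star < dist.original_estimate)
    flagged = False
    if frac <= 0.0 or frac >= 1.0:
        frac = min(max(frac, 0.5 / B), 1.0 - 0.5 / B)
        flagged = True
    z0 = stats.norm.ppf(frac)

    theta = jackknife_slopes(fit, k=k)
    d = theta.mean() - theta
    denom = float(np.sum(d * d))
    if denom <= 0.0:
        lo, hi = percentile_ci(dist, level, method=method)
        return BCaInterval(lo, hi, z0=float(z0), accel=0.0, flagged=True)
    accel = float(np.sum(d**3) / (6.0 * denom**1.5))

    alpha = 1.0 - level
    z = stats.norm.ppf([alpha / 2.0, 1.0 - alpha / 2.0])
    zz = z0 + z
    levels = stats.norm.cdf(z0 + zz / (1.0 - accel * zz))
    lo, hi = np.quantile(dist.beta_star, levels, method=method)
    return BCaInterval(
        float(lo), float(hi), z0=float(z0), accel=accel, flagged=flagged
    )
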