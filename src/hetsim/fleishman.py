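"""Fleishman power-method transform for simulating non-normal variates.

A standard-normal draw ``Z`` is mapped through the cubic polynomial

    u = a + b*Z + c*Z**2 + d*Z**3

with coefficients chosen so that ``u`` has population mean 0, variance 1, and
prescribed skewness and excess kurtosis.  The coefficient constraints are the
classic Fleishman moment equations:

    a = -c
    b^2 + 6*b*d + 2*c^2 + 15*d^2                       = 1      (variance)
    2*c*(b^2 + 24*b*d + 105*d^2 + 2)                   = skew
    24*[b*d + c^2*(1 + b^2 + 28*b*d)
        + d^2*(12 + 48*b*d + 141*c^2 + 225*d^2)]       = excess kurtosis

Feasibility requires (approximately) excess kurtosis >= skew^2 - 2; outside
that region no real solution exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = ["FleishmanCoefficients", "solve_fleishman", "fleishman_transform"]


class FleishmanInfeasibleError(ValueError):
    """Target (skewness, excess kurtosis) pair has no Fleishman solution."""


class FleishmanConvergenceError(RuntimeError):
    """Root finder failed to reach the required residual tolerance."""


@dataclass(frozen=True)
class FleishmanCoefficients:
    """Polynomial coefficients for ``u = a + b*Z + c*Z^2 + d*Z^3``."""

    a: float
    b: float
    c: float
    d: float

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d])


def _moment_residuals(params: np.ndarray, skew: float, exkurt: float) -> list[float]:
    b, c, d = params
    var = b * b + 6.0 * b * d + 2.0 * c * c + 15.0 * d * d - 1.0
    sk = 2.0 * c * (b * b + 24.0 * b * d + 105.0 * d * d + 2.0) - skew
    ku = (
        24.0
        * (
            b * d
            + c * c * (1.0 + b * b + 28.0 * b * d)
            + d * d * (12.0 + 48.0 * b * d + 141.0 * c * c + 225.0 * d * d)
        )
        - exkurt
    )
    return [var, sk, ku]


def solve_fleishman(
    target_skew: float,
    target_kurtosis: float,
    *,
    tol: float = 1e-10,
) -> FleishmanCoefficients:
    """Solve the Fleishman moment equations for the given targets.

    Parameters
    ----------
    target_skew
        Population skewness of the transformed variate.
    target_kurtosis
        Population *excess* kurtosis (normal = 0).
    tol
        Maximum absolute residual of the three moment equations.

    Returns
    -------
    FleishmanCoefficients
        Coefficients on the ``b > 0`` branch (positively correlated with Z).

    Raises
    ------
    FleishmanInfeasibleError
        If the target pair lies outside the feasible region
        (excess kurtosis < skew^2 - 2, up to a small margin).
    FleishmanConvergenceError
        If the root finder does not reach ``tol``.
    """
    skew = float(target_skew)
    exkurt = float(target_kurtosis)
    if exkurt < skew * skew - 2.0:
        raise FleishmanInfeasibleError(
            f"(skew={skew}, excess kurtosis={exkurt}) violates the feasibility "
            f"bound excess kurtosis >= skew^2 - 2 = {skew * skew - 2.0:g}"
        )
    if skew == 0.0 and exkurt == 0.0:
        return FleishmanCoefficients(0.0, 1.0, 0.0, 0.0)

    # Solve for (b, c, d) with |skew|, then flip odd coefficients if needed:
    # negating skew negates a and c while leaving b, d unchanged.
    sgn = 1.0 if skew >= 0 else -1.0
    best = None
    for x0 in ([0.9, 0.15 * abs(skew) + 0.05, 0.05], [1.0, 0.1, 0.01], [0.5, 0.3, 0.2]):
        sol = optimize.root(_moment_residuals, x0, args=(abs(skew), exkurt), tol=1e-14)
        res = np.max(np.abs(_moment_residuals(sol.x, abs(skew), exkurt)))
        if sol.x[0] > 0 and res < tol:
            best = (sol.x, res)
            break
        if best is None or res < best[1]:
            best = (sol.x, res)
    (b, c, d), res = best
    if res > tol:
        raise FleishmanConvergenceError(
            f"Fleishman solver residual {res:.3e} exceeds tolerance {tol:.1e} "
            f"for targets (skew={skew}, excess kurtosis={exkurt})"
        )
    if b < 0:  # mirror solution: (b,c,d) -> (-b,c,-d) preserves all four moments
        b, d = -b, -d
    return FleishmanCoefficients(a=-sgn * c, b=b, c=sgn * c, d=d)


def fleishman_transform(z: np.ndarray, coef: FleishmanCoefficients) -> np.ndarray:
    """Apply ``u = a + b*z + c*z^2 + d*z^3`` elementwise."""
    return coef.a + z * (coef.b + z * (coef.c + z * coef.d))
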