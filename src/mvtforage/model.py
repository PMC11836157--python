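"""Closed-form marginal-value-theorem (MVT) mathematics for a single patch.

The patch yields cumulative gain ``g(T) = A * (1 - exp(-k*T))`` after a
residence time ``T`` (minutes): a concave saturating curve with upper
asymptote ``A`` (the maximum attainable gain, in Euro or product count) and
initial gain rate ``k`` (1/min), so that ``g'(0) = A*k``.

Travel time ``t`` is the round-trip time between the central place (home)
and the patch. Throughout this package ``t`` is *signed negative*: the
tangent construction places the travel time to the left of the origin on
the residence-time axis, so the MVT-optimal residence time is the abscissa
at which the tangent to the gain curve passes through ``(t, 0)``.

At the optimum the net gain rate ``g(T) / (T - t)`` equals the marginal
gain rate ``g'(T)``; equivalently ``exp(k*T) = k*(T - t) + 1``, which is
solved numerically by :func:`solve_residence_time`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "GainCurve",
    "gain",
    "gain_rate",
    "predict_travel_time",
    "solve_residence_time",
    "net_gain_rate",
    "tangent_line",
]

# Numerical policy for the implicit-equation solver: absolute tolerance on
# the residual of exp(kT) - k(T - t) - 1, and the bracket-expansion budget.
SOLVER_TOL: float = 1e-10
SOLVER_MAX_EXPANSIONS: int = 200


@dataclass(frozen=True)
class GainCurve:
    """Two-parameter asymptotic gain model.

    Parameters
    ----------
    A : float
        Maximum attainable gain in the patch (Euro, or product count when
        gain is operationalized as number of products). Must be positive.
    k : float
        Initial gain-rate parameter (1/minute). Must be positive.
    """

    A: float
    k: float

    def __post_init__(self) -> None:
        if not (self.A > 0 and math.isfinite(self.A)):
            raise ValueError(f"A must be positive and finite, got {self.A}")
        if not (self.k > 0 and math.isfinite(self.k)):
            raise ValueError(f"k must be positive and finite, got {self.k}")


def _check_nonneg(T, name: str = "T"):
    T = np.asarray(T, dtype=float)
    if np.any(T < 0):
        raise ValueError(f"{name} must be >= 0")
    return T


def gain(curve: GainCurve, T):
    """Cumulative gain ``A * (1 - exp(-k*T))`` at residence time ``T >= 0``.

    Accepts scalars or arrays; returns the same shape. ``gain(curve, 0) == 0``
    and the result is strictly below ``A`` for finite ``T``.
    """
    T = _check_nonneg(T)
    out = curve.A * (-np.expm1(-curve.k * T))
    return float(out) if out.ndim == 0 else out


def gain_rate(curve: GainCurve, T):
    """Marginal gain rate ``g'(T) = A * k * exp(-k*T)``; decreasing in ``T``."""
    T = _check_nonneg(T)
    out = curve.A * curve.k * np.exp(-curve.k * T)
    return float(out) if out.ndim == 0 else out


def predict_travel_time(curve: GainCurve, T):
    """Signed travel time for which ``T`` is the MVT-optimal residence time.

    The tangent to the gain curve at ``(T, g(T))`` crosses zero at

        ``t = T - g(T) / g'(T) = T - (exp(k*T) - 1) / k``

    which is negative for every ``T > 0`` under this package's sign
    convention (travel plotted left of the origin). The result depends on
    ``k`` and ``T`` only; ``A`` cancels in ``g/g'``.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("T must be > 0 for a travel-time prediction")
    out = T - np.expm1(curve.k * T) / curve.k
    return float(out) if out.ndim == 0 else out


def _solve_one(k: float, t: float) -> float:
    """Unique root T >= 0 of f(T) = exp(kT) - k*(T - t) - 1 for t <= 0."""
    if t == 0.0:
        return 0.0

    def f(T: float) -> float:
        return math.expm1(k * T) - k * (T - t)

    # f(0) = k*t < 0 and f is strictly increasing for T > 0, so expand the
    # upper end geometrically until the sign changes. Start from the
    # closed-form bracket hint ln(1 + k*(-t))/k, which undershoots the root.
    lo = 0.0
    hi = math.log1p(k * (-t)) / k + 1.0 / k
    for _ in range(SOLVER_MAX_EXPANSIONS):
        if f(hi) > 0:
            break
        lo = hi
        hi *= 2.0
    else:
        raise RuntimeError(
            f"residence-time bracket expansion failed (k={k}, t={t}, hi={hi})"
        )
    root = brentq(f, lo, hi, xtol=1e-13, rtol=8.9e-16)
    # Newton polish to drive the implicit-equation residual below tolerance.
    for _ in range(5):
        r = f(root)
        if abs(r) <= SOLVER_TOL:
            break
        root -= r / (k * math.exp(k * root) - k + 1e-300)
    return max(root, 0.0)


def solve_residence_time(curve: GainCurve, t):
    """Optimal residence time ``T`` for a signed travel time ``t <= 0``.

    Solves ``exp(k*T) = k*(T - t) + 1`` for the unique ``T >= 0``. The root
    exists and is unique because ``f(T) = exp(kT) - kT + kt - 1`` satisfies
    ``f(0) = kt <= 0`` with ``f' > 0`` for ``T > 0``. Longer travel (more
    negative ``t``) gives a longer optimal stay.

    Raises
    ------
    ValueError
        If ``t > 0`` (positive values violate the sign convention) or ``t``
        is not finite.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(~np.isfinite(t_arr)):
        raise ValueError("t must be finite")
    if np.any(t_arr > 0):
        raise ValueError("t must be <= 0 (signed-negative travel-time convention)")
    if t_arr.ndim == 0:
        return _solve_one(curve.k, float(t_arr))
    return np.array([_solve_one(curve.k, ti) for ti in t_arr.ravel()]).reshape(
        t_arr.shape
    )


def net_gain_rate(curve: GainCurve, T, t):
    """Net gain rate ``g(T) / (T - t)`` over the full time budget.

    ``T > 0`` is the residence time and ``t <= 0`` the signed travel time,
    so the denominator ``T - t`` is the total time away from home. At the
    MVT optimum this equals the marginal rate ``g'(T)``.
    """
    T = np.asarray(T, dtype=float)
    t_arr = np.asarray(t, dtype=float)
    if np.any(T <= 0):
        raise ValueError("T must be > 0")
    if np.any(t_arr > 0):
        raise ValueError("t must be <= 0")
    denom = T - t_arr
    if np.any(denom == 0):
        raise ValueError("total time budget T - t must be nonzero")
    out = curve.A * (-np.expm1(-curve.k * T)) / denom
    return float(out) if out.ndim == 0 else out


def tangent_line(curve: GainCurve, T0: float) -> tuple[float, float]:
    """Tangent to the gain curve at ``T0 > 0`` as ``(slope, intercept)``.

    The slope is ``g'(T0)`` (Euro/min) and the intercept
    ``b = g(T0) - g'(T0) * T0 = -A*k*exp(-k*T0) * t`` (Euro), so the line
    passes through ``(T0, g(T0))`` and crosses zero at
    ``predict_travel_time(curve, T0)``.
    """
    if not T0 > 0:
        raise ValueError("T0 must be > 0")
    slope = gain_rate(curve, T0)
    intercept = gain(curve, T0) - slope * T0
    return slope, intercept
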