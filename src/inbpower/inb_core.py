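"""Incremental net benefit: point estimate, ICER, variance and CI curves.

For a two-arm trial with incremental effectiveness ``delta_e`` and
incremental cost ``delta_c``, the incremental net benefit (INB) at
willingness-to-pay ``lambda`` is

    b(lambda) = lambda * delta_e - delta_c        (CAD)

Positive values mean the experimental arm is cost-effective at that
willingness-to-pay.  The ICER ``delta_c / delta_e`` is the root of
``b(lambda)`` in lambda, and the confidence bounds of the INB curve cross
zero at the Fieller limits of the ICER.

The INB variance combines the per-arm second moments of effectiveness and
cost; its cross term ``-2 lambda rho sd_E sd_C`` makes a positive
effectiveness-cost correlation *reduce* the variance, which is the
phenomenon this package exists to quantify.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .trial_params import ArmStats, ParameterError, SimplifiedCEAParams

__all__ = [
    "VarianceResult",
    "IntervalCurve",
    "inb",
    "icer",
    "variance_general",
    "variance_simplified",
    "variance_as_linear_in_rho",
    "inb_interval_curve",
]

#: Default willingness-to-pay grid for CI curves: $0 to $250,000 in $1,000 steps.
DEFAULT_WTP_GRID = np.arange(0, 250_001, 1_000, dtype=float)


@dataclass(frozen=True)
class VarianceResult:
    """Variance of the INB estimate at one willingness-to-pay.

    ``value`` is in CAD^2.  ``components`` holds the effect, cost and
    cross-term contributions *before* the sample-size factor ``scale``, so
    that ``value == scale * sum(components.values())``.  ``display_value``
    is ``value / 1000``, the conventional reporting scale (thousands of
    CAD^2) for these variances.
    """

    value: float
    scale: float
    components: dict[str, float]

    @property
    def display_value(self) -> float:
        return self.value / 1_000.0

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.value))


def inb(delta_e: float, delta_c: float, wtp: float) -> float:
    """Incremental net benefit b(lambda) = lambda*delta_e - delta_c (CAD)."""
    if wtp < 0:
        raise ParameterError(f"invalid wtp: {wtp!r}")
    return wtp * delta_e - delta_c


def icer(delta_e: float, delta_c: float) -> float:
    """Incremental cost-effectiveness ratio delta_c / delta_e (CAD/effect).

    Equals the willingness-to-pay at which the INB is zero.  Undefined for
    ``delta_e == 0`` (the ratio's standard error diverges as the
    effectiveness difference vanishes).
    """
    if delta_e == 0:
        raise ZeroDivisionError(
            "ICER undefined: delta_e is zero (standard error diverges)"
        )
    return delta_c / delta_e


def _arm_terms(arm: ArmStats, wtp: float) -> tuple[float, float, float]:
    return (
        wtp**2 * arm.sd_effect**2,
        arm.sd_cost**2,
        -2.0 * wtp * arm.rho * arm.sd_effect * arm.sd_cost,
    )


def variance_general(arm0: ArmStats, arm1: ArmStats, wtp: float) -> VarianceResult:
    """INB variance from per-arm moments.

    sigma^2_b = sum_j (1/n_j) (wtp^2 sd_Ej^2 + sd_Cj^2
                               - 2 wtp rho_j sd_Ej sd_Cj)

    The components are the per-term sums already weighted by 1/n_j, so the
    sample-size ``scale`` is 1.
    """
    t0, t1 = _arm_terms(arm0, wtp), _arm_terms(arm1, wtp)
    components = {
        "effect": t0[0] / arm0.n + t1[0] / arm1.n,
        "cost": t0[1] / arm0.n + t1[1] / arm1.n,
        "cross": t0[2] / arm0.n + t1[2] / arm1.n,
    }
    return VarianceResult(
        value=sum(components.values()), scale=1.0, components=components
    )


def variance_simplified(params: SimplifiedCEAParams, wtp: float) -> VarianceResult:
    """INB variance under balanced arms with common moments.

    sigma^2_b = (4/n) (wtp^2 sd_E^2 + sd_C^2 - 2 wtp rho sd_E sd_C)

    ``display_value`` (value / 1000) is the conventional reporting scale.
    The event ratio ``pi`` plays no role here: it belongs to the
    sample-size formula, not to the variance of an observed INB.
    """
    effect = wtp**2 * params.sd_effect**2
    cost = params.sd_cost**2
    cross = -2.0 * wtp * params.rho * params.sd_effect * params.sd_cost
    scale = 4.0 / params.n_total
    components = {"effect": effect, "cost": cost, "cross": cross}
    return VarianceResult(
        value=scale * (effect + cost + cross), scale=scale, components=components
    )


def variance_as_linear_in_rho(
    params: SimplifiedCEAParams, wtp: float
) -> tuple[float, float]:
    """The INB variance as an affine function of the correlation.

    Returns ``(intercept, slope)`` in CAD^2 such that the simplified
    variance at any rho equals ``intercept + slope * rho`` exactly:

        intercept = (4/n)(wtp^2 sd_E^2 + sd_C^2)
        slope     = -(4/n) * 2 * wtp * sd_E * sd_C

    ``abs(slope) / intercept`` is the relative variance swing when rho moves
    from 0 to +/-1.
    """
    scale = 4.0 / params.n_total
    intercept = scale * (wtp**2 * params.sd_effect**2 + params.sd_cost**2)
    slope = -scale * 2.0 * wtp * params.sd_effect * params.sd_cost
    return intercept, slope


@dataclass(frozen=True)
class IntervalCurve:
    """INB estimate and confidence band over a willingness-to-pay grid.

    ``fieller`` holds the lambda values where the confidence bounds cross
    zero — the Fieller limits of the ICER — as ``(lower, upper)``; either
    entry is ``None`` when the corresponding bound never crosses zero on the
    grid's hull (the unbounded-interval pathology of near-zero incremental
    effectiveness).
    """

    wtp_grid: np.ndarray
    estimate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    fieller: tuple[Optional[float], Optional[float]]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "wtp": self.wtp_grid,
                "estimate": self.estimate,
                "lower": self.lower,
                "upper": self.upper,
            }
        )


def _sd_function(
    params: Optional[SimplifiedCEAParams],
    arms: Optional[tuple[ArmStats, ArmStats]],
):
    if (params is None) == (arms is None):
        raise ParameterError("supply exactly one of params or arms")
    if params is not None:
        return lambda lam: np.sqrt(variance_simplified(params, lam).value)
    arm0, arm1 = arms
    return lambda lam: np.sqrt(variance_general(arm0, arm1, lam).value)


def _endpoint_roots(f, grid: np.ndarray) -> list[float]:
    """All sign-change roots of f over consecutive grid cells."""
    vals = np.array([f(x) for x in grid])
    roots = []
    for i in range(len(grid) - 1):
        a, b = vals[i], vals[i + 1]
        if a == 0.0:
            roots.append(float(grid[i]))
        elif a * b < 0:
            roots.append(float(brentq(f, grid[i], grid[i + 1], xtol=1e-9, rtol=1e-12)))
    if vals[-1] == 0.0:
        roots.append(float(grid[-1]))
    return roots


def inb_interval_curve(
    params: Optional[SimplifiedCEAParams] = None,
    *,
    arms: Optional[tuple[ArmStats, ArmStats]] = None,
    delta_e: Optional[float] = None,
    delta_c: Optional[float] = None,
    wtp_grid: Union[Sequence[float], np.ndarray, None] = None,
    level: float = 0.95,
) -> IntervalCurve:
    """Confidence band of the INB across willingness-to-pay values.

    The estimate is the straight line ``lambda*delta_e - delta_c``; the
    bounds are ``estimate +/- z_(1+level)/2 * sd_b(lambda)`` with the
    variance taken from the pooled ``params`` or from the per-arm ``arms``
    moments.  When ``params`` carries ``delta_e``/``delta_c`` they are used
    unless explicitly overridden.

    The Fieller limits are located by bracketing each confidence-bound curve
    over the grid hull and refining with Brent's method; a bound that never
    changes sign yields ``None`` on that side.
    """
    if not 0 < level < 1:
        raise ParameterError(f"invalid level: {level!r}")
    if wtp_grid is None:
        wtp_grid = DEFAULT_WTP_GRID
    grid = np.asarray(wtp_grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
        raise ParameterError("wtp_grid must be a 1-D strictly ascending grid")
    if delta_e is None:
        if params is None:
            raise ParameterError("delta_e is required when using per-arm moments")
        delta_e = params.delta_e
    if delta_c is None:
        if params is None:
            raise ParameterError("delta_c is required when using per-arm moments")
        delta_c = params.delta_c

    sd = _sd_function(params, arms)
    z = norm.ppf(0.5 + level / 2.0)
    estimate = grid * delta_e - delta_c
    sds = np.array([sd(lam) for lam in grid])
    lower = estimate - z * sds
    upper = estimate + z * sds

    lower_f = lambda lam: lam * delta_e - delta_c - z * sd(lam)
    upper_f = lambda lam: lam * delta_e - delta_c + z * sd(lam)
    up_roots = _endpoint_roots(upper_f, grid)
    lo_roots = _endpoint_roots(lower_f, grid)
    crossings = up_roots + lo_roots
    if up_roots and lo_roots:
        fieller = (min(crossings), max(crossings))
    elif len(crossings) >= 2:
        fieller = (min(crossings), max(crossings))
    elif len(crossings) == 1:
        # Only one bound crosses inside the hull.  For delta_e > 0 the upper
        # bound crosses at the lower Fieller limit and the lower bound at the
        # upper limit; the roles swap for delta_e < 0.  The missing side is
        # outside the grid hull or unbounded.
        root = crossings[0]
        from_upper = bool(up_roots)
        if (delta_e >= 0) == from_upper:
            fieller = (root, None)
        else:
            fieller = (None, root)
    else:
        fieller = (None, None)
    return IntervalCurve(
        wtp_grid=grid,
        estimate=estimate,
        lower=lower,
        upper=upper,
        level=level,
        fieller=fieller,
    )
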