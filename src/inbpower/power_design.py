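"""Power and sample-size calculation on the incremental net benefit scale.

The design question: how many patients does a trial-embedded
cost-effectiveness analysis need so that a one-sided level-``alpha`` test of
H0: b(lambda) <= 0 detects a smallest important net-benefit difference
b_delta with the target power?  With the normal approximation,

    n = (z_{1-alpha} + z_{1-beta})^2 * V1 / b_delta^2

where ``V1 = n * sigma^2_b`` is the sample-size-free "unit variance" of the
INB under balanced allocation.  With pooled moments and the event ratio
``pi = n_e / d_e`` of the efficacy design, the unit variance is

    V1 = 4 (lambda^2 pi sd_E^2 + sd_C^2 - 2 lambda rho sqrt(pi) sd_E sd_C)

and the corresponding power at a given n is

    P = Phi( b_delta / sigma_b - z_{1-alpha} ).

A positive effectiveness-cost correlation lowers the variance and therefore
the required sample size; rho = 0 is the conservative planning assumption.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .trial_params import (
    ParameterError,
    SimplifiedCEAParams,
    SmallestImportantDifference,
    TestSpec,
)

__all__ = [
    "PowerResult",
    "SampleSizeResult",
    "z_factor",
    "smallest_important_difference",
    "unit_variance",
    "sample_size_from_unit_variance",
    "sample_size",
    "analytic_power",
    "power_curve_vs_n",
    "power_curve_vs_rho",
    "power_curve_vs_wtp",
]


@dataclass(frozen=True)
class PowerResult:
    """Power of the INB test at a given design."""

    power: float
    n_total: float
    b_delta: float
    sd_inb: float


@dataclass(frozen=True)
class SampleSizeResult:
    """Required sample size; ``n_total`` is ``n_exact`` rounded up to an
    even integer for balanced arms."""

    n_exact: float
    n_total: int
    z_factor: float


def _z_alpha(test: TestSpec) -> float:
    alpha = test.alpha / 2.0 if test.direction == "two_sided" else test.alpha
    return float(norm.ppf(1.0 - alpha))


def z_factor(alpha: float, target_power: float) -> float:
    """(z_{1-alpha} + z_{1-beta})^2 for one-sided alpha.

    E.g. alpha = 0.05, power = 0.80 gives 6.18.
    """
    return float((norm.ppf(1.0 - alpha) + norm.ppf(target_power)) ** 2)


def smallest_important_difference(
    spec: SmallestImportantDifference,
    *,
    delta_e: Optional[float] = None,
    delta_c: Optional[float] = None,
    wtp: Optional[float] = None,
    sd_inb: Optional[float] = None,
    test: Optional[TestSpec] = None,
) -> float:
    """Resolve the smallest important INB difference b(lambda)_delta (CAD).

    ``observed``:    lambda*delta_e - delta_c (errors when exactly zero —
                     the required sample size diverges);
    ``frequentist``: (z_{1-alpha} + z_{1-beta}) * sd_inb, the minimum
                     detectable difference at the test's alpha and power;
    ``explicit``:    the user-supplied value.
    """
    if spec.mode == "explicit":
        return float(spec.value)  # validated finite at construction
    if spec.mode == "observed":
        if delta_e is None or delta_c is None or wtp is None:
            raise ParameterError(
                "observed mode requires delta_e, delta_c and wtp"
            )
        b = wtp * delta_e - delta_c
        if b == 0:
            raise ParameterError(
                "degenerate smallest important difference: "
                "wtp*delta_e - delta_c is zero (sample size diverges)"
            )
        return float(b)
    # frequentist
    if sd_inb is None or test is None:
        raise ParameterError("frequentist mode requires sd_inb and test")
    return float((_z_alpha(test) + norm.ppf(test.target_power)) * sd_inb)


def unit_variance(params: SimplifiedCEAParams, wtp: float, use_pi: bool = True) -> float:
    """Sample-size-free INB variance V1 = n * sigma^2_b (CAD^2).

    With ``use_pi`` the effectiveness term carries the event ratio pi and
    the cross term sqrt(pi), as in the design-stage sample-size formula;
    without it this is exactly n times the pooled variance.
    """
    pi = params.pi if use_pi else 1.0
    return 4.0 * (
        wtp**2 * pi * params.sd_effect**2
        + params.sd_cost**2
        - 2.0 * wtp * params.rho * math.sqrt(pi) * params.sd_effect * params.sd_cost
    )


def _round_even(n_exact: float) -> int:
    n = math.ceil(n_exact)
    return n if n % 2 == 0 else n + 1


def sample_size_from_unit_variance(
    unit_var: float, b_delta: float, test: TestSpec
) -> SampleSizeResult:
    """Required n from a unit variance and smallest important difference.

    n_exact = (z_{1-alpha} + z_{1-beta})^2 * V1 / b_delta^2, with alpha
    halved for a two-sided test; ``n_total`` rounds up to the next even
    integer for balanced arms.
    """
    if b_delta == 0:
        raise ParameterError(
            "degenerate smallest important difference: b_delta is zero"
        )
    alpha = test.alpha / 2.0 if test.direction == "two_sided" else test.alpha
    z = z_factor(alpha, test.target_power)
    n_exact = z * unit_var / b_delta**2
    return SampleSizeResult(n_exact=n_exact, n_total=_round_even(n_exact), z_factor=z)


def sample_size(
    params: SimplifiedCEAParams,
    test: TestSpec,
    sid: SmallestImportantDifference = SmallestImportantDifference("observed"),
) -> SampleSizeResult:
    """Required total sample size for the INB test from pooled moments.

        n = 4 z (lambda^2 pi sd_E^2 + sd_C^2 - 2 lambda rho sqrt(pi) sd_E sd_C)
            / (lambda*delta_e - delta_c)^2

    The denominator is the squared smallest important difference in its
    observed definition; ``sid`` switches to an explicit CAD value.  (The
    frequentist definition fixes power by construction and has no finite
    solved-for n, so it is rejected here.)
    """
    if sid.mode == "frequentist":
        raise ParameterError(
            "frequentist smallest important difference is defined *from* a "
            "sample size; solve for power instead"
        )
    b_delta = smallest_important_difference(
        sid,
        delta_e=params.delta_e,
        delta_c=params.delta_c,
        wtp=test.wtp,
        test=test,
    )
    return sample_size_from_unit_variance(
        unit_variance(params, test.wtp), b_delta, test
    )


def analytic_power(
    params: SimplifiedCEAParams,
    test: TestSpec,
    n_total: Optional[float] = None,
    sid: SmallestImportantDifference = SmallestImportantDifference("observed"),
) -> PowerResult:
    """Normal-approximation power of the INB test at sample size ``n_total``.

    Direction ``greater``:  Phi( b_delta/sigma_b - z_{1-alpha} );
    ``less``:               same with the sign of b_delta flipped;
    ``two_sided``:          Phi( |b_delta|/sigma_b - z_{1-alpha/2} ),
    neglecting the vanishing wrong-tail probability.

    ``n_total`` defaults to ``params.n_total`` and may be non-integer (the
    continuous solution of the sample-size formula round-trips to the target
    power exactly).
    """
    n = float(params.n_total if n_total is None else n_total)
    if n <= 0:
        raise ParameterError(f"invalid n_total: {n_total!r}")
    var = unit_variance(params, test.wtp, use_pi=False) / n
    sd_inb = math.sqrt(var)
    if sid.mode == "frequentist":
        b_delta = smallest_important_difference(sid, sd_inb=sd_inb, test=test)
    else:
        b_delta = smallest_important_difference(
            sid,
            delta_e=params.delta_e,
            delta_c=params.delta_c,
            wtp=test.wtp,
            test=test,
        )
    z_a = _z_alpha(test)
    if test.direction == "greater":
        shift = b_delta / sd_inb
    elif test.direction == "less":
        shift = -b_delta / sd_inb
    else:
        shift = abs(b_delta) / sd_inb
    power = float(norm.cdf(shift - z_a))
    return PowerResult(power=power, n_total=n, b_delta=b_delta, sd_inb=sd_inb)


def power_curve_vs_n(
    params: SimplifiedCEAParams, test: TestSpec, n_grid: Sequence[float]
) -> list[tuple[float, float]]:
    """Power at each sample size of an ascending grid."""
    grid = np.asarray(n_grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ParameterError("n_grid must be strictly ascending")
    return [(float(n), analytic_power(params, test, n_total=n).power) for n in grid]


def power_curve_vs_rho(
    params: SimplifiedCEAParams, test: TestSpec, rho_grid: Sequence[float]
) -> list[tuple[float, float]]:
    """Power at each correlation of an ascending grid (n fixed)."""
    grid = np.asarray(rho_grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ParameterError("rho_grid must be strictly ascending")
    return [
        (float(r), analytic_power(params.with_(rho=float(r)), test).power)
        for r in grid
    ]


def power_curve_vs_wtp(
    params: SimplifiedCEAParams, test: TestSpec, wtp_grid: Sequence[float]
) -> list[tuple[float, float]]:
    """Power at each willingness-to-pay of an ascending grid (n fixed)."""
    grid = np.asarray(wtp_grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ParameterError("wtp_grid must be strictly ascending")
    out = []
    for lam in grid:
        t = TestSpec(
            alpha=test.alpha,
            target_power=test.target_power,
            wtp=float(lam),
            direction=test.direction,
        )
        out.append((float(lam), analytic_power(params, t).power))
    return out
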