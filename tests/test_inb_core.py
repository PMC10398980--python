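"""INB estimate, ICER, variance formulas, CI curves and Fieller limits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq
from scipy.stats import norm

import inbpower as ip
from inbpower.trial_params import ParameterError

# strategies for well-conditioned pooled parameters
_params_st = st.builds(
    ip.SimplifiedCEAParams,
    n_total=st.integers(4, 2000),
    sd_effect=st.floats(0.01, 5.0),
    sd_cost=st.floats(100.0, 50_000.0),
    rho=st.floats(-1.0, 1.0),
    delta_e=st.just(0.1),
    delta_c=st.just(1000.0),
)
_wtp_st = st.floats(0.0, 300_000.0)


@pytest.mark.parametrize(
    "delta_e, delta_c, wtp, expected",
    [(0, 0, 100_000, 0.0), (0.5, 30_000, 100_000, 20_000.0), (0.5, 30_000, 60_000, 0.0)],
)
def test_inb_arithmetic(delta_e, delta_c, wtp, expected):
    assert ip.inb(delta_e, delta_c, wtp) == pytest.approx(expected)


def test_inb_is_zero_at_the_icer():
    assert ip.inb(0.37, 12_345.0, ip.icer(0.37, 12_345.0)) == pytest.approx(0.0, abs=1e-9)


@pytest.mark.parametrize("delta_e, delta_c, expected", [(0.5, 30_000, 60_000.0), (1, 0, 0.0)])
def test_icer_arithmetic(delta_e, delta_c, expected):
    assert ip.icer(delta_e, delta_c) == expected


def test_icer_matches_bisection_root_of_inb():
    # independent oracle: bisection on the INB curve in wtp
    root = brentq(lambda lam: ip.inb(0.5, 30_000, lam), 1.0, 1e6, xtol=1e-9)
    assert root == pytest.approx(ip.icer(0.5, 30_000), abs=1e-6)


def test_icer_undefined_for_zero_effect_difference():
    with pytest.raises(ZeroDivisionError, match="delta_e"):
        ip.icer(0.0, 1000.0)


def _arm(n=100, sd_e=1.0, sd_c=1000.0, rho=0.3):
    return ip.ArmStats(
        n=n, mean_effect=0.0, sd_effect=sd_e, mean_cost=0.0, sd_cost=sd_c, rho=rho
    )


def test_general_variance_at_zero_wtp_is_cost_only():
    a0, a1 = _arm(n=50, sd_c=2000.0), _arm(n=80, sd_c=1000.0)
    v = ip.variance_general(a0, a1, 0.0)
    assert v.value == pytest.approx(2000.0**2 / 50 + 1000.0**2 / 80)


def test_general_variance_vanishes_at_perfect_correlation():
    # rho = 1 and wtp*sd_E == sd_C in both arms
    a = _arm(sd_e=1.0, sd_c=100.0, rho=1.0)
    assert ip.variance_general(a, a, 100.0).value == pytest.approx(0.0, abs=1e-6)


def test_simplified_variance_unit_case():
    p = ip.SimplifiedCEAParams(
        n_total=4, sd_effect=1.0, sd_cost=1.0, rho=0.0, delta_e=0.1, delta_c=1.0
    )
    assert ip.variance_simplified(p, 0.0).value == pytest.approx(1.0)


def test_display_value_is_thousands_of_cad_squared(co17):
    v = ip.variance_simplified(co17, 100_000.0)
    assert v.display_value == pytest.approx(v.value / 1000.0)


def test_variance_components_sum_to_value(co17):
    v = ip.variance_simplified(co17, 123_456.0)
    assert v.value == pytest.approx(v.scale * sum(v.components.values()))


@settings(derandomize=True, max_examples=200)
@given(params=_params_st, wtp=_wtp_st)
def test_general_reduces_to_simplified_under_equal_arms(params, wtp):
    """Two identical balanced arms give exactly the pooled-variance formula."""
    arm = ip.ArmStats(
        n=params.n_total // 2 if params.n_total % 2 == 0 else params.n_total,
        mean_effect=0.0,
        sd_effect=params.sd_effect,
        mean_cost=0.0,
        sd_cost=params.sd_cost,
        rho=params.rho,
    )
    general = ip.variance_general(arm, arm, wtp).value
    pooled = ip.variance_simplified(params.with_(n_total=2 * arm.n), wtp).value
    assert general == pytest.approx(pooled, rel=1e-12, abs=1e-12)


@settings(derandomize=True, max_examples=200)
@given(params=_params_st, wtp=_wtp_st)
def test_variance_cauchy_schwarz_lower_bound(params, wtp):
    """sigma^2_b >= (4/n)(wtp*sd_E - sd_C)^2 >= 0 for any |rho| <= 1."""
    v = ip.variance_simplified(params, wtp).value
    bound = (4.0 / params.n_total) * (wtp * params.sd_effect - params.sd_cost) ** 2
    assert v >= bound - 1e-6 * max(1.0, bound)
    assert v >= -1e-9


@settings(derandomize=True, max_examples=200)
@given(params=_params_st, wtp=_wtp_st, rho=st.floats(-1.0, 1.0))
def test_variance_is_affine_in_rho(params, wtp, rho):
    intercept, slope = ip.variance_as_linear_in_rho(params, wtp)
    direct = ip.variance_simplified(params.with_(rho=rho), wtp).value
    assert direct == pytest.approx(intercept + slope * rho, rel=1e-12, abs=1e-9)


def test_rho_slope_vanishes_at_zero_wtp(co17):
    _, slope = ip.variance_as_linear_in_rho(co17, 0.0)
    assert slope == 0.0


def test_variance_strictly_decreasing_in_rho_for_positive_wtp(co17):
    rhos = np.linspace(-1, 1, 21)
    vals = [ip.variance_simplified(co17.with_(rho=float(r)), 100_000.0).value for r in rhos]
    assert np.all(np.diff(vals) < 0)


# --- interval curves and Fieller limits ------------------------------------


def test_interval_curve_basic_shape(co17):
    grid = np.arange(0.0, 250_001.0, 1_000.0)
    curve = ip.inb_interval_curve(co17, wtp_grid=grid)
    assert np.all(curve.lower <= curve.estimate) and np.all(curve.estimate <= curve.upper)
    # the estimate is affine in wtp
    slopes = np.diff(curve.estimate) / np.diff(curve.wtp_grid)
    assert np.allclose(slopes, co17.delta_e)


def test_interval_width_widens_with_wtp(co17):
    """Beyond sd_C*rho/sd_E the band width is increasing in wtp."""
    lam0 = co17.sd_cost * co17.rho / co17.sd_effect
    grid = np.arange(lam0, lam0 + 150_000.0, 1_000.0)
    curve = ip.inb_interval_curve(co17, wtp_grid=grid)
    width = curve.upper - curve.lower
    assert np.all(np.diff(width) > 0)


def test_perfect_correlation_band_inside_uncorrelated_band(co17):
    grid = np.arange(1_000.0, 250_001.0, 1_000.0)
    c1 = ip.inb_interval_curve(co17.with_(rho=1.0), wtp_grid=grid)
    c0 = ip.inb_interval_curve(co17.with_(rho=0.0), wtp_grid=grid)
    assert np.all(c1.upper - c1.lower < c0.upper - c0.lower)


def _closed_form_fieller(params, level=0.95):
    """Independent oracle: classical Fieller interval for delta_c/delta_e
    from the same pooled moments, via the quadratic in lambda."""
    z = norm.ppf(0.5 + level / 2.0)
    n = params.n_total
    v_e = (4.0 / n) * params.sd_effect**2
    v_c = (4.0 / n) * params.sd_cost**2
    cov = (4.0 / n) * params.rho * params.sd_effect * params.sd_cost
    a = params.delta_e**2 - z**2 * v_e
    b = -2.0 * (params.delta_e * params.delta_c - z**2 * cov)
    c = params.delta_c**2 - z**2 * v_c
    roots = np.roots([a, b, c])
    return tuple(sorted(float(r) for r in roots))


def test_fieller_limits_match_closed_form(co17):
    curve = ip.inb_interval_curve(co17, wtp_grid=np.arange(0.0, 250_001.0, 1_000.0))
    lo, hi = _closed_form_fieller(co17)
    assert curve.fieller[0] == pytest.approx(lo, rel=1e-6)
    assert curve.fieller[1] == pytest.approx(hi, rel=1e-6)


def test_fieller_absent_when_bounds_never_cross(co17):
    # a cost-saving, effective treatment with tiny uncertainty: the whole
    # band stays positive on the grid, so no crossing exists
    p = co17.with_(n_total=1_000_000, delta_e=1.0, delta_c=-10_000.0)
    curve = ip.inb_interval_curve(p, wtp_grid=np.arange(0.0, 250_001.0, 1_000.0))
    assert curve.fieller == (None, None)
    assert np.all(curve.lower > 0)


def test_interval_curve_rejects_bad_grid(co17):
    with pytest.raises(ParameterError, match="ascending"):
        ip.inb_interval_curve(co17, wtp_grid=[1000.0, 500.0])
    with pytest.raises(ParameterError, match="level"):
        ip.inb_interval_curve(co17, wtp_grid=[0.0, 1000.0], level=1.5)
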