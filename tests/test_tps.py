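"""Forward-model tests: shape function against independent quadrature, the
closed-form steady limit, scaling laws of the mean temperature rise, the
diffusion-length rule and the simplified erfc model."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import dblquad, quad
from scipy.special import erf, ive, j1

from epitherm.tps import (
    STEADY_STATE_D,
    InvalidParameterError,
    SensorConfig,
    SimplifiedFitConstants,
    ThermalProperties,
    TransientCurve,
    diffusion_length,
    dimensionless_time,
    mean_temperature_rise,
    shape_function,
    simplified_rise,
)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def brute_force_shape(tau: float, sigma0: float = 1e-3) -> float:
    """Nested adaptive quadrature of the triple integral, in rotated disc
    coordinates (w = u - v along the kernel ridge, m = u + v), entirely
    separate from the implementation's substitution and fixed-order rules.
    The [0, sigma0] head contributes sigma0 to one part in 1e6 (the outer
    integrand tends to 1 there)."""

    def inner(sigma: float) -> float:
        def fn(m, w):
            u = 0.5 * (m + w)
            v = 0.5 * (m - w)
            return u * v * ive(0, u * v / (2 * sigma**2)) * np.exp(-(w * w) / (4 * sigma**2))

        val, _ = dblquad(fn, 0, 1, lambda w: w, lambda w: 2 - w, epsabs=1e-12, epsrel=1e-8)
        return val / sigma**2  # x2 for w-symmetry, x1/2 Jacobian

    val, _ = quad(inner, sigma0, tau, epsabs=1e-9, epsrel=1e-6, limit=200)
    return val + sigma0


def hankel_shape(tau: float) -> float:
    """Closed-form-route oracle: the disc-average of the constant-flux
    half-space solution in Hankel space gives
    D(tau) = sqrt(pi) * int_0^inf (J1(mu)/mu)^2 erf(mu*tau) dmu."""
    fn = lambda mu: (j1(mu) / mu) ** 2 * erf(mu * tau)
    val, _ = quad(fn, 0, 100.0, limit=2000, epsabs=1e-13, epsrel=1e-11)
    tail, _ = quad(lambda mu: 1.0 / (np.pi * mu**3), 100.0, np.inf)  # J1^2 ~ 1/(pi*mu)
    return float(np.sqrt(np.pi) * (val + tail))


# ---------------------------------------------------------------------------
# dimensionless time and diffusion length
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "t, alpha, a, expected",
    [
        (0.0, 0.25, 0.3, 0.0),
        (2.0, 0.1, 0.4472135954999579, 1.0),  # a^2 = alpha * t
        (2.0, 0.1, 0.254, 3.100006200012400),  # 0.2 / 0.254**2
    ],
)
def test_dimensionless_time_values(t, alpha, a, expected):
    assert dimensionless_time(t, alpha, a) == pytest.approx(expected, rel=1e-12)


def test_dimensionless_time_rejects_bad_parameters():
    with pytest.raises(InvalidParameterError):
        dimensionless_time(1.0, -0.1, 0.3)
    with pytest.raises(InvalidParameterError):
        dimensionless_time(1.0, 0.1, 0.0)
    with pytest.raises(InvalidParameterError):
        dimensionless_time(-1.0, 0.1, 0.3)


def test_diffusion_length_protocol_value():
    """2 s at alpha = 0.1 mm^2/s probes ~450 um of tissue (447 um unrounded)."""
    lam = diffusion_length(0.1, 2.0)
    assert lam == pytest.approx(447.2135955, rel=1e-9)
    assert round(lam, -1) == 450.0


def test_diffusion_length_square_root_law():
    assert diffusion_length(0.1, 0.0) == 0.0
    assert diffusion_length(0.1, 4.0) == pytest.approx(2 * diffusion_length(0.1, 1.0))
    assert diffusion_length(0.1, 2.0, pi_factor=2.0) == pytest.approx(
        2 * diffusion_length(0.1, 2.0)
    )
    with pytest.raises(InvalidParameterError):
        diffusion_length(-0.1, 2.0)


# ---------------------------------------------------------------------------
# shape function
# ---------------------------------------------------------------------------


def test_shape_function_zero_and_negative():
    assert shape_function(0.0) == 0.0
    with pytest.raises(InvalidParameterError):
        shape_function(-0.5)


def test_shape_function_monotone_nonnegative():
    tau = np.geomspace(1e-4, 150, 400)
    d = shape_function(tau)
    assert np.all(d >= 0)
    assert np.all(np.diff(d) >= 0)


@pytest.mark.parametrize("tau", [0.1, 0.3, 1.0, 3.0, 10.0])
def test_shape_function_matches_brute_force(tau):
    """Table and adaptive-quadrature paths agree with an independent nested
    quadrature to well inside 0.1%."""
    oracle = brute_force_shape(tau)
    assert shape_function(tau) == pytest.approx(oracle, rel=1e-3)
    assert shape_function(tau, method="quad") == pytest.approx(oracle, rel=1e-3)


@pytest.mark.parametrize("tau", [0.05, 0.5, 2.0, 3.1, 20.0])
def test_shape_function_matches_hankel_identity(tau):
    """Agreement with the Hankel-space disc-average identity to 1e-5."""
    assert shape_function(tau) == pytest.approx(hankel_shape(tau), rel=1e-5)


def test_shape_function_steady_limit():
    """For large tau, D approaches 4/(3 sqrt(pi)): the steady mean rise of a
    uniformly powered disc embedded in an infinite medium,
    dT = 4 P0/(3 pi^2 a k)."""
    assert STEADY_STATE_D == pytest.approx(4 / (3 * np.sqrt(np.pi)), rel=1e-15)
    assert shape_function(5e4) == pytest.approx(STEADY_STATE_D, rel=2e-4)


# ---------------------------------------------------------------------------
# mean temperature rise
# ---------------------------------------------------------------------------


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    p0=st.floats(1e-4, 0.1),
    k=st.floats(0.1, 1.2),
    scale=st.floats(0.5, 4.0),
)
def test_rise_scaling_laws(p0, k, scale):
    """Homogeneity: degree 1 in P0, degree -1 in k at fixed tau."""
    times = np.linspace(0.05, 2.0, 20)
    alpha = 0.1
    cfg = SensorConfig(0.5, 0.254, p0, 2.0)
    base = mean_temperature_rise(ThermalProperties(k, alpha), cfg, times)
    cfg2 = SensorConfig(0.5, 0.254, scale * p0, 2.0)
    np.testing.assert_allclose(
        mean_temperature_rise(ThermalProperties(k, alpha), cfg2, times), scale * base, rtol=1e-12
    )
    # scaling k alone at the same alpha keeps tau fixed: rise scales as 1/k
    np.testing.assert_allclose(
        mean_temperature_rise(ThermalProperties(scale * k, alpha), cfg, times),
        base / scale,
        rtol=1e-12,
    )


def test_rise_water_curve_matches_quadrature(sensor):
    """Forward curve for water-like properties (k = 0.6 W/m/K) agrees with
    the per-point quadrature path to <= 0.1%."""
    water = ThermalProperties(k=0.6, alpha=0.1434)
    times = np.array([0.1, 0.5, 1.0, 2.0])
    fast = mean_temperature_rise(water, sensor, times)
    slow = mean_temperature_rise(water, sensor, times, method="quad")
    np.testing.assert_allclose(fast, slow, rtol=1e-3)
    assert np.all(np.diff(fast) > 0)


# ---------------------------------------------------------------------------
# simplified erfc model
# ---------------------------------------------------------------------------


def test_simplified_rise_limits():
    consts = SimplifiedFitConstants(a1=1.3, a2=0.4)
    k, alpha, p0, t_inf = 0.5, 0.12, 5e-3, 295.0
    assert simplified_rise(0.0, consts, k, alpha, p0, t_inf) == pytest.approx(t_inf)
    plateau = t_inf + consts.a1 * p0 / (2 * np.pi * consts.a2 * 1e-3 * k)
    assert simplified_rise(1e14, consts, k, alpha, p0, t_inf) == pytest.approx(plateau, rel=1e-8)
    t = np.geomspace(1e-3, 10, 200)
    temps = simplified_rise(t, consts, k, alpha, p0, t_inf)
    assert np.all(np.diff(temps) >= 0) and temps[-1] > temps[0]


def test_simplified_model_tracks_exact_model(sensor, porcine_props):
    """With (A1, A2) calibrated on an exact-model curve, the erfc model stays
    within a few percent of the peak rise over [0.1 s, 2 s]."""
    from epitherm.inversion import fit_simplified_constants

    times = np.linspace(0.01, 2.0, 200)
    exact = mean_temperature_rise(porcine_props, sensor, times)
    curve = TransientCurve(times, exact)
    consts = fit_simplified_constants(curve, sensor, porcine_props)
    window = times >= 0.1
    approx = simplified_rise(
        times[window], consts, porcine_props.k, porcine_props.alpha, sensor.power, t_inf=0.0
    )
    max_dev = np.max(np.abs(approx - exact[window]))
    assert max_dev < 0.05 * exact.max()


# ---------------------------------------------------------------------------
# domain-type validation
# ---------------------------------------------------------------------------


def test_thermal_properties_invariants():
    props = ThermalProperties(k=0.6, alpha=0.1434)
    assert props.rho_cp == pytest.approx(0.6 / 0.1434e-6, rel=1e-12)
    for bad in ({"k": -1, "alpha": 0.1}, {"k": 0.4, "alpha": 0.0}, {"k": 0.0, "alpha": 0.1}):
        with pytest.raises(InvalidParameterError):
            ThermalProperties(**bad)


def test_sensor_config_validation():
    with pytest.raises(InvalidParameterError):
        SensorConfig(true_radius=0.5, effective_radius=0.6, power=1e-3, duration=2.0)
    with pytest.raises(InvalidParameterError):
        SensorConfig(true_radius=0.5, effective_radius=0.25, power=0.0, duration=2.0)
    cfg = SensorConfig.from_power_density(0.5, 0.254, 7e-3, 2.0)
    assert cfg.power == pytest.approx(7e-3 * np.pi * 0.25, rel=1e-12)
    assert cfg.power_density == pytest.approx(7e-3, rel=1e-12)


def test_transient_curve_validation():
    with pytest.raises(InvalidParameterError):
        TransientCurve(times=np.array([0.0, 0.2, 0.1]), delta_T=np.zeros(3))
    with pytest.raises(InvalidParameterError):
        TransientCurve(times=np.array([0.0, 0.1]), delta_T=np.array([0.0, np.nan]))
    with pytest.raises(InvalidParameterError):
        TransientCurve(times=np.array([-0.1, 0.1]), delta_T=np.zeros(2))
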