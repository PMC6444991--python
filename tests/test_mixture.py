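"""Effective-medium tests: rule-of-mixtures relations with the skin/water
constants, unit-cell conduction against the mixture bounds, the volumetric
heat-capacity balance, and the sign structure of d(alpha)/dx."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epitherm.mixture import (
    SKIN_WATER,
    InvalidParameterError,
    Phase,
    PhasePair,
    UnitCell,
    diffusivity_curve,
    diffusivity_slope,
    k_mixture_bounds,
    max_fill,
    mixture_density,
    mixture_specific_heat,
    property_table,
    rho_cp_slope,
    unit_cell_k,
    unit_cell_rho_cp,
    volumetric_rho_cp,
)


# ---------------------------------------------------------------------------
# rule-of-mixtures algebra
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "x, rho, cp",
    [(0.0, 900.0, 1500.0), (1.0, 1000.0, 4200.0), (0.5, 950.0, 2850.0)],
)
def test_linear_mixtures(x, rho, cp):
    assert mixture_density(x) == pytest.approx(rho)
    assert mixture_specific_heat(x) == pytest.approx(cp)


def test_mixture_rejects_out_of_range():
    with pytest.raises(InvalidParameterError):
        mixture_density(1.2)
    with pytest.raises(InvalidParameterError):
        mixture_specific_heat(-0.1)


def test_rho_cp_slope_components():
    """d(rho*Cp)/dx = (drho/dx)Cp + (dCp/dx)rho: (100*1500, 2700*900) at x=0
    and (100*4200, 2700*1000) at x=1; the Cp term dominates at both ends."""
    d0, c0 = rho_cp_slope(0.0)
    assert d0 == pytest.approx(100 * 1500, rel=1e-12)
    assert c0 == pytest.approx(2.43e6, rel=1e-12)
    d1, c1 = rho_cp_slope(1.0)
    assert d1 == pytest.approx(4.2e5, rel=1e-12)
    assert c1 == pytest.approx(2.7e6, rel=1e-12)
    assert c0 > d0 and c1 > d1


def test_k_mixture_bounds_examples():
    lo0, up0 = k_mixture_bounds(0.0)
    assert lo0 == up0 == pytest.approx(0.2)
    lo1, up1 = k_mixture_bounds(1.0)
    assert lo1 == up1 == pytest.approx(0.6)
    lo, up = k_mixture_bounds(0.5)
    assert lo == pytest.approx(0.3, rel=1e-12)  # harmonic: 2/(1/0.2 + 1/0.6)
    assert up == pytest.approx(0.4, rel=1e-12)  # arithmetic


@settings(max_examples=40, deadline=None, derandomize=True)
@given(x=st.floats(0.0, 1.0))
def test_bounds_ordered(x):
    lo, up = k_mixture_bounds(x)
    assert lo <= up + 1e-15


def test_max_fill_values():
    assert max_fill("cylinder-2d") == pytest.approx(np.pi / 4)
    assert round(max_fill("cylinder-2d"), 2) in (0.78, 0.79)
    assert max_fill("sphere-3d") == pytest.approx(np.pi / 6)
    with pytest.raises(InvalidParameterError):
        max_fill("torus")
    with pytest.raises(InvalidParameterError):
        UnitCell(x_cell=0.9, geometry="cylinder-2d")
    with pytest.raises(InvalidParameterError):
        UnitCell(x_cell=0.55, geometry="sphere-3d")


# ---------------------------------------------------------------------------
# unit-cell conduction
# ---------------------------------------------------------------------------


def test_homogeneous_cell_recovers_matrix_k():
    cell = UnitCell(0.0, "cylinder-2d", grid_n=32)
    assert unit_cell_k(cell) == pytest.approx(SKIN_WATER.matrix.k, rel=5e-3)
    cell3 = UnitCell(0.0, "sphere-3d", grid_n=16)
    assert unit_cell_k(cell3) == pytest.approx(SKIN_WATER.matrix.k, rel=5e-3)


@pytest.mark.parametrize("geometry, grid_n", [("cylinder-2d", 64), ("sphere-3d", 32)])
def test_unit_cell_k_within_bounds(geometry, grid_n):
    xs = [0.1, 0.3, 0.5]
    prev = 0.0
    for x in xs:
        k_eff = unit_cell_k(UnitCell(x, geometry, grid_n=grid_n))
        lo, up = k_mixture_bounds(x)
        assert lo - 1e-9 <= k_eff <= up + 1e-9
        assert k_eff > prev  # monotone in x for k_water > k_dry
        prev = k_eff


def test_unit_cell_k_grid_convergence():
    """Self-convergence: doubling the resolution moves k_cell by < 1%."""
    for geometry, n in (("cylinder-2d", 64), ("sphere-3d", 16)):
        coarse = unit_cell_k(UnitCell(0.3, geometry, grid_n=n))
        fine = unit_cell_k(UnitCell(0.3, geometry, grid_n=2 * n))
        assert fine == pytest.approx(coarse, rel=0.01)


def test_unit_cell_k_scale_invariance():
    a = unit_cell_k(UnitCell(0.3, "cylinder-2d", d_cell=1.0, grid_n=48))
    b = unit_cell_k(UnitCell(0.3, "cylinder-2d", d_cell=2.5, grid_n=48))
    assert a == pytest.approx(b, rel=1e-12)


def test_unit_cell_rho_cp_matches_volume_mixture():
    """The adiabatic energy balance reproduces the volumetric rule of
    mixtures within 1%, identically in 2D and 3D, and is independent of the
    injected heat."""
    for x in (0.1, 0.3, 0.5):
        c2 = UnitCell(x, "cylinder-2d", grid_n=64)
        c3 = UnitCell(x, "sphere-3d", grid_n=32)
        expected = volumetric_rho_cp(x)
        r2 = unit_cell_rho_cp(c2)
        r3 = unit_cell_rho_cp(c3)
        assert r2 == pytest.approx(expected, rel=0.01)
        assert r3 == pytest.approx(expected, rel=0.01)
        assert r2 == pytest.approx(r3, rel=0.01)
        assert unit_cell_rho_cp(c2, q_cell=7.3) == pytest.approx(r2, rel=1e-12)
    with pytest.raises(InvalidParameterError):
        unit_cell_rho_cp(UnitCell(0.1, grid_n=16), q_cell=0.0)


# ---------------------------------------------------------------------------
# diffusivity
# ---------------------------------------------------------------------------


def test_diffusivity_endpoints():
    al = diffusivity_curve([0.0, 1.0])
    assert al[0] == pytest.approx(0.2 / (900 * 1500) * 1e6, rel=1e-12)
    assert al[1] == pytest.approx(0.6 / (1000 * 4200) * 1e6, rel=1e-12)


def test_diffusivity_monotone_with_mixture_k_but_dips_with_cell_k():
    """With arithmetic rule-of-mixtures k the diffusivity decreases
    monotonically; the numerically computed unit-cell k(x) produces an
    interior minimum near x ~ 0.5."""
    xs = np.round(np.arange(0.05, 0.76, 0.05), 2)
    mono = diffusivity_curve(xs)
    assert np.all(np.diff(mono) < 0)
    ks = np.array([unit_cell_k(UnitCell(float(x), "cylinder-2d", grid_n=64)) for x in xs])
    dips = diffusivity_curve(xs, k_of_x=ks)
    slopes = np.diff(dips) / np.diff(xs)
    mids = 0.5 * (xs[:-1] + xs[1:])
    assert np.all(slopes[mids < 0.5] < 0)
    assert np.all(slopes[mids > 0.55] > 0)
    assert 0.35 <= xs[np.argmin(dips)] <= 0.6


def test_diffusivity_curve_length_mismatch():
    with pytest.raises(InvalidParameterError):
        diffusivity_curve([0.1, 0.2], k_of_x=[0.3])


def test_diffusivity_slope_signs_and_balance():
    cp0 = mixture_specific_heat(0.2)
    k0 = 0.25
    # balance point: dk/dx = k * (dCp/dx)/Cp gives exactly zero slope
    balanced = k0 * 2700.0 / cp0
    assert diffusivity_slope(0.2, k=k0, dk_dx=balanced) == pytest.approx(0.0, abs=1e-15)
    assert diffusivity_slope(0.2, k=k0, dk_dx=0.5 * balanced) < 0
    assert diffusivity_slope(0.2, k=k0, dk_dx=2.0 * balanced) > 0


def test_diffusivity_slope_exact_at_constant_density():
    """When both phases genuinely share the averaged density, the
    constant-density quotient rule is the exact derivative: compare against
    a central difference of the diffusivity curve itself."""
    pair = PhasePair(matrix=Phase(950.0, 1500.0, 0.2), inclusion=Phase(950.0, 4200.0, 0.6))
    dk_dx = pair.inclusion.k - pair.matrix.k
    h = 1e-6
    for x in (0.1, 0.4, 0.8):
        _, k_here = k_mixture_bounds(x, pair)
        analytic = diffusivity_slope(x, pair, k=k_here, dk_dx=dk_dx, rho_bar=950.0)
        lo, hi = diffusivity_curve([x - h, x + h], pair)
        assert analytic == pytest.approx((hi - lo) / (2 * h), rel=1e-6)


# ---------------------------------------------------------------------------
# table and validation
# ---------------------------------------------------------------------------


def test_property_table_shape_and_nan_masking():
    table = property_table([0.0, 0.3, 0.6], grid_n_2d=32, grid_n_3d=16)
    assert list(table["x"]) == [0.0, 0.3, 0.6]
    assert np.isnan(table.loc[2, "k_3d_W_per_mK"])  # 0.6 > pi/6
    assert table.loc[2, "k_2d_W_per_mK"] > 0
    assert np.all(np.diff(table["rho_cp_J_per_m3K"]) > 0)


def test_phase_validation():
    with pytest.raises(InvalidParameterError):
        Phase(rho=-1, cp=1500, k=0.2)
    pair = PhasePair(matrix=Phase(900, 1500, 0.2), inclusion=Phase(1000, 4200, 0.6))
    assert pair.matrix.rho_cp == pytest.approx(1.35e6)
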