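"""Two-phase effective-medium models of hydrated epidermis.

The outer epidermis is treated as a periodic array of square (2D) or cubic
(3D) unit cells of dry-skin matrix containing a water inclusion — a cylinder
in 2D, a sphere in 3D — occupying volume fraction ``x``.  The cell-level
properties then stand in for the bulk:

* volumetric heat capacity from an adiabatic energy balance (exactly the
  volumetric rule of mixtures);
* conductivity from a steady two-phase conduction solve with two opposite
  faces held at fixed temperatures, bracketed by the arithmetic (rule of
  mixtures) and harmonic (inverse rule of mixtures) bounds;
* diffusivity as their ratio, ``alpha(x) = k(x) / (rho*Cp)(x)``, which is
  non-monotone in ``x`` when the numerically computed ``k(x)`` is used: heat
  capacity rises faster than conductivity below ``x ~ 0.5`` and slower above.

The steady solve uses a regular-grid finite-volume discretization with
harmonic face averaging of the conductivity (flux-conservative across the
phase interface) and a sparse direct solve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import LinearOperator, cg, spsolve

from epitherm.tps import InvalidParameterError

__all__ = [
    "Phase",
    "PhasePair",
    "UnitCell",
    "SKIN_WATER",
    "mixture_density",
    "mixture_specific_heat",
    "rho_cp_slope",
    "volumetric_rho_cp",
    "k_mixture_bounds",
    "max_fill",
    "unit_cell_k",
    "unit_cell_rho_cp",
    "diffusivity_curve",
    "diffusivity_slope",
    "property_table",
]

Geometry = Literal["cylinder-2d", "sphere-3d"]


@dataclass(frozen=True)
class Phase:
    """One material phase: density (kg/m^3), specific heat (J/kg/K),
    conductivity (W/m/K)."""

    rho: float
    cp: float
    k: float

    def __post_init__(self) -> None:
        if not (self.rho > 0 and self.cp > 0 and self.k > 0):
            raise InvalidParameterError(f"phase properties must all be > 0: {self}")

    @property
    def rho_cp(self) -> float:
        return self.rho * self.cp


@dataclass(frozen=True)
class PhasePair:
    """Matrix (dry skin) and inclusion (water) phases of the unit cell."""

    matrix: Phase
    inclusion: Phase


#: Literature constants for the dry-skin matrix and water: densities 900 and
#: 1000 kg/m^3, specific heats 1500 and 4200 J/kg/K, conductivities 0.2 and
#: 0.6 W/m/K.
SKIN_WATER = PhasePair(
    matrix=Phase(rho=900.0, cp=1500.0, k=0.2),
    inclusion=Phase(rho=1000.0, cp=4200.0, k=0.6),
)


def max_fill(geometry: Geometry) -> float:
    """Maximum geometric fill factor of the inclusion.

    pi/4 ~ 78% for a cylinder inscribed in a square, pi/6 ~ 52% for a sphere
    inscribed in a cube.
    """
    if geometry == "cylinder-2d":
        return float(np.pi / 4.0)
    if geometry == "sphere-3d":
        return float(np.pi / 6.0)
    raise InvalidParameterError(f"unknown geometry {geometry!r}")


@dataclass(frozen=True)
class UnitCell:
    """Square/cubic two-phase cell with a centred inclusion.

    ``x_cell`` is the water volume fraction (0 = dry skin); ``d_cell`` the
    side length in mm; ``grid_n`` the finite-volume resolution per axis.
    """

    x_cell: float
    geometry: Geometry = "cylinder-2d"
    d_cell: float = 1.0  # mm
    grid_n: int = 64

    def __post_init__(self) -> None:
        limit = max_fill(self.geometry)
        if not 0.0 <= self.x_cell <= limit:
            raise InvalidParameterError(
                f"x_cell={self.x_cell} outside [0, {limit:.4f}] for {self.geometry}"
            )
        if self.grid_n < 16:
            raise InvalidParameterError("grid_n must be >= 16")
        if not self.d_cell > 0:
            raise InvalidParameterError("d_cell must be > 0")

    @property
    def ndim(self) -> int:
        return 2 if self.geometry == "cylinder-2d" else 3

    @property
    def inclusion_radius(self) -> float:
        """Inclusion radius (mm) from the volume fraction:
        x = pi r^2/d^2 in 2D, x = (4/3) pi r^3/d^3 in 3D."""
        if self.ndim == 2:
            return self.d_cell * float(np.sqrt(self.x_cell / np.pi))
        return self.d_cell * float((3.0 * self.x_cell / (4.0 * np.pi)) ** (1.0 / 3.0))

    def inclusion_mask(self) -> np.ndarray:
        """Boolean array marking cells whose centre lies inside the inclusion."""
        n, d = self.grid_n, self.d_cell
        h = d / n
        centers = (np.arange(n) + 0.5) * h - d / 2.0
        grids = np.meshgrid(*([centers] * self.ndim), indexing="ij")
        r2 = sum(g * g for g in grids)
        return r2 <= self.inclusion_radius**2


# ---------------------------------------------------------------------------
# rule-of-mixtures relations
# ---------------------------------------------------------------------------


def _check_fraction(x) -> np.ndarray:
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0) or np.any(x_arr > 1):
        raise InvalidParameterError("water fraction must lie in [0, 1]")
    return x_arr


def mixture_density(x, phases: PhasePair = SKIN_WATER):
    """Linear mixture density rho(x), kg/m^3 (900 + 100 x for skin/water)."""
    x_arr = _check_fraction(x)
    out = phases.matrix.rho + (phases.inclusion.rho - phases.matrix.rho) * x_arr
    return float(out) if np.isscalar(x) else out


def mixture_specific_heat(x, phases: PhasePair = SKIN_WATER):
    """Linear mixture specific heat Cp(x), J/kg/K (1500 + 2700 x)."""
    x_arr = _check_fraction(x)
    out = phases.matrix.cp + (phases.inclusion.cp - phases.matrix.cp) * x_arr
    return float(out) if np.isscalar(x) else out


def volumetric_rho_cp(x, phases: PhasePair = SKIN_WATER):
    """Volumetric mixture of the phase heat capacities, J/m^3/K.

    (1-x) * rho_m*Cp_m + x * rho_w*Cp_w — the exact equilibrium value for a
    two-phase cell, and what the adiabatic unit-cell computation returns.
    """
    x_arr = _check_fraction(x)
    out = phases.matrix.rho_cp + (phases.inclusion.rho_cp - phases.matrix.rho_cp) * x_arr
    return float(out) if np.isscalar(x) else out


def rho_cp_slope(x, phases: PhasePair = SKIN_WATER) -> tuple:
    """d(rho*Cp)/dx of the product form rho(x)*Cp(x), split into components.

    Returns ``(density_term, cp_term)`` where the density term is
    (drho/dx)*Cp(x) and the cp term is (dCp/dx)*rho(x); their sum is the
    slope.  For the skin/water constants the Cp term dominates at both
    endpoints, by two orders of magnitude at x=0 and one at x=1.
    """
    x_arr = _check_fraction(x)
    d_rho = phases.inclusion.rho - phases.matrix.rho
    d_cp = phases.inclusion.cp - phases.matrix.cp
    density_term = d_rho * mixture_specific_heat(x_arr, phases)
    cp_term = d_cp * mixture_density(x_arr, phases)
    if np.isscalar(x):
        return float(density_term), float(cp_term)
    return density_term, cp_term


def k_mixture_bounds(x, phases: PhasePair = SKIN_WATER) -> tuple:
    """(lower, upper) conductivity bounds, W/m/K.

    Upper = arithmetic (rule of mixtures), lower = harmonic (inverse rule of
    mixtures); any isotropic two-phase arrangement falls in between.
    """
    x_arr = _check_fraction(x)
    km, ki = phases.matrix.k, phases.inclusion.k
    upper = (1.0 - x_arr) * km + x_arr * ki
    lower = 1.0 / ((1.0 - x_arr) / km + x_arr / ki)
    if np.isscalar(x):
        return float(lower), float(upper)
    return lower, upper


# ---------------------------------------------------------------------------
# unit-cell finite-volume computations
# ---------------------------------------------------------------------------


def _conductivity_field(cell: UnitCell, phases: PhasePair) -> np.ndarray:
    k = np.full((cell.grid_n,) * cell.ndim, phases.matrix.k)
    k[cell.inclusion_mask()] = phases.inclusion.k
    return k


def _solve_steady(k_field: np.ndarray, h: float) -> tuple[np.ndarray, float]:
    """Steady conduction with T=0 / T=1 Dirichlet on the two faces normal to
    axis 0 and insulated elsewhere.  Returns (T, total heat flow in W per
    metre of depth in 2D / W in 3D, for h in metres).

    Finite volume on cell centres; face conductance uses the harmonic mean of
    the adjacent cell conductivities so flux stays continuous across the
    phase interface.
    """
    shape = k_field.shape
    ndim = k_field.ndim
    n_cells = k_field.size
    idx = np.arange(n_cells).reshape(shape)
    area = h ** (ndim - 1)

    rows, cols, vals = [], [], []
    diag = np.zeros(n_cells)
    rhs = np.zeros(n_cells)

    for axis in range(ndim):
        sl_lo = [slice(None)] * ndim
        sl_hi = [slice(None)] * ndim
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        k_lo = k_field[tuple(sl_lo)]
        k_hi = k_field[tuple(sl_hi)]
        g = 2.0 * k_lo * k_hi / (k_lo + k_hi) * area / h  # harmonic mean
        i_lo = idx[tuple(sl_lo)].ravel()
        i_hi = idx[tuple(sl_hi)].ravel()
        g_flat = g.ravel()
        rows.extend([i_lo, i_hi])
        cols.extend([i_hi, i_lo])
        vals.extend([-g_flat, -g_flat])
        np.add.at(diag, i_lo, g_flat)
        np.add.at(diag, i_hi, g_flat)

    # Dirichlet faces on axis 0: half-cell distance to the boundary
    first = [slice(None)] * ndim
    last = [slice(None)] * ndim
    first[0] = 0
    last[0] = -1
    for face_slice, t_bc in ((first, 0.0), (last, 1.0)):
        i_b = idx[tuple(face_slice)].ravel()
        g_b = (k_field[tuple(face_slice)] * area / (h / 2.0)).ravel()
        np.add.at(diag, i_b, g_b)
        rhs[i_b] += g_b * t_bc

    rows.append(np.arange(n_cells))
    cols.append(np.arange(n_cells))
    vals.append(diag)
    mat = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_cells, n_cells),
    )
    if n_cells <= 20000:
        temp = spsolve(mat, rhs)
        ok = bool(np.all(np.isfinite(temp)))
    else:
        # large 3-D systems: the matrix is SPD, so Jacobi-preconditioned CG
        # is much cheaper than a direct factorization
        precond = LinearOperator(mat.shape, matvec=lambda x: x / diag)
        temp, info = cg(mat, rhs, rtol=1e-10, atol=0.0, maxiter=5000, M=precond)
        ok = info == 0 and bool(np.all(np.isfinite(temp)))
    if not ok:
        raise RuntimeError(
            f"steady conduction solve failed on grid {shape}; check the conductivity field"
        )
    temp = temp.reshape(shape)

    # heat entering through the hot face (T = 1)
    g_hot = k_field[tuple(last)] * area / (h / 2.0)
    q_dot = float(np.sum(g_hot * (1.0 - temp[tuple(last)])))
    return temp, q_dot


def unit_cell_k(cell: UnitCell, phases: PhasePair = SKIN_WATER) -> float:
    """Effective conductivity of the two-phase cell, W/m/K.

    Solves steady conduction with unit temperature difference across the
    cell and converts the area-normalised heat flux back through Fourier's
    law, ``k_cell = q_dot * d / (A * dT)``.  Scale-invariant in ``d_cell``
    and always inside :func:`k_mixture_bounds`.
    """
    h_m = cell.d_cell * 1e-3 / cell.grid_n
    k_field = _conductivity_field(cell, phases)
    _, q_dot = _solve_steady(k_field, h_m)
    d_m = cell.d_cell * 1e-3
    area_m = d_m ** (cell.ndim - 1)
    return q_dot * d_m / (area_m * 1.0)


def unit_cell_rho_cp(cell: UnitCell, phases: PhasePair = SKIN_WATER, q_cell: float = 1.0) -> float:
    """Effective volumetric heat capacity of the adiabatic cell, J/m^3/K.

    Injects ``q_cell`` joules into the insulated cell, computes the
    equilibrium temperature rise from the energy balance
    ``dT = Q / sum(rho_i Cp_i V_i)`` (exact at equilibrium — no time stepping
    needed), and returns ``Q / (dT * V)``.  Independent of ``q_cell``.
    """
    if not q_cell > 0:
        raise InvalidParameterError("q_cell must be > 0")
    mask = cell.inclusion_mask()
    v_cell = (cell.d_cell * 1e-3) ** cell.ndim
    v_sub = v_cell / mask.size
    heat_capacity = v_sub * (
        mask.sum() * phases.inclusion.rho_cp + (mask.size - mask.sum()) * phases.matrix.rho_cp
    )
    delta_t = q_cell / heat_capacity
    return q_cell / (delta_t * v_cell)


# ---------------------------------------------------------------------------
# diffusivity
# ---------------------------------------------------------------------------


def diffusivity_curve(
    x_values: Sequence[float],
    phases: PhasePair = SKIN_WATER,
    k_of_x: Sequence[float] | None = None,
) -> np.ndarray:
    """alpha(x) = k(x) / (rho*Cp)(x) in mm^2/s.

    ``k_of_x`` supplies the per-x conductivities (e.g. from
    :func:`unit_cell_k`); when omitted the arithmetic rule of mixtures is
    used.  The denominator is the volumetric mixture of the phase heat
    capacities.  With rule-of-mixtures k the curve is strictly monotone;
    the numerically computed unit-cell k(x) produces an interior minimum
    near x ~ 0.5.
    """
    x_arr = _check_fraction(np.asarray(x_values, dtype=float))
    if k_of_x is None:
        _, k_arr = k_mixture_bounds(x_arr, phases)
    else:
        k_arr = np.asarray(k_of_x, dtype=float)
        if k_arr.shape != x_arr.shape:
            raise InvalidParameterError("x_values and k_of_x must have the same length")
    return k_arr / volumetric_rho_cp(x_arr, phases) * 1e6  # m^2/s -> mm^2/s


def diffusivity_slope(
    x: float,
    phases: PhasePair = SKIN_WATER,
    k: float = None,
    dk_dx: float = None,
    rho_bar: float = 950.0,
) -> float:
    """d(alpha)/dx under the constant-density approximation, mm^2/s per unit x.

    Uses the quotient rule with rho held at the averaged value ``rho_bar``:

        d(alpha)/dx = [rho_bar*Cp(x)*dk/dx - k*rho_bar*dCp/dx] / (rho_bar*Cp(x))^2

    The sign flips where k's fractional growth overtakes Cp's: negative while
    ``k * dCp/dx > Cp * dk/dx`` and positive beyond.
    """
    _check_fraction(x)
    if k is None or dk_dx is None:
        raise InvalidParameterError("k and dk_dx are required")
    cp = mixture_specific_heat(x, phases)
    d_cp = phases.inclusion.cp - phases.matrix.cp
    num = rho_bar * cp * dk_dx - k * rho_bar * d_cp
    return num / (rho_bar * cp) ** 2 * 1e6  # m^2/s -> mm^2/s


def property_table(
    x_values: Sequence[float],
    phases: PhasePair = SKIN_WATER,
    grid_n_2d: int = 64,
    grid_n_3d: int = 32,
    d_cell: float = 1.0,
) -> pd.DataFrame:
    """Tabulate (x, rho, Cp, rho*Cp, k_2D, k_3D, alpha_2D, alpha_3D).

    x values above a geometry's maximum fill factor get NaN in that
    geometry's columns.
    """
    x_arr = _check_fraction(np.asarray(x_values, dtype=float))
    rows = []
    for x in x_arr:
        row = {
            "x": x,
            "rho_kg_per_m3": mixture_density(float(x), phases),
            "cp_J_per_kgK": mixture_specific_heat(float(x), phases),
            "rho_cp_J_per_m3K": volumetric_rho_cp(float(x), phases),
        }
        for label, geometry, n in (("2d", "cylinder-2d", grid_n_2d), ("3d", "sphere-3d", grid_n_3d)):
            if x <= max_fill(geometry):
                cell = UnitCell(float(x), geometry=geometry, d_cell=d_cell, grid_n=n)
                k_eff = unit_cell_k(cell, phases)
                row[f"k_{label}_W_per_mK"] = k_eff
                row[f"alpha_{label}_mm2_per_s"] = k_eff / row["rho_cp_J_per_m3K"] * 1e6
            else:
                row[f"k_{label}_W_per_mK"] = np.nan
                row[f"alpha_{label}_mm2_per_s"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
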