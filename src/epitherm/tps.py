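"""Forward models for transient plane source (TPS) measurements on skin.

A TPS element is a thin resistive disc that Joule-heats the medium beneath it
while simultaneously reporting its own spatially averaged temperature through
the temperature coefficient of resistance of the metal.  For a disc of radius
``a`` dissipating total power ``P0`` into a semi-infinite medium of thermal
conductivity ``k`` and diffusivity ``alpha``, the mean temperature rise is

    dT(tau) = P0 * pi**(-3/2) / (a * k) * D(tau),        tau = t * alpha / a**2

where ``D`` is a dimensionless shape function given by a triple integral over
the disc geometry with a modified-Bessel-function kernel.  Both ``k`` and
``alpha`` shape the transient, which is what makes the inverse problem posed
in :mod:`epitherm.inversion` possible; their ratio gives the volumetric heat
capacity ``rho*Cp = k/alpha``.

This module provides the exact shape function (adaptive quadrature and a
precomputed monotone interpolation table), the resulting mean-temperature-rise
curve, the thermal diffusion length that sets the probing depth, and a
simplified complementary-error-function model used for high-throughput fitting
of clinical data.

Units
-----
Public interfaces use the sensor-scale units conventional in this field:
radii in mm, diffusivity in mm^2/s, conductivity in W/(m K), power in W,
time in s, temperature in K, diffusion length in um.  Conversions to SI happen
internally at the point of use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_simpson, quad
from scipy.interpolate import PchipInterpolator
from scipy.special import erfc, ive

__all__ = [
    "InvalidParameterError",
    "QuadratureError",
    "ThermalProperties",
    "SensorConfig",
    "TransientCurve",
    "SimplifiedFitConstants",
    "dimensionless_time",
    "shape_function",
    "mean_temperature_rise",
    "diffusion_length",
    "simplified_rise",
    "STEADY_STATE_D",
]

MM_TO_M = 1e-3
MM2_TO_M2 = 1e-6

#: Large-time limit of the shape function, D(inf) = 4/(3*sqrt(pi)).
#: The model describes a uniformly powered disc embedded in an infinite
#: medium (the classic hot-disk geometry: the element feeds both sides), so
#: the steady mean rise is dT_inf = 4*P0/(3*pi**2*a*k) — half the value
#: 8*P0/(3*pi**2*a*k) of a disc feeding a single half-space.  On skin the
#: calibrated effective radius absorbs this geometric prefactor.
STEADY_STATE_D = 4.0 / (3.0 * np.sqrt(np.pi))


class InvalidParameterError(ValueError):
    """A physical parameter is outside its admissible range."""


class QuadratureError(RuntimeError):
    """The shape-function quadrature failed to converge."""


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThermalProperties:
    """Bulk thermal transport properties of an effectively homogeneous medium.

    Parameters
    ----------
    k : float
        Thermal conductivity, W m^-1 K^-1.
    alpha : float
        Thermal diffusivity, mm^2 s^-1.
    """

    k: float
    alpha: float

    def __post_init__(self) -> None:
        if not (self.k > 0 and np.isfinite(self.k)):
            raise InvalidParameterError(f"thermal conductivity must be > 0, got {self.k}")
        if not (self.alpha > 0 and np.isfinite(self.alpha)):
            raise InvalidParameterError(f"thermal diffusivity must be > 0, got {self.alpha}")

    @property
    def rho_cp(self) -> float:
        """Volumetric heat capacity k/alpha, J m^-3 K^-1."""
        return self.k / (self.alpha * MM2_TO_M2)


@dataclass(frozen=True)
class SensorConfig:
    """Geometry and actuation of one TPS element.

    The *effective* radius is the calibrated radius that absorbs deviations of
    the real layered device from the ideal disc-on-half-space model; for this
    sensor class it is roughly half the lithographic (true) radius.
    """

    true_radius: float  # mm
    effective_radius: float  # mm
    power: float  # total applied power P0, W
    duration: float  # actuation time, s

    def __post_init__(self) -> None:
        if not 0 < self.effective_radius <= self.true_radius:
            raise InvalidParameterError(
                "require 0 < effective_radius <= true_radius, got "
                f"{self.effective_radius} / {self.true_radius} mm"
            )
        if not self.power > 0:
            raise InvalidParameterError(f"power must be > 0, got {self.power}")
        if not self.duration > 0:
            raise InvalidParameterError(f"duration must be > 0, got {self.duration}")

    @classmethod
    def from_power_density(
        cls,
        true_radius: float,
        effective_radius: float,
        power_density: float,
        duration: float,
    ) -> "SensorConfig":
        """Build a config from an areal power density in W mm^-2.

        Total power is the density times the true (lithographic) disc area,
        ``P0 = q * pi * true_radius**2``.
        """
        if not power_density > 0:
            raise InvalidParameterError(f"power density must be > 0, got {power_density}")
        p0 = power_density * np.pi * true_radius**2
        return cls(true_radius, effective_radius, p0, duration)

    @property
    def power_density(self) -> float:
        """Areal power density over the true disc, W mm^-2."""
        return self.power / (np.pi * self.true_radius**2)


@dataclass(frozen=True)
class TransientCurve:
    """A sampled temperature-rise record from one actuation.

    ``delta_T`` is the rise above the pre-actuation baseline ``t_inf``.
    """

    times: np.ndarray  # s
    delta_T: np.ndarray  # K
    t_inf: float = 293.15  # baseline temperature, K

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        delta_T = np.asarray(self.delta_T, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "delta_T", delta_T)
        if times.ndim != 1 or delta_T.ndim != 1 or times.size != delta_T.size:
            raise InvalidParameterError("times and delta_T must be 1-D and equally long")
        if times.size and times[0] < 0:
            raise InvalidParameterError("times must start at >= 0")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            bad = int(np.flatnonzero(np.diff(times) <= 0)[0]) + 1
            raise InvalidParameterError(f"times must be strictly increasing (row {bad})")
        if not (np.all(np.isfinite(times)) and np.all(np.isfinite(delta_T))):
            raise InvalidParameterError("curve contains non-finite values")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def span(self) -> float:
        return float(self.times[-1] - self.times[0]) if len(self) else 0.0


@dataclass(frozen=True)
class SimplifiedFitConstants:
    """Constants of the simplified erfc model.

    ``a1`` is a dimensionless scale and ``a2`` an effective length (mm); both
    absorb the layered device geometry, edge effects and convective losses.
    """

    a1: float
    a2: float  # mm

    def __post_init__(self) -> None:
        if not self.a1 > 0:
            raise InvalidParameterError(f"A1 must be > 0, got {self.a1}")
        if not self.a2 > 0:
            raise InvalidParameterError(f"A2 must be > 0, got {self.a2}")


# ---------------------------------------------------------------------------
# shape function D(tau)
# ---------------------------------------------------------------------------

# Quadrature layout.  The inner double integral over the disc coordinates
# (u, v) concentrates on the diagonal u = v with width ~sigma, so we
# substitute v = u + sigma*s: the kernel becomes ive(0, u*v/2sigma^2) *
# exp(-s^2/4), which is order-one and smooth for every sigma.  Gauss-Legendre
# in u and s then converges fast at all sigma.
_N_U = 64
_N_S = 64
_S_MAX = 10.0  # exp(-s^2/4) < 3e-11 beyond this
_SIGMA_MIN = 1e-6  # below this the outer integrand equals 1 to ~1e-6
_TAU_TABLE_MAX = 200.0
_N_TABLE = 2001


@lru_cache(maxsize=8)
def _gauss01(n: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.legendre.leggauss(n)
    return 0.5 * (x + 1.0), 0.5 * w


@lru_cache(maxsize=8)
def _gauss11(n: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.legendre.leggauss(n)
    return x, w


_IVE_ASYMPTOTIC_Z = 1e8


def _ive0(z: np.ndarray) -> np.ndarray:
    """Exponentially scaled I0; scipy's ive loses accuracy (NaN) for very
    large arguments, so switch to the standard asymptotic series there."""
    z = np.asarray(z, dtype=float)
    safe = np.minimum(z, _IVE_ASYMPTOTIC_Z)
    direct = ive(0, safe)
    with np.errstate(divide="ignore"):
        zz = np.maximum(z, 1.0)
        asym = (1.0 + 1.0 / (8.0 * zz) + 9.0 / (128.0 * zz * zz)) / np.sqrt(2.0 * np.pi * zz)
    return np.where(z > _IVE_ASYMPTOTIC_Z, asym, direct)


def _outer_integrand(sigma: float) -> float:
    """Integrand f(sigma) of the outer integral, D(tau) = int_0^tau f.

    f(sigma) = sigma^-2 * int_0^1 int_0^1 u v exp(-(u^2+v^2)/4sigma^2)
               * I0(u v / 2 sigma^2) du dv.
    Tends to 1 as sigma -> 0 and to 1/(4 sigma^2) as sigma -> inf.
    """
    u, wu = _gauss01(_N_U)
    xs, ws = _gauss11(_N_S)
    u = u[:, None]
    lo = np.maximum(-_S_MAX, -u / sigma)
    hi = np.minimum(_S_MAX, (1.0 - u) / sigma)
    s = 0.5 * (hi - lo) * xs[None, :] + 0.5 * (hi + lo)
    w_s = 0.5 * (hi - lo) * ws[None, :]
    v = u + sigma * s
    z = u * v / (2.0 * sigma * sigma)
    vals = u * v * _ive0(z) * np.exp(-0.25 * s * s)
    inner = float(np.sum(wu[:, None] * w_s * vals))
    return inner / sigma


@lru_cache(maxsize=1)
def _shape_table() -> PchipInterpolator:
    """Cumulative integral of f on a geometric sigma grid, as a monotone
    interpolator in log(tau).  Built once per process."""
    sigma = np.geomspace(_SIGMA_MIN, _TAU_TABLE_MAX, _N_TABLE)
    f = np.array([_outer_integrand(s) for s in sigma])
    d = cumulative_simpson(f, x=sigma, initial=0.0)
    d += _SIGMA_MIN  # f ~= 1 on (0, sigma_min]
    return PchipInterpolator(np.log(sigma), d, extrapolate=False)


def shape_function(tau, method: str = "table"):
    """Dimensionless TPS shape function D(tau).

    Parameters
    ----------
    tau : float or array_like
        Dimensionless time, >= 0.
    method : {"table", "quad"}
        "table" (default) evaluates a precomputed monotone interpolant of the
        cumulative outer integral; "quad" runs adaptive quadrature per point
        and serves as the slow reference path.

    Returns
    -------
    float or ndarray
        D(tau); nonnegative, nondecreasing, D(0) = 0, and approaching
        ``STEADY_STATE_D`` = 8/(3 sqrt(pi)) for large tau.
    """
    tau_arr = np.asarray(tau, dtype=float)
    if np.any(~np.isfinite(tau_arr)) or np.any(tau_arr < 0):
        raise InvalidParameterError("tau must be finite and >= 0")
    if method == "table":
        out = _shape_eval_table(tau_arr)
    elif method == "quad":
        out = np.array([_shape_quad(t) for t in np.atleast_1d(tau_arr)]).reshape(tau_arr.shape)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(out) if np.isscalar(tau) or tau_arr.ndim == 0 else out


def _shape_eval_table(tau_arr: np.ndarray) -> np.ndarray:
    table = _shape_table()
    tau_flat = np.atleast_1d(tau_arr).astype(float)
    out = np.empty_like(tau_flat)
    tiny = tau_flat <= _SIGMA_MIN
    big = tau_flat > _TAU_TABLE_MAX
    mid = ~tiny & ~big
    out[tiny] = tau_flat[tiny]  # f ~= 1 near zero
    out[mid] = table(np.log(tau_flat[mid]))
    if np.any(big):
        d_max = float(table(np.log(_TAU_TABLE_MAX)))
        # tail: f ~ 1/(4 sigma^2)
        out[big] = d_max + 0.25 * (1.0 / _TAU_TABLE_MAX - 1.0 / tau_flat[big])
    return out.reshape(tau_arr.shape)


def _shape_quad(tau: float) -> float:
    if tau <= _SIGMA_MIN:
        return float(tau)
    # split at decades so QUADPACK sees well-scaled panels
    edges = [_SIGMA_MIN]
    e = _SIGMA_MIN
    while e * 10.0 < tau:
        e *= 10.0
        edges.append(e)
    edges.append(tau)
    total = _SIGMA_MIN
    for a, b in zip(edges[:-1], edges[1:]):
        val, err = quad(_outer_integrand, a, b, epsabs=1e-11, epsrel=1e-9, limit=200)
        if not np.isfinite(val) or err > max(1e-6, 1e-4 * abs(val)):
            raise QuadratureError(
                f"outer quadrature failed on [{a:g}, {b:g}]: value {val:g}, error {err:g}"
            )
        total += val
    return total


# ---------------------------------------------------------------------------
# forward curves
# ---------------------------------------------------------------------------


def dimensionless_time(t, alpha: float, a: float):
    """tau = t * alpha / a**2 with t in s, alpha in mm^2/s, a in mm."""
    if not alpha > 0:
        raise InvalidParameterError(f"alpha must be > 0, got {alpha}")
    if not a > 0:
        raise InvalidParameterError(f"radius must be > 0, got {a}")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise InvalidParameterError("time must be >= 0")
    tau = t_arr * alpha / a**2
    return float(tau) if np.isscalar(t) or t_arr.ndim == 0 else tau


def mean_temperature_rise(
    props: ThermalProperties,
    cfg: SensorConfig,
    times: Sequence[float],
    method: str = "table",
) -> np.ndarray:
    """Mean temperature rise of the disc, dT(t) in K, at the given times.

    Linear in the applied power and inversely proportional to k at fixed tau.
    """
    tau = dimensionless_time(np.asarray(times, dtype=float), props.alpha, cfg.effective_radius)
    d = shape_function(tau, method=method)
    a_m = cfg.effective_radius * MM_TO_M
    return cfg.power / (np.pi**1.5 * a_m * props.k) * np.asarray(d)


def diffusion_length(alpha: float, t, pi_factor: float = 1.0):
    """Characteristic thermal diffusion length Lambda = Pi * sqrt(alpha * t), um.

    ``Pi`` is a dimensionless factor of order unity (default 1).  This length
    sets the depth of skin probed by the measurement: ~450 um for a 2 s
    actuation at alpha = 0.1 mm^2/s.
    """
    if alpha < 0 or pi_factor < 0:
        raise InvalidParameterError("alpha and Pi must be >= 0")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise InvalidParameterError("time must be >= 0")
    lam_mm = pi_factor * np.sqrt(alpha * t_arr)
    lam_um = lam_mm * 1e3
    return float(lam_um) if np.isscalar(t) or t_arr.ndim == 0 else lam_um


def simplified_rise(
    t,
    consts: SimplifiedFitConstants,
    k: float,
    alpha: float,
    p0: float,
    t_inf: float = 293.15,
):
    """Simplified erfc model of the sensor temperature, K.

    T(t) = T_inf + A1*P0 / (2*pi*A2*k) * erfc(A2 / (2*sqrt(alpha*t)))

    with A2 an effective distance (mm).  T -> T_inf as t -> 0+ and
    T -> T_inf + A1*P0/(2*pi*A2*k) as t -> inf; monotone increasing between.
    """
    if not (k > 0 and alpha > 0 and p0 > 0):
        raise InvalidParameterError("k, alpha and P0 must be > 0")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise InvalidParameterError("time must be >= 0")
    amp = consts.a1 * p0 / (2.0 * np.pi * consts.a2 * MM_TO_M * k)
    with np.errstate(divide="ignore"):
        arg = np.where(t_arr > 0, consts.a2 / (2.0 * np.sqrt(alpha * np.maximum(t_arr, 1e-300))), np.inf)
    out = t_inf + amp * erfc(arg)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out
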