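"""Inverse TPS analysis: recover (k, alpha) from measured transients.

The central objects follow the model/results pattern: build a
:class:`TPSModel` from a :class:`~epitherm.tps.TransientCurve` and a
:class:`~epitherm.tps.SensorConfig`, call :meth:`TPSModel.fit`, and work with
the returned :class:`TPSResults`, which carries the estimates and exposes the
identifiability diagnostics (perturb-and-refit sensitivity scans, SSE error
surfaces) the method is known for.  The conductivity is strongly identified by
the late, near-steady part of the transient; the diffusivity only enters
through the curve shape, so its uncertainty is roughly an order of magnitude
larger — the error surface is strongly elongated along the alpha axis.

Module-level functions (:func:`fit_tps`, :func:`sensitivity_scan`,
:func:`error_surface`, :func:`calibrate_effective_radius`) are thin wrappers
for script use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize_scalar

from epitherm.tps import (
    MM2_TO_M2,
    InvalidParameterError,
    SensorConfig,
    SimplifiedFitConstants,
    ThermalProperties,
    TransientCurve,
    mean_temperature_rise,
    simplified_rise,
)

__all__ = [
    "DegenerateCurveError",
    "CalibrationConsistencyWarning",
    "ErrorSurface",
    "TPSModel",
    "TPSResults",
    "fit_tps",
    "sensitivity_scan",
    "error_surface",
    "calibrate_effective_radius",
    "volumetric_heat_capacity",
    "fit_simplified_constants",
    "DEFAULT_INIT",
    "DEFAULT_BOUNDS",
]

#: Default initial guess: typical healthy-skin conductivity is 0.3-0.5 W/m/K
#: and representative fits give alpha ~ 0.10 mm^2/s.
DEFAULT_INIT = ThermalProperties(k=0.3, alpha=0.10)

#: Physiological search box: k in W/m/K, alpha in mm^2/s.
DEFAULT_BOUNDS = {"k": (0.05, 1.5), "alpha": (0.01, 0.5)}

# optimizer tolerances: stop on relative SSE change < 1e-10 or step < 1e-8
_FTOL, _XTOL, _GTOL = 1e-10, 1e-8, 1e-14


class DegenerateCurveError(ValueError):
    """The transient carries no usable signal (constant or all-zero)."""


class CalibrationConsistencyWarning(UserWarning):
    """Per-material calibration radii disagree by more than the stated spread."""


@dataclass(frozen=True)
class ErrorSurface:
    """Sum-of-squared-residuals surface over a (k, alpha) grid."""

    k_grid: np.ndarray  # W/m/K, ascending
    alpha_grid: np.ndarray  # mm^2/s, ascending
    sse: np.ndarray  # shape (len(k_grid), len(alpha_grid)), K^2

    def __post_init__(self) -> None:
        if self.sse.shape != (self.k_grid.size, self.alpha_grid.size):
            raise InvalidParameterError("sse shape must match the grids")
        if np.any(self.sse < 0):
            raise InvalidParameterError("sse entries must be >= 0")

    @property
    def argmin(self) -> tuple[int, int]:
        """Indices of the grid minimum; ties resolve to smallest k then alpha."""
        flat = int(np.argmin(self.sse))  # first occurrence, row-major: k then alpha
        return np.unravel_index(flat, self.sse.shape)  # type: ignore[return-value]

    @property
    def min_point(self) -> tuple[float, float]:
        i, j = self.argmin
        return float(self.k_grid[i]), float(self.alpha_grid[j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.sse, index=pd.Index(self.k_grid, name="k_W_per_mK"),
                            columns=pd.Index(self.alpha_grid, name="alpha_mm2_per_s"))

    def plot(self, ax=None, log10: bool = True):
        """Filled-contour map of the (optionally log10) SSE surface."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        z = np.log10(np.maximum(self.sse, 1e-300)) if log10 else self.sse
        cs = ax.contourf(self.alpha_grid, self.k_grid, z, levels=30)
        ax.figure.colorbar(cs, ax=ax, label="log10 SSE (K$^2$)" if log10 else "SSE (K$^2$)")
        ax.set_xlabel(r"$\alpha$ (mm$^2$ s$^{-1}$)")
        ax.set_ylabel(r"$k$ (W m$^{-1}$ K$^{-1}$)")
        return ax


class TPSModel:
    """TPS inverse model for one transient curve.

    Parameters
    ----------
    curve : TransientCurve
        Measured (or synthetic) temperature-rise record.
    config : SensorConfig
        Actuation geometry and power; the *effective* radius is used.
    exclude_initial_fraction : float, optional
        Fraction of the actuation duration to drop from the start of the
        curve before fitting (the early transient is most affected by the
        device's own layers).  Default 0.0: fit the whole curve.
    """

    def __init__(
        self,
        curve: TransientCurve,
        config: SensorConfig,
        exclude_initial_fraction: float = 0.0,
    ) -> None:
        if not 0.0 <= exclude_initial_fraction < 1.0:
            raise InvalidParameterError("exclude_initial_fraction must be in [0, 1)")
        if np.ptp(curve.delta_T) == 0.0:
            raise DegenerateCurveError("temperature rise is constant; nothing to fit")
        self.curve = curve
        self.config = config
        self.exclude_initial_fraction = exclude_initial_fraction
        t_cut = exclude_initial_fraction * config.duration
        self._mask = curve.times >= t_cut
        if int(self._mask.sum()) < 4:
            raise InvalidParameterError("need at least 4 usable samples to fit")
        if int(self._mask.sum()) < 20 or curve.span < 1.0:
            warnings.warn(
                "curve is short (<20 samples or <1 s span); estimates may be fragile",
                UserWarning,
                stacklevel=2,
            )
        self._t = curve.times[self._mask]
        self._y = curve.delta_T[self._mask]

    # ---- forward evaluation -------------------------------------------------

    def predict(self, props: ThermalProperties, times: Sequence[float] | None = None) -> np.ndarray:
        """Model temperature rise at the fitted sample times (or ``times``)."""
        t = self._t if times is None else np.asarray(times, dtype=float)
        return mean_temperature_rise(props, self.config, t)

    def sse(self, props: ThermalProperties) -> float:
        """Sum of squared residuals of ``props`` against the curve, K^2."""
        r = self.predict(props) - self._y
        return float(r @ r)

    # ---- fitting ------------------------------------------------------------

    def fit(
        self,
        init: ThermalProperties = DEFAULT_INIT,
        bounds: dict[str, tuple[float, float]] | None = None,
    ) -> "TPSResults":
        """Least-squares fit of (k, alpha).

        Deterministic given the initial point and tolerances.  Non-convergence
        is flagged on the result rather than raised.
        """
        bounds = dict(DEFAULT_BOUNDS, **(bounds or {}))
        lo = np.array([bounds["k"][0], bounds["alpha"][0]])
        hi = np.array([bounds["k"][1], bounds["alpha"][1]])
        x0 = np.clip([init.k, init.alpha], lo, hi)

        def resid(x: np.ndarray) -> np.ndarray:
            return self.predict(ThermalProperties(k=x[0], alpha=x[1])) - self._y

        res = least_squares(
            resid, x0, bounds=(lo, hi), x_scale=np.abs(x0),
            ftol=_FTOL, xtol=_XTOL, gtol=_GTOL,
        )
        props = ThermalProperties(k=float(res.x[0]), alpha=float(res.x[1]))
        return TPSResults(
            model=self,
            props=props,
            sse=float(2.0 * res.cost),
            n_samples=int(self._t.size),
            converged=bool(res.status > 0),
            bounds=bounds,
        )

    def refit_fixed(
        self,
        fixed: str,
        fixed_value: float,
        other_init: float,
        bounds: dict[str, tuple[float, float]],
    ) -> tuple[float, float, bool]:
        """Refit one parameter with the other held fixed.

        Returns (refit value, sse, converged).  Used by the sensitivity scan.
        """
        free = "alpha" if fixed == "k" else "k"
        lo, hi = bounds[free]

        def resid(x: np.ndarray) -> np.ndarray:
            kw = {fixed: fixed_value, free: x[0]}
            return self.predict(ThermalProperties(**kw)) - self._y

        res = least_squares(
            resid, np.clip([other_init], lo, hi), bounds=([lo], [hi]),
            x_scale=[abs(other_init)], ftol=_FTOL, xtol=_XTOL, gtol=_GTOL,
        )
        return float(res.x[0]), float(2.0 * res.cost), bool(res.status > 0)


@dataclass(frozen=True)
class TPSResults:
    """Results of a TPS fit: estimates, fit quality and diagnostics."""

    model: TPSModel
    props: ThermalProperties
    sse: float
    n_samples: int
    converged: bool
    bounds: dict[str, tuple[float, float]]
    fitted_constants: SimplifiedFitConstants | None = None

    @property
    def k(self) -> float:
        return self.props.k

    @property
    def alpha(self) -> float:
        return self.props.alpha

    @property
    def rho_cp(self) -> float:
        """Volumetric heat capacity k/alpha, J m^-3 K^-1."""
        return self.props.rho_cp

    @property
    def rmse(self) -> float:
        return float(np.sqrt(self.sse / self.n_samples))

    def predict(self, times: Sequence[float] | None = None) -> np.ndarray:
        return self.model.predict(self.props, times)

    # ---- diagnostics --------------------------------------------------------

    def sensitivity_scan(
        self,
        which: str,
        perturbations: Iterable[float] = (-0.15, -0.10, -0.05, 0.05, 0.10, 0.15),
    ) -> pd.DataFrame:
        """Perturb-and-refit scan of parameter coupling.

        For each fractional perturbation ``delta``, the parameter ``which``
        ("k" or "alpha") is fixed at ``(1 + delta)`` times its best-fit value
        and only the other parameter is refit; the table reports the
        fractional shift this induces in the refit parameter.
        """
        if which not in ("k", "alpha"):
            raise InvalidParameterError("which must be 'k' or 'alpha'")
        if not self.converged:
            raise InvalidParameterError("scan requires a converged fit")
        other = "alpha" if which == "k" else "k"
        best_fixed = getattr(self.props, which)
        best_other = getattr(self.props, other)
        rows = []
        for delta in perturbations:
            fixed_value = (1.0 + delta) * best_fixed
            refit, sse, ok = self.model.refit_fixed(which, fixed_value, best_other, self.bounds)
            rows.append(
                {
                    "perturbation": float(delta),
                    f"fixed_{which}": fixed_value,
                    f"refit_{other}": refit,
                    "fractional_shift": refit / best_other - 1.0,
                    "sse": sse,
                    "converged": ok,
                }
            )
        return pd.DataFrame(rows)

    def error_surface(self, span: float = 0.15, n_per_axis: int = 31) -> ErrorSurface:
        """SSE over a (k, alpha) grid spanning +-``span`` about the best fit."""
        if not self.converged:
            raise InvalidParameterError("error surface requires a converged fit")
        fr = np.linspace(-span, span, n_per_axis)
        k_grid = self.props.k * (1.0 + fr)
        a_grid = self.props.alpha * (1.0 + fr)
        sse = np.empty((n_per_axis, n_per_axis))
        for i, k in enumerate(k_grid):
            for j, a in enumerate(a_grid):
                sse[i, j] = self.model.sse(ThermalProperties(k=k, alpha=a))
        return ErrorSurface(k_grid=k_grid, alpha_grid=a_grid, sse=sse)

    # ---- presentation -------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "TPS transient fit",
            "=================",
            f"samples fitted        : {self.n_samples}",
            f"converged             : {self.converged}",
            f"k      (W m^-1 K^-1)  : {self.k:.4f}",
            f"alpha  (mm^2 s^-1)    : {self.alpha:.4f}",
            f"rho*Cp (J m^-3 K^-1)  : {self.rho_cp:.4g}",
            f"SSE    (K^2)          : {self.sse:.4g}",
            f"RMSE   (K)            : {self.rmse:.4g}",
            f"effective radius (mm) : {self.model.config.effective_radius:.4g}",
            f"power P0 (W)          : {self.model.config.power:.4g}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "k_W_per_mK": self.k,
            "alpha_mm2_per_s": self.alpha,
            "rho_cp_J_per_m3K": self.rho_cp,
            "sse_K2": self.sse,
            "rmse_K": self.rmse,
            "n_samples": self.n_samples,
            "converged": self.converged,
        }

    def plot_fit(self, ax=None):
        """Measured points with the fitted forward curve overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.curve.times, self.model.curve.delta_T, ".", ms=3, label="data")
        tt = np.linspace(self.model.curve.times[0], self.model.curve.times[-1], 200)
        ax.plot(tt, self.predict(tt), "-", label="fit")
        ax.set_xlabel("time (s)")
        ax.set_ylabel(r"$\Delta T$ (K)")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# functional wrappers and auxiliary operations
# ---------------------------------------------------------------------------


def fit_tps(
    curve: TransientCurve,
    cfg: SensorConfig,
    init: ThermalProperties = DEFAULT_INIT,
    bounds: dict[str, tuple[float, float]] | None = None,
    exclude_initial_fraction: float = 0.0,
) -> TPSResults:
    """Fit (k, alpha) to a transient; see :class:`TPSModel`."""
    return TPSModel(curve, cfg, exclude_initial_fraction).fit(init=init, bounds=bounds)


def sensitivity_scan(
    curve: TransientCurve,
    cfg: SensorConfig,
    best: TPSResults,
    which: str,
    perturbations: Iterable[float] = (-0.15, -0.10, -0.05, 0.05, 0.10, 0.15),
) -> pd.DataFrame:
    """Functional wrapper for :meth:`TPSResults.sensitivity_scan`."""
    del curve, cfg  # the results object already holds its model
    return best.sensitivity_scan(which, perturbations)


def error_surface(
    curve: TransientCurve,
    cfg: SensorConfig,
    best: TPSResults,
    span: float = 0.15,
    n_per_axis: int = 31,
) -> ErrorSurface:
    """Functional wrapper for :meth:`TPSResults.error_surface`."""
    del curve, cfg
    return best.error_surface(span=span, n_per_axis=n_per_axis)


def volumetric_heat_capacity(props: ThermalProperties | None = None, *, k: float | None = None,
                             alpha: float | None = None) -> float:
    """rho*Cp = k/alpha in J m^-3 K^-1.

    Accepts either a :class:`ThermalProperties` or explicit ``k`` (W/m/K) and
    ``alpha`` (mm^2/s) keywords; ``k = 0`` is allowed in the keyword form and
    returns 0.
    """
    if props is not None:
        return props.rho_cp
    if k is None or alpha is None:
        raise InvalidParameterError("provide either props or both k and alpha")
    if not alpha > 0:
        raise InvalidParameterError(f"alpha must be > 0, got {alpha}")
    if k < 0:
        raise InvalidParameterError(f"k must be >= 0, got {k}")
    return k / (alpha * MM2_TO_M2)


def calibrate_effective_radius(
    references: Sequence[tuple[TransientCurve, ThermalProperties]],
    cfg: SensorConfig,
    max_relative_spread: float = 0.20,
) -> float:
    """Calibrate the effective sensor radius on reference materials.

    With (k, alpha) fixed at the known values of each reference material
    (e.g. water, ethylene glycol), the effective radius is the single ``a``
    minimizing the summed SSE of the forward model against all reference
    curves.  For this sensor class the result is roughly half the true
    (lithographic) radius.

    Emits :class:`CalibrationConsistencyWarning` when the per-material optima
    spread by more than ``max_relative_spread`` of their mean.
    """
    if not references:
        raise InvalidParameterError("need at least one reference material")
    lo, hi = 0.02, cfg.true_radius

    def sse_for(a: float, subset) -> float:
        c = replace(cfg, effective_radius=a)
        total = 0.0
        for curve, props in subset:
            r = mean_temperature_rise(props, c, curve.times) - curve.delta_T
            total += float(r @ r)
        return total

    res = minimize_scalar(sse_for, args=(references,), bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-7})
    if len(references) > 1:
        per = [
            minimize_scalar(sse_for, args=([ref],), bounds=(lo, hi), method="bounded",
                            options={"xatol": 1e-7}).x
            for ref in references
        ]
        spread = (max(per) - min(per)) / np.mean(per)
        if spread > max_relative_spread:
            warnings.warn(
                f"per-material effective radii disagree (relative spread {spread:.1%}): "
                + ", ".join(f"{a:.4f} mm" for a in per),
                CalibrationConsistencyWarning,
                stacklevel=2,
            )
    return float(res.x)


def fit_simplified_constants(
    curve: TransientCurve,
    cfg: SensorConfig,
    props: ThermalProperties,
) -> SimplifiedFitConstants:
    """Calibrate the erfc-model constants (A1, A2) against a reference curve.

    With (k, alpha) known, A1 and A2 are chosen by least squares so the
    simplified model tracks the measured (or exact-model) rise.
    """

    def resid(x: np.ndarray) -> np.ndarray:
        consts = SimplifiedFitConstants(a1=x[0], a2=x[1])
        model = simplified_rise(curve.times, consts, props.k, props.alpha, cfg.power, t_inf=0.0)
        return model - curve.delta_T

    res = least_squares(
        resid,
        [1.0, cfg.effective_radius],
        bounds=([1e-6, 1e-4], [1e3, 100.0]),
        ftol=_FTOL, xtol=_XTOL, gtol=_GTOL,
    )
    return SimplifiedFitConstants(a1=float(res.x[0]), a2=float(res.x[1]))
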