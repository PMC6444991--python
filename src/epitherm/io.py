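"""File formats and run configuration.

All on-disk formats are comma-separated UTF-8 text with '.' decimals and
'#'-prefixed ``key = value`` metadata lines before the header row — the
dialect typical of instrument exports.  Transient curves carry their
actuation metadata (power, radii, duration, baseline temperature) so a file
is self-describing; impedance spectra store real and imaginary parts in
separate columns.
"""

from __future__ import annotations

import io as _io
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from epitherm.electrical import ImpedanceSpectrum
from epitherm.inversion import DEFAULT_BOUNDS, DEFAULT_INIT, TPSModel
from epitherm.tps import InvalidParameterError, SensorConfig, ThermalProperties, TransientCurve

__all__ = [
    "SchemaError",
    "RunConfig",
    "read_transient",
    "write_transient",
    "read_spectrum",
    "write_spectrum",
    "run_pipeline",
]

log = logging.getLogger("epitherm")


class SchemaError(ValueError):
    """A file does not match the expected schema."""


# ---------------------------------------------------------------------------
# transient curve files
# ---------------------------------------------------------------------------

_CURVE_COLUMNS = ["time_s", "delta_T_K"]


def _read_metadata(path: Path) -> dict[str, float]:
    meta: dict[str, float] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                try:
                    meta[key.strip()] = float(value)
                except ValueError:
                    pass
    return meta


def read_transient(path) -> tuple[TransientCurve, SensorConfig | None]:
    """Read a transient-curve CSV.

    Returns the curve and, when the metadata block carries the full actuation
    record (P0_W, true_radius_mm, effective_radius_mm, duration_s), the
    sensor configuration; otherwise the config slot is None.
    """
    path = Path(path)
    meta = _read_metadata(path)
    try:
        frame = pd.read_csv(path, comment="#")
    except Exception as exc:  # malformed text
        raise SchemaError(f"{path}: cannot parse as CSV ({exc})") from exc
    missing = [c for c in _CURVE_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    times = frame["time_s"].to_numpy(dtype=float)
    if times.size > 1:
        bad = np.flatnonzero(np.diff(times) <= 0)
        if bad.size:
            raise SchemaError(f"{path}: time_s not strictly increasing at row {int(bad[0]) + 1}")
    try:
        curve = TransientCurve(
            times=times,
            delta_T=frame["delta_T_K"].to_numpy(dtype=float),
            t_inf=meta.get("T_inf_K", 293.15),
        )
    except InvalidParameterError as exc:
        raise SchemaError(f"{path}: {exc}") from exc
    cfg = None
    keys = ("P0_W", "true_radius_mm", "effective_radius_mm", "duration_s")
    if all(k in meta for k in keys):
        cfg = SensorConfig(
            true_radius=meta["true_radius_mm"],
            effective_radius=meta["effective_radius_mm"],
            power=meta["P0_W"],
            duration=meta["duration_s"],
        )
    return curve, cfg


def write_transient(path, curve: TransientCurve, cfg: SensorConfig | None = None) -> None:
    """Write a transient curve (and optional actuation metadata) as CSV."""
    path = Path(path)
    buf = _io.StringIO()
    buf.write(f"# T_inf_K = {curve.t_inf!r}\n")
    if cfg is not None:
        buf.write(f"# P0_W = {cfg.power!r}\n")
        buf.write(f"# true_radius_mm = {cfg.true_radius!r}\n")
        buf.write(f"# effective_radius_mm = {cfg.effective_radius!r}\n")
        buf.write(f"# duration_s = {cfg.duration!r}\n")
    pd.DataFrame({"time_s": curve.times, "delta_T_K": curve.delta_T}).to_csv(
        buf, index=False, float_format="%.9g"
    )
    path.write_text(buf.getvalue(), encoding="utf-8")


# ---------------------------------------------------------------------------
# impedance spectrum files
# ---------------------------------------------------------------------------

_SPECTRUM_COLUMNS = ["freq_hz", "z_real_ohm", "z_imag_ohm"]


def read_spectrum(path) -> ImpedanceSpectrum:
    path = Path(path)
    meta = _read_metadata(path)
    frame = pd.read_csv(path, comment="#")
    missing = [c for c in _SPECTRUM_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    z = frame["z_real_ohm"].to_numpy(float) + 1j * frame["z_imag_ohm"].to_numpy(float)
    try:
        return ImpedanceSpectrum(
            frequencies=frame["freq_hz"].to_numpy(float),
            impedance=z,
            drive_voltage=meta.get("drive_Vpp", 2.0),
        )
    except InvalidParameterError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_spectrum(path, spectrum: ImpedanceSpectrum) -> None:
    path = Path(path)
    buf = _io.StringIO()
    buf.write(f"# drive_Vpp = {spectrum.drive_voltage!r}\n")
    pd.DataFrame(
        {
            "freq_hz": spectrum.frequencies,
            "z_real_ohm": spectrum.impedance.real,
            "z_imag_ohm": spectrum.impedance.imag,
        }
    ).to_csv(buf, index=False, float_format="%.9g")
    path.write_text(buf.getvalue(), encoding="utf-8")


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Defaults threaded through CLI runs; JSON-serialisable."""

    seed: int = 0
    true_radius_mm: float = 0.5
    effective_radius_mm: float = 0.254
    power_density_W_mm2: float = 7e-3
    duration_s: float = 2.0
    init_k: float = DEFAULT_INIT.k
    init_alpha: float = DEFAULT_INIT.alpha
    bounds_k: tuple = tuple(DEFAULT_BOUNDS["k"])
    bounds_alpha: tuple = tuple(DEFAULT_BOUNDS["alpha"])
    exclude_initial_fraction: float = 0.0
    surface_span: float = 0.15
    surface_n: int = 31
    emm_grid_n_2d: int = 64
    emm_grid_n_3d: int = 32

    def __post_init__(self) -> None:
        self.bounds_k = tuple(self.bounds_k)  # JSON arrays arrive as lists
        self.bounds_alpha = tuple(self.bounds_alpha)
        if not 0 < self.effective_radius_mm <= self.true_radius_mm:
            raise InvalidParameterError("effective radius must be in (0, true radius]")
        if not (self.bounds_k[0] <= self.init_k <= self.bounds_k[1]):
            raise InvalidParameterError("init_k outside bounds_k")
        if not (self.bounds_alpha[0] <= self.init_alpha <= self.bounds_alpha[1]):
            raise InvalidParameterError("init_alpha outside bounds_alpha")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        cfg = cls(**data)
        return cfg

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2), encoding="utf-8")

    def sensor(self) -> SensorConfig:
        return SensorConfig.from_power_density(
            self.true_radius_mm,
            self.effective_radius_mm,
            self.power_density_W_mm2,
            self.duration_s,
        )

    def init_props(self) -> ThermalProperties:
        return ThermalProperties(k=self.init_k, alpha=self.init_alpha)

    def bounds(self) -> dict[str, tuple[float, float]]:
        return {"k": tuple(self.bounds_k), "alpha": tuple(self.bounds_alpha)}


def run_pipeline(
    config: RunConfig,
    curve_paths,
    with_sensitivity: bool = False,
) -> dict:
    """Fit every curve file and assemble a JSON-ready report.

    Per curve: the fitted (k, alpha), derived rho*Cp and convergence flag;
    files that fail to parse or are degenerate are reported with their error
    instead of aborting the batch.  ``ok`` is True only if every file
    produced a converged fit.
    """
    entries = []
    all_ok = True
    for path in curve_paths:
        entry: dict = {"file": str(path)}
        try:
            curve, file_cfg = read_transient(path)
            sensor = file_cfg or config.sensor()
            model = TPSModel(curve, sensor, config.exclude_initial_fraction)
            result = model.fit(init=config.init_props(), bounds=config.bounds())
            entry.update(result.to_dict())
            if with_sensitivity and result.converged:
                entry["sensitivity_alpha_pm5"] = result.sensitivity_scan(
                    "alpha", (-0.05, 0.05)
                )["fractional_shift"].tolist()
                entry["sensitivity_k_pm5"] = result.sensitivity_scan(
                    "k", (-0.05, 0.05)
                )["fractional_shift"].tolist()
            if not result.converged:
                all_ok = False
            log.info("fit %s: k=%.4f alpha=%.4f converged=%s", path,
                     result.k, result.alpha, result.converged)
        except (SchemaError, InvalidParameterError, ValueError) as exc:
            entry["error"] = str(exc)
            all_ok = False
            log.warning("failed %s: %s", path, exc)
        entries.append(entry)
    return {"config": asdict(config), "n_curves": len(entries), "ok": all_ok,
            "results": entries}
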