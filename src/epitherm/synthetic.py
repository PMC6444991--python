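"""Seeded synthetic-data generators for every measurement modality.

These generators stand in for the instrument: TPS transients with additive
Gaussian noise, hydration sweeps that mirror the porcine soaking experiment
(water fraction -> effective-medium properties -> transient), impedance
spectra for dehydrated/hydrated skin, and clinical-protocol time series with
arm-specific effect profiles.  Everything is driven by explicit integer
seeds and is bit-reproducible.

Default study conditions follow the measurement protocol: 7 mW/mm^2 areal
power for 2 s on a 0.5 mm radius element (calibrated effective radius
0.254 mm), sampled at 100 Hz; transient noise defaults to 1% of the peak
rise of a typical-skin curve, a thermistor-class precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from epitherm.electrical import ImpedanceSpectrum, SkinElectricalState, lumped_impedance
from epitherm.mixture import (
    SKIN_WATER,
    PhasePair,
    UnitCell,
    unit_cell_k,
    volumetric_rho_cp,
)
from epitherm.tps import (
    InvalidParameterError,
    SensorConfig,
    ThermalProperties,
    TransientCurve,
    mean_temperature_rise,
)

__all__ = [
    "NoiseModel",
    "ProtocolTimeline",
    "TRIAL_ARMS",
    "default_sensor",
    "generate_transient",
    "generate_hydration_sweep",
    "generate_spectrum",
    "generate_trial_series",
]

#: Arms of the clinical protocol: occlusive patch plus three lotion
#: formulations by glycerin weight fraction.
TRIAL_ARMS = ("patch", "glycerin_0", "glycerin_15", "glycerin_30")


@dataclass(frozen=True)
class NoiseModel:
    """Additive i.i.d. Gaussian measurement noise with a fixed seed."""

    sigma: float = 0.0  # K for transients; relative for trial series
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise InvalidParameterError(f"sigma must be >= 0, got {self.sigma}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class ProtocolTimeline:
    """Measurement schedule of the clinical protocol, minutes.

    -15 is the pre-treatment baseline; 0 the measurement immediately after
    application; 300 follows removal/cleaning of the compound.
    """

    times: tuple = (-15.0, 0.0, 30.0, 60.0, 270.0, 300.0)
    arms: tuple = TRIAL_ARMS

    def __post_init__(self) -> None:
        if not all(a < b for a, b in zip(self.times, self.times[1:])):
            raise InvalidParameterError("timeline must be strictly ascending")
        unknown = set(self.arms) - set(TRIAL_ARMS)
        if unknown:
            raise InvalidParameterError(f"unknown arms: {sorted(unknown)}")


def default_sensor() -> SensorConfig:
    """Protocol sensor: 0.5 mm true radius, 0.254 mm effective radius,
    7 mW/mm^2 for 2 s."""
    return SensorConfig.from_power_density(
        true_radius=0.5, effective_radius=0.254, power_density=7e-3, duration=2.0
    )


def generate_transient(
    props: ThermalProperties,
    cfg: SensorConfig | None = None,
    sampling_hz: float = 100.0,
    noise: NoiseModel = NoiseModel(),
    t_inf: float = 293.15,
) -> TransientCurve:
    """One noisy TPS transient; with ``sigma = 0`` it equals the forward
    model exactly."""
    if cfg is None:
        cfg = default_sensor()
    if not sampling_hz > 0:
        raise InvalidParameterError("sampling rate must be > 0")
    n = int(round(cfg.duration * sampling_hz))
    times = np.arange(1, n + 1) / sampling_hz
    clean = mean_temperature_rise(props, cfg, times)
    noisy = clean + noise.rng().normal(0.0, noise.sigma, size=clean.shape) if noise.sigma else clean
    return TransientCurve(times=times, delta_T=noisy, t_inf=t_inf)


def generate_hydration_sweep(
    x_values,
    phases: PhasePair = SKIN_WATER,
    cfg: SensorConfig | None = None,
    noise: NoiseModel = NoiseModel(),
    sampling_hz: float = 100.0,
    grid_n: int = 64,
) -> dict[float, tuple[TransientCurve, ThermalProperties]]:
    """Transients across a water-fraction sweep, keyed by x.

    Per x, the conductivity comes from the 2-D unit-cell solve and the heat
    capacity from the volumetric mixture; the implied (k, alpha) drive the
    forward model.  Emulates the porcine soaking series: fitted k rises and
    the 2 s peak temperature falls as hydration increases.  Each curve draws
    from an independent child seed of ``noise.seed``.
    """
    if cfg is None:
        cfg = default_sensor()
    out: dict[float, tuple[TransientCurve, ThermalProperties]] = {}
    seeds = np.random.SeedSequence(noise.seed).spawn(len(list(x_values)))
    for x, ss in zip(x_values, seeds):
        cell = UnitCell(float(x), geometry="cylinder-2d", grid_n=grid_n)
        k_eff = unit_cell_k(cell, phases)
        alpha = k_eff / volumetric_rho_cp(float(x), phases) * 1e6  # mm^2/s
        props = ThermalProperties(k=k_eff, alpha=alpha)
        sub_noise = NoiseModel(sigma=noise.sigma, seed=int(ss.generate_state(1)[0] % 2**31))
        out[float(x)] = (generate_transient(props, cfg, sampling_hz, sub_noise), props)
    return out


def generate_spectrum(
    state: SkinElectricalState,
    cell_constant: float = 120.0,
    n_points: int = 40,
    noise: NoiseModel = NoiseModel(),
    drive_voltage: float = 2.0,
) -> ImpedanceSpectrum:
    """Impedance spectrum over the 10 kHz - 1.2 MHz instrument band.

    Noise (relative, from ``noise.sigma``) perturbs real and imaginary parts
    independently.
    """
    f = np.geomspace(10e3, 1.2e6, n_points)
    z = lumped_impedance(state, cell_constant, f)
    if noise.sigma:
        rng = noise.rng()
        scale = noise.sigma * np.abs(z)
        z = z + rng.normal(0, scale) + 1j * rng.normal(0, scale)
    return ImpedanceSpectrum(frequencies=f, impedance=z, drive_voltage=drive_voltage,
                             instrument_data=True)


#: Baseline values for the trial quantities: thermal conductivity (W/m/K),
#: diffusivity (mm^2/s), impedance magnitude at the working frequency (ohm),
#: corneometer index (a.u.).
_TRIAL_BASELINES = {"k": 0.35, "alpha": 0.12, "z_mag": 3.0e4, "corneometer": 35.0}

#: Direction each quantity moves under increased hydration.
_TRIAL_SIGNS = {"k": +1.0, "alpha": -1.0, "z_mag": -1.0, "corneometer": +1.0}

#: Fraction of the peak effect that persists at the post-removal time point
#: (300 min) for glycerin arms: thermal properties do not return to baseline,
#: while impedance and corneometer largely do.
_PERSISTENCE = {"k": 0.5, "alpha": 0.5, "z_mag": 0.1, "corneometer": 0.1}


def _profile(arm: str, t: float, patch_duration_min: float) -> float:
    """Unitless effect profile in [0, 1] for one arm at time t (min)."""
    if t < 0:
        return 0.0
    if arm == "patch":
        # longer occlusion accumulates more transepidermal water; once the
        # patch comes off it evaporates fast, back to baseline within ~30 min
        amplitude = 1.0 - float(np.exp(-patch_duration_min / 20.0))
        return amplitude * float(np.exp(-t / 8.0))
    # lotion arms: immediate effect relaxing to a plateau
    plateau = {"glycerin_0": 0.35, "glycerin_15": 0.75, "glycerin_30": 0.85}[arm]
    return float(plateau + (1.0 - plateau) * np.exp(-t / 30.0))


def generate_trial_series(
    timeline: ProtocolTimeline,
    arm: str,
    effect_sizes: dict[str, float] | None = None,
    noise: NoiseModel = NoiseModel(),
    patch_duration_min: float = 15.0,
) -> pd.DataFrame:
    """Seeded clinical time series for one protocol arm.

    Returns a DataFrame indexed by time (min) with columns k, alpha, z_mag
    and corneometer.  ``effect_sizes`` gives the peak fractional change per
    quantity (default 10%); signs follow the physics (hydration raises k and
    the corneometer index, lowers alpha and impedance).  Glycerin arms keep
    part of the thermal effect after removal at 300 min; the patch arm decays
    back to baseline within tens of minutes.  ``noise.sigma`` is a relative
    noise level.
    """
    if arm not in TRIAL_ARMS:
        raise InvalidParameterError(f"unknown arm {arm!r}; expected one of {TRIAL_ARMS}")
    effect_sizes = dict.fromkeys(_TRIAL_BASELINES, 0.10) | (effect_sizes or {})
    rng = noise.rng()
    t_final = timeline.times[-1]
    rows = {}
    for qty, base in _TRIAL_BASELINES.items():
        delta = effect_sizes[qty]
        sign = _TRIAL_SIGNS[qty]
        vals = []
        for t in timeline.times:
            p = _profile(arm, t, patch_duration_min)
            if arm != "patch" and t >= t_final:
                # compound removed and skin cleaned
                p = _PERSISTENCE[qty] * _profile(arm, 270.0, patch_duration_min)
            v = base * (1.0 + sign * delta * p)
            if noise.sigma:
                v += rng.normal(0.0, noise.sigma * base)
            vals.append(v)
        rows[qty] = vals
    return pd.DataFrame(rows, index=pd.Index(timeline.times, name="time_min"))
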