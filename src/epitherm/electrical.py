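"""Electrical impedance and calorimetry helpers for the hydration sensor.

Covers the lumped surrogate model of the epidermal impedance sensor (EIS),
the electrode-spacing rule for its measurement depth, specific-heat
extraction from differential scanning calorimetry (DSC) records, and the
area-under-the-curve (AUC) descriptor used to summarise clinical time series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from epitherm.tps import InvalidParameterError

__all__ = [
    "VACUUM_PERMITTIVITY",
    "DEHYDRATED_SKIN",
    "HYDRATED_SKIN",
    "ImpedanceSpectrum",
    "SkinElectricalState",
    "DscRecord",
    "lumped_impedance",
    "eis_measurement_depth",
    "electrode_gap_from_diameters",
    "dsc_calibrate",
    "dsc_specific_heat",
    "auc_descriptor",
]

VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m

#: Instrument band of the impedance analyser, Hz.
INSTRUMENT_BAND = (10e3, 1.2e6)


@dataclass(frozen=True)
class SkinElectricalState:
    """Quasi-static electrical state of skin: relative permittivity and
    conductivity (S/m)."""

    permittivity: float
    conductivity: float

    def __post_init__(self) -> None:
        if not (self.permittivity > 0 and self.conductivity > 0):
            raise InvalidParameterError(f"permittivity and conductivity must be > 0: {self}")


#: Literature states used in the field simulations: dehydrated and hydrated skin.
DEHYDRATED_SKIN = SkinElectricalState(permittivity=1133.6, conductivity=2.04e-4)
HYDRATED_SKIN = SkinElectricalState(permittivity=29010.0, conductivity=2.93e-3)


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """Frequency-indexed complex impedance record.

    When ``instrument_data`` is set, frequencies must lie within the
    analyser band of 10 kHz - 1.2 MHz.
    """

    frequencies: np.ndarray  # Hz, ascending
    impedance: np.ndarray  # complex ohm
    drive_voltage: float = 2.0  # V peak-to-peak
    instrument_data: bool = False

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        z = np.asarray(self.impedance, dtype=complex)
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "impedance", z)
        if f.ndim != 1 or z.shape != f.shape:
            raise InvalidParameterError("frequencies and impedance must be 1-D, equal length")
        if f.size > 1 and not np.all(np.diff(f) > 0):
            raise InvalidParameterError("frequencies must be strictly ascending")
        if np.any(np.abs(z) <= 0):
            raise InvalidParameterError("impedance magnitudes must be > 0")
        if self.instrument_data and f.size:
            lo, hi = INSTRUMENT_BAND
            if f[0] < lo or f[-1] > hi:
                raise InvalidParameterError(
                    f"instrument data must lie within [{lo:g}, {hi:g}] Hz"
                )

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.impedance)

    @property
    def phase_deg(self) -> np.ndarray:
        return np.degrees(np.angle(self.impedance))


@dataclass(frozen=True)
class DscRecord:
    """A referenced DSC heat-flow deviation.

    ``h`` is the baseline-corrected, pan-normalised heat-flow deviation (W);
    ``beta`` the heating rate (K/min); ``b`` the sapphire-determined
    calibration factor.
    """

    h: float
    beta: float
    b: float = 1.0

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise InvalidParameterError(f"heating rate must be > 0, got {self.beta}")
        if not self.b > 0:
            raise InvalidParameterError(f"calibration factor must be > 0, got {self.b}")


def lumped_impedance(state: SkinElectricalState, cell_constant: float, f) -> complex:
    """Single-dispersion parallel-RC surrogate of the EIS measurement, ohm.

    Z(f) = 1 / (G + i 2 pi f C) with G = sigma / kappa and
    C = eps_r * eps_0 / kappa, where kappa (1/m) is the geometric cell
    constant of the electrode pair.  This is a quasi-static lumped surrogate
    for the full electrode field problem — useful for trend and descriptor
    plumbing, not a reproduction of simulated field maps.  |Z| decreases
    strictly with frequency and is smaller for hydrated than dehydrated skin.
    """
    if not cell_constant > 0:
        raise InvalidParameterError(f"cell constant must be > 0, got {cell_constant}")
    f_arr = np.asarray(f, dtype=float)
    if np.any(f_arr <= 0):
        raise InvalidParameterError("frequency must be > 0")
    g = state.conductivity / cell_constant
    c = state.permittivity * VACUUM_PERMITTIVITY / cell_constant
    z = 1.0 / (g + 1j * 2.0 * np.pi * f_arr * c)
    return complex(z) if np.isscalar(f) or f_arr.ndim == 0 else z


def eis_measurement_depth(electrode_gap: float) -> float:
    """Measurement depth of a concentric electrode pair, um.

    The sensing depth is roughly half the radial spacing between the
    electrodes: ``depth = gap / 2``.
    """
    if not electrode_gap > 0:
        raise InvalidParameterError(f"electrode gap must be > 0, got {electrode_gap}")
    return electrode_gap / 2.0


def electrode_gap_from_diameters(inner_diameter: float, outer_diameter: float) -> float:
    """Radial gap (um) between the outer edge of the inner disc and the inner
    edge of the outer ring, given the inner disc diameter and the ring's
    inner diameter (um): ``gap = (OD - ID) / 2``."""
    if not 0 < inner_diameter < outer_diameter:
        raise InvalidParameterError("require 0 < inner_diameter < outer_diameter")
    return (outer_diameter - inner_diameter) / 2.0


def dsc_calibrate(h_ref: float, beta: float, cp_ref: float) -> float:
    """Calibration factor B from a reference material (e.g. sapphire).

    Rearranges Cp = h/(B*beta) to B = h_ref/(cp_ref*beta).
    """
    if not (h_ref > 0 and beta > 0 and cp_ref > 0):
        raise InvalidParameterError("h_ref, beta and cp_ref must all be > 0")
    return h_ref / (cp_ref * beta)


def dsc_specific_heat(h: float, b: float, beta: float) -> float:
    """Specific heat from a DSC deviation: Cp = h / (B * beta), J/kg/K."""
    if not b > 0:
        raise InvalidParameterError(f"calibration factor must be > 0, got {b}")
    if not beta > 0:
        raise InvalidParameterError(f"heating rate must be > 0, got {beta}")
    return h / (b * beta)


def auc_descriptor(times, values, baseline: float = 0.0) -> float:
    """Trapezoidal area under (values - baseline) over time, value*min.

    Summarises a per-subject time profile as a single number; additive over
    contiguous time partitions and exactly zero for a series pinned at the
    baseline.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.ndim != 1 or v.shape != t.shape:
        raise InvalidParameterError("times and values must be 1-D and equally long")
    if t.size < 2:
        raise InvalidParameterError("need at least 2 points")
    if not np.all(np.diff(t) > 0):
        raise InvalidParameterError("times must be strictly ascending")
    return float(np.trapezoid(v - baseline, t))
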