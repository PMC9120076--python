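"""Chromophore optics and two-state photoswitching kinetics.

The switchable probe is a bacterial phytochrome (BphP1) that interconverts
between a far-red absorbing ground state (Pfr, the photoacoustic "ON" state,
absorption band 740-800 nm) and a red absorbing state (Pr, "OFF", band
620-680 nm).  Continuous-wave 635 nm light drives Pr -> Pfr; 790 nm
continuous-wave light and the 750 nm imaging pulses both drive Pfr -> Pr.
Oxy- and deoxy-hemoglobin do not switch and form the background.

This module holds the molar extinction tables, the illumination schedule of
one switching/imaging cycle, the Pfr-fraction trajectory solver, and the
conversion from concentration maps to an optical absorption map.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError, RangeError

__all__ = [
    "SPECIES",
    "SpectralLibrary",
    "KineticsParams",
    "IlluminationSchedule",
    "SwitchTrajectory",
    "load_spectra",
    "default_spectra",
    "pfr_trajectory",
    "absorption_map",
]

#: Species identifiers used across the package.  ``BphP1`` in a phantom is a
#: total-probe concentration that is split between ``BphP1_Pfr`` and
#: ``BphP1_Pr`` according to the instantaneous Pfr fraction.
SPECIES = ("HbO2", "HbR", "BphP1_Pfr", "BphP1_Pr")


@dataclass(frozen=True)
class SpectralLibrary:
    """Tabulated molar extinction coefficients, interpolated linearly.

    Parameters
    ----------
    wavelengths
        Strictly increasing wavelengths in nm.
    epsilon
        Mapping from species name to extinction coefficients in
        M^-1 cm^-1, one value per tabulated wavelength.
    """

    wavelengths: np.ndarray
    epsilon: dict = field(default_factory=dict)

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        if wl.ndim != 1 or wl.size == 0:
            raise FormatError("wavelength table must be a non-empty 1-D array")
        if wl.size > 1 and not np.all(np.diff(wl) > 0):
            raise FormatError("wavelengths must be strictly increasing")
        for sp in SPECIES:
            if sp not in self.epsilon:
                raise FormatError(f"missing species column: {sp}")
        eps = {}
        for sp, values in self.epsilon.items():
            values = np.asarray(values, dtype=float)
            if values.shape != wl.shape:
                raise FormatError(f"species {sp} has {values.size} values for "
                                  f"{wl.size} wavelengths")
            if np.any(values < 0) or not np.all(np.isfinite(values)):
                raise FormatError(f"extinction for {sp} must be finite and >= 0")
            eps[sp] = values
        object.__setattr__(self, "epsilon", eps)

    def lookup(self, species: str, wavelength: float) -> float:
        """Linear interpolation of epsilon(wavelength) for one species."""
        if species not in self.epsilon:
            raise FormatError(f"unknown species: {species}")
        wl = self.wavelengths
        if wavelength < wl[0] or wavelength > wl[-1]:
            raise RangeError(
                f"wavelength {wavelength} nm outside tabulated range "
                f"[{wl[0]}, {wl[-1]}] nm")
        return float(np.interp(wavelength, wl, self.epsilon[species]))

    def contrast_ratio(self, wavelength: float = 750.0) -> float:
        """epsilon_Pfr / epsilon_Pr at the imaging wavelength (ON/OFF contrast)."""
        return self.lookup("BphP1_Pfr", wavelength) / self.lookup("BphP1_Pr", wavelength)


def load_spectra(path) -> SpectralLibrary:
    """Read a spectra CSV with columns ``wavelength_nm`` plus one per species."""
    table = pd.read_csv(path)
    if "wavelength_nm" not in table.columns:
        raise FormatError("spectra CSV needs a 'wavelength_nm' column")
    missing = [sp for sp in SPECIES if sp not in table.columns]
    if missing:
        raise FormatError(f"spectra CSV missing species columns: {missing}")
    return SpectralLibrary(
        wavelengths=table["wavelength_nm"].to_numpy(float),
        epsilon={sp: table[sp].to_numpy(float) for sp in SPECIES},
    )


def default_spectra() -> SpectralLibrary:
    """The packaged extinction table (600-900 nm at 5 nm steps).

    Hemoglobin values follow published whole-blood compilations; the BphP1
    Pfr/Pr bands are Gaussian models of published RpBphP1 absorption spectra
    (Pfr peak near 755 nm, Pr peak near 680 nm).  These are configuration
    data, not measured ground truth.
    """
    ref = importlib.resources.files("rspat.data").joinpath("spectra_default.csv")
    with importlib.resources.as_file(ref) as path:
        return load_spectra(path)


@dataclass(frozen=True)
class KineticsParams:
    """Effective phase-level photoswitching rates.

    ``k_on`` is the Pr -> Pfr rate under the switching-ON continuous-wave
    light; ``k_off_cw`` the Pfr -> Pr rate under the 790 nm continuous-wave
    light; ``delta_off_pulse`` the fractional Pfr -> Pr conversion caused by
    each imaging pulse (the imaging light also switches the probe off).
    Defaults give a nearly fully-ON probe at the start of the imaging phase
    and a mostly-OFF probe at its end under the default 16 s cycle.
    """

    k_on: float = 1.0          # s^-1
    k_off_cw: float = 0.5      # s^-1
    delta_off_pulse: float = 0.15  # per pulse, dimensionless

    def __post_init__(self):
        if self.k_on < 0 or self.k_off_cw < 0:
            raise ConfigError("switching rates must be >= 0")
        if not 0.0 <= self.delta_off_pulse <= 1.0:
            raise ConfigError("delta_off_pulse must lie in [0, 1]")


@dataclass(frozen=True)
class IlluminationSchedule:
    """One switching/imaging cycle: CW switching-ON phase then pulsed imaging.

    Defaults reproduce the 16 s cycle: 8 s of switching-ON continuous-wave
    light, then 8 s of pulsed imaging at 750 nm with the switching-OFF
    790 nm continuous-wave light turned on 6 s into the imaging phase.
    """

    t_on_phase: float = 8.0       # s
    t_imaging_phase: float = 8.0  # s
    t_790_delay: float = 6.0      # s after imaging-phase start
    pulse_rate: float = 10.0      # Hz
    n_cycles: int = 1
    on_wavelength_nm: float = 635.0
    imaging_wavelength_nm: float = 750.0

    def __post_init__(self):
        if min(self.t_on_phase, self.t_imaging_phase, self.t_790_delay) < 0:
            raise ConfigError("schedule durations must be >= 0")
        if self.pulse_rate <= 0:
            raise ConfigError("pulse_rate must be > 0")
        if self.n_cycles < 1:
            raise ConfigError("n_cycles must be >= 1")

    @property
    def cycle_duration(self) -> float:
        return self.t_on_phase + self.t_imaging_phase

    @property
    def pulses_per_cycle(self) -> int:
        return int(round(self.t_imaging_phase * self.pulse_rate))

    def pulse_times(self) -> np.ndarray:
        """Absolute times of every imaging pulse over all cycles, in s."""
        within = self.t_on_phase + np.arange(self.pulses_per_cycle) / self.pulse_rate
        starts = np.arange(self.n_cycles) * self.cycle_duration
        return (starts[:, None] + within[None, :]).ravel()


@dataclass
class SwitchTrajectory:
    """Pfr fraction sampled at every imaging pulse."""

    pulse_times: np.ndarray   # s
    f: np.ndarray             # Pfr fraction in [0, 1]
    cycle_index: np.ndarray   # int, per pulse
    pulse_index: np.ndarray   # int, pulse number within the cycle

    def pulse(self, cycle: int, pulse: int) -> float:
        """Pfr fraction at one (cycle, pulse) position."""
        sel = (self.cycle_index == cycle) & (self.pulse_index == pulse)
        if not sel.any():
            raise ConfigError(f"no pulse (cycle={cycle}, pulse={pulse}) in trajectory")
        return float(self.f[sel][0])


def pfr_trajectory(schedule: IlluminationSchedule,
                   kin: KineticsParams,
                   f0: float = 0.0) -> SwitchTrajectory:
    """Piecewise-analytic Pfr-fraction trajectory under the cycle schedule.

    During the switching-ON phase ``df/dt = k_on (1 - f)``.  During the
    imaging phase each pulse instantaneously multiplies ``f`` by
    ``(1 - delta_off_pulse)`` (the sampled value is the pre-pulse state the
    pulse actually probes) and, once the 790 nm light is on
    (``t >= t_790_delay`` into the phase), ``f`` decays at ``k_off_cw``.
    Exact exponential propagation between events; no photobleaching or
    thermal reversion terms.
    """
    if not 0.0 <= f0 <= 1.0:
        raise ConfigError("f0 must lie in [0, 1]")
    n_pulses = schedule.pulses_per_cycle
    f_list, t_list, c_list, p_list = [], [], [], []
    f = float(f0)
    for c in range(schedule.n_cycles):
        t_cycle = c * schedule.cycle_duration
        # CW ON phase: mono-exponential approach to f = 1.
        f = 1.0 - (1.0 - f) * np.exp(-kin.k_on * schedule.t_on_phase)
        for j in range(n_pulses):
            t_in_phase = j / schedule.pulse_rate
            t_list.append(t_cycle + schedule.t_on_phase + t_in_phase)
            f_list.append(f)
            c_list.append(c)
            p_list.append(j)
            f *= 1.0 - kin.delta_off_pulse
            t_next = ((j + 1) / schedule.pulse_rate if j + 1 < n_pulses
                      else schedule.t_imaging_phase)
            # 790 nm CW decay acts only on the part of the interval after
            # the delay.
            lo = max(t_in_phase, schedule.t_790_delay)
            hi = max(t_next, schedule.t_790_delay)
            f *= np.exp(-kin.k_off_cw * (hi - lo))
    return SwitchTrajectory(
        pulse_times=np.asarray(t_list),
        f=np.clip(np.asarray(f_list), 0.0, 1.0),
        cycle_index=np.asarray(c_list, dtype=int),
        pulse_index=np.asarray(p_list, dtype=int),
    )


def absorption_map(phantom, lib: SpectralLibrary, wavelength: float,
                   f: float = 1.0) -> np.ndarray:
    """Optical absorption coefficient map mu_a in mm^-1.

    ``mu_a = ln(10) * sum_i eps_i(lambda) * c_i / 10`` with concentrations in
    M and extinction in M^-1 cm^-1 (the /10 converts cm^-1 to mm^-1).  The
    total BphP1 concentration is split as ``f*c`` into the Pfr state and
    ``(1-f)*c`` into the Pr state.
    """
    if not 0.0 <= f <= 1.0:
        raise ConfigError("Pfr fraction f must lie in [0, 1]")
    mu = None
    for sp, conc in phantom.maps.items():
        if sp == "BphP1":
            eps = (f * lib.lookup("BphP1_Pfr", wavelength)
                   + (1.0 - f) * lib.lookup("BphP1_Pr", wavelength))
        elif sp in lib.epsilon:
            eps = lib.lookup(sp, wavelength)
        else:
            raise FormatError(f"phantom species {sp!r} not in spectral library")
        term = np.asarray(conc, dtype=float) * eps
        mu = term if mu is None else mu + term
    if mu is None:
        raise ConfigError("phantom has no concentration maps")
    return mu * (np.log(10.0) / 10.0)
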