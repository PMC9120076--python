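"""Quantification: calibration, CNR, detection sensitivity, and baselines.

Concentration is calibrated against tube phantoms of purified probe at
known concentrations imaged through the same pipeline (ordinary least
squares of differential signal on concentration, intercept included to
absorb the non-negative envelope floor).  Detection sensitivity is the
noise-equivalent concentration: probe concentration divided by the image
contrast-to-noise ratio.  A pixelwise linear spectral-unmixing baseline is
included for comparison with differential detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ConfigError, InputError, UnmixingError
from .spectra_kinetics import SpectralLibrary

__all__ = [
    "CalibrationCurve",
    "QuantReport",
    "fit_calibration",
    "estimate_concentration",
    "cnr",
    "detection_sensitivity",
    "organ_relative",
    "light_to_dark_ratio",
    "linear_unmix",
]


@dataclass
class CalibrationCurve:
    """Least-squares line of differential signal versus concentration."""

    concentrations: np.ndarray   # M, strictly increasing
    signals: np.ndarray          # image units
    slope: float
    intercept: float
    r_squared: float
    slope_warning: bool = False  # set when the fitted slope is <= 0


@dataclass
class QuantReport:
    """Per-region differential-signal statistics and derived quantities."""

    region_means: dict = field(default_factory=dict)
    region_cnr: dict = field(default_factory=dict)
    estimated_concentration_m: dict = field(default_factory=dict)
    detection_sensitivity_m: float | None = None
    relative_to_reference: dict = field(default_factory=dict)
    reference_region: str | None = None
    sigma_bg: float | None = None

    def to_dict(self) -> dict:
        return {
            "region_means": self.region_means,
            "region_cnr": self.region_cnr,
            "estimated_concentration_m": self.estimated_concentration_m,
            "detection_sensitivity_m": self.detection_sensitivity_m,
            "relative_to_reference": self.relative_to_reference,
            "reference_region": self.reference_region,
            "sigma_bg": self.sigma_bg,
        }


def fit_calibration(concentrations, signals) -> CalibrationCurve:
    """OLS of region-mean signal on known tube concentration."""
    conc = np.asarray(concentrations, dtype=float)
    sig = np.asarray(signals, dtype=float)
    if conc.size < 2:
        raise InputError("calibration needs at least 2 tubes")
    if conc.size != sig.size:
        raise InputError("concentrations and signals differ in length")
    if np.any(conc <= 0):
        raise InputError("calibration concentrations must be > 0")
    if not np.all(np.diff(conc) > 0):
        raise InputError("calibration concentrations must be strictly increasing")
    fit = stats.linregress(conc, sig)
    return CalibrationCurve(concentrations=conc, signals=sig,
                            slope=float(fit.slope),
                            intercept=float(fit.intercept),
                            r_squared=float(fit.rvalue) ** 2,
                            slope_warning=fit.slope <= 0)


def estimate_concentration(signal: float, curve: CalibrationCurve,
                           clip: bool = True) -> float:
    """Invert the calibration line: (signal - intercept) / slope."""
    if curve.slope <= 0:
        raise ConfigError("calibration curve has non-positive slope")
    conc = (float(signal) - curve.intercept) / curve.slope
    if clip and conc < 0:
        return 0.0
    return conc


def cnr(diff_map: np.ndarray, signal_mask: np.ndarray,
        background_mask: np.ndarray) -> float:
    """Contrast-to-noise ratio: (mean_sig - mean_bg) / std_bg."""
    signal_mask = np.asarray(signal_mask, dtype=bool)
    background_mask = np.asarray(background_mask, dtype=bool)
    if not signal_mask.any() or not background_mask.any():
        raise InputError("signal and background masks must be non-empty")
    if (signal_mask & background_mask).any():
        raise InputError("signal and background masks must be disjoint")
    bg = diff_map[background_mask]
    sd = float(np.std(bg, ddof=1))
    if sd == 0:
        raise InputError("background std is zero; CNR undefined")
    return float((diff_map[signal_mask].mean() - bg.mean()) / sd)


def detection_sensitivity(concentration_m: float, cnr_value: float) -> float:
    """Noise-equivalent concentration: concentration / CNR, in M."""
    if cnr_value <= 0:
        raise InputError("CNR must be > 0 for a detection sensitivity")
    return float(concentration_m) / float(cnr_value)


def organ_relative(diff_map: np.ndarray, organ_masks: dict,
                   reference: str = "liver") -> dict:
    """Per-organ mean differential signal normalized to a reference organ."""
    if reference not in organ_masks:
        raise InputError(f"reference organ {reference!r} not among masks")
    ref_mean = float(diff_map[np.asarray(organ_masks[reference], bool)].mean())
    if ref_mean <= 0:
        raise InputError("reference organ mean must be > 0 for normalization")
    return {name: float(diff_map[np.asarray(mask, bool)].mean()) / ref_mean
            for name, mask in organ_masks.items()}


def light_to_dark_ratio(full_light: float, full_dark: float,
                        reporter_light: float, reporter_dark: float) -> float:
    """Reporter-subtracted fold activation of light-induced expression.

    ``(full_light - reporter_light) / (full_dark - reporter_dark)`` where the
    reporter-only signals are the background produced without the
    transactivator component.
    """
    denom = full_dark - reporter_dark
    if denom <= 0:
        raise InputError(
            "reporter-subtracted dark signal must be > 0; the fold ratio is "
            "undefined otherwise")
    return (full_light - reporter_light) / denom


def linear_unmix(images: dict, lib: SpectralLibrary, species,
                 scale: float = 1.0) -> dict:
    """Pixelwise least-squares spectral unmixing baseline.

    ``images`` maps wavelength (nm) to a 2D image assumed proportional to
    ``scale * mu_a``; the system ``image = scale * ln(10)/10 * E c`` is
    solved per pixel for the species concentrations.  This is the
    traditional multi-wavelength approach whose accuracy degrades under
    wavelength-dependent fluence attenuation — the comparison point for
    single-wavelength differential detection.
    """
    wavelengths = sorted(images)
    species = list(species)
    if len(wavelengths) < len(species):
        raise UnmixingError(
            f"need at least {len(species)} wavelengths, got {len(wavelengths)}")
    E = np.array([[lib.lookup(sp, wl) for sp in species] for wl in wavelengths])
    E = E * (np.log(10.0) / 10.0) * scale
    if np.linalg.matrix_rank(E) < len(species):
        raise UnmixingError("extinction matrix is rank deficient")
    shape = images[wavelengths[0]].shape
    stack = np.stack([np.asarray(images[wl], float).ravel()
                      for wl in wavelengths], axis=0)
    coeffs, *_ = np.linalg.lstsq(E, stack, rcond=None)
    return {sp: coeffs[i].reshape(shape) for i, sp in enumerate(species)}
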