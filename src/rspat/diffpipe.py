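"""Differential-imaging pipeline: envelope, ON-OFF subtraction, thresholding.

The switchable probe is fully ON at the first imaging pulse of a cycle and
mostly OFF at the last, so the differential image — processed ON image
minus processed OFF image — cancels the non-switching hemoglobin
background.  Processing of each reconstructed frame is a Hilbert-transform
envelope followed by a 3x3 median filter.  Per-cycle differential maps are
averaged over cycles to beat down noise, the background noise level sigma
is the standard deviation outside the imaged region, and displayed maps
keep only pixels at or above 3 sigma (one-sided: the probe only adds
ON-state signal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, signal

from .errors import ConfigError, InputError
from .recon import ReconImage

__all__ = [
    "DifferentialResult",
    "TimeCourse",
    "run_pipeline",
    "envelope",
    "median3x3",
    "process_image",
    "make_state_images",
    "differential_image",
    "average_cycles",
    "noise_std_background",
    "threshold_mask",
    "extract_timecourse",
    "fit_switch_rate",
]


@dataclass
class DifferentialResult:
    """ON/OFF images, differential map, noise level and threshold mask."""

    on_image: np.ndarray
    off_image: np.ndarray
    diff_image: np.ndarray
    sigma_bg: float
    mask: np.ndarray
    masked_diff: np.ndarray
    per_cycle: np.ndarray = None   # (n_cycles, n_y, n_x)


@dataclass
class TimeCourse:
    """Region-mean processed signal per imaging pulse."""

    pulse_index: np.ndarray
    t_s: np.ndarray
    roi_mean: np.ndarray
    cycle_index: np.ndarray = None
    k_hat: float | None = None      # per pulse
    amplitude: float | None = None
    offset: float | None = None
    flat: bool = False


def envelope(image, axis: int = 1) -> np.ndarray:
    """Magnitude of the analytic signal along one image axis (>= 0)."""
    pixels = image.pixels if isinstance(image, ReconImage) else np.asarray(image)
    if not np.all(np.isfinite(pixels)):
        raise InputError("image must be finite")
    return np.abs(signal.hilbert(pixels, axis=axis))


def median3x3(image) -> np.ndarray:
    """3x3 median filter with reflecting borders."""
    pixels = image.pixels if isinstance(image, ReconImage) else np.asarray(image)
    if min(pixels.shape) < 3:
        raise InputError("image smaller than the 3x3 kernel")
    return ndimage.median_filter(pixels, size=3, mode="reflect")


def process_image(image, axis: int = 1) -> np.ndarray:
    """Standard per-frame processing: envelope then 3x3 median."""
    return median3x3(envelope(image, axis=axis))


def make_state_images(stack, m: int = 1, axis: int = 1):
    """(ON, OFF) images: means of the first and last m processed frames."""
    frames = list(stack)
    if m < 1 or 2 * m > len(frames):
        raise ConfigError(f"m={m} invalid for a stack of {len(frames)} frames")
    on = np.mean([process_image(f, axis=axis) for f in frames[:m]], axis=0)
    off = np.mean([process_image(f, axis=axis) for f in frames[-m:]], axis=0)
    return on, off


def differential_image(on_image: np.ndarray, off_image: np.ndarray) -> np.ndarray:
    """Pixelwise ON minus OFF."""
    on_image = np.asarray(on_image)
    off_image = np.asarray(off_image)
    if on_image.shape != off_image.shape:
        raise InputError(f"grid mismatch: {on_image.shape} vs {off_image.shape}")
    return on_image - off_image


def average_cycles(per_cycle_diffs) -> np.ndarray:
    """Pixelwise mean over per-cycle differential maps."""
    diffs = list(per_cycle_diffs)
    if not diffs:
        raise InputError("no cycles to average")
    return np.mean(diffs, axis=0)


def noise_std_background(diff_map: np.ndarray, background_mask) -> float:
    """Sample std of the differential signal outside the imaged region."""
    background_mask = np.asarray(background_mask, dtype=bool)
    if not background_mask.any():
        raise InputError("background mask is empty")
    return float(np.std(diff_map[background_mask], ddof=1))


def threshold_mask(diff_map: np.ndarray, sigma: float, k: float = 3.0):
    """One-sided threshold at k * sigma; returns (mask, masked map)."""
    if sigma < 0:
        raise InputError("sigma must be >= 0")
    if sigma == 0:
        mask = diff_map > 0
    else:
        mask = diff_map >= k * sigma
    masked = np.where(mask, diff_map, 0.0)
    return mask, masked


def extract_timecourse(stack, roi_mask, axis: int = 1) -> TimeCourse:
    """Per-pulse ROI mean of processed frames, ordered by pulse time."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise InputError("ROI mask is empty")
    frames = sorted(stack, key=lambda f: (f.cycle_index, f.pulse_index))
    means = [float(process_image(f, axis=axis)[roi_mask].mean()) for f in frames]
    return TimeCourse(
        pulse_index=np.array([f.pulse_index for f in frames]),
        t_s=np.array([float(f.meta.get("t_s", f.pulse_index)) for f in frames]),
        roi_mean=np.array(means),
        cycle_index=np.array([f.cycle_index for f in frames]),
    )


def fit_switch_rate(tc, flat_rtol: float = 1e-12) -> TimeCourse:
    """Least-squares fit of ``A exp(-k n) + b`` over pulse index n.

    Quantifies the within-phase OFF-switching decay of the ROI signal.
    Returns the time course with ``k_hat`` (per pulse), ``amplitude`` and
    ``offset`` filled in; a flat signal yields ``k_hat = 0`` with the
    ``flat`` flag set.
    """
    if isinstance(tc, TimeCourse):
        n = np.asarray(tc.pulse_index, dtype=float)
        y = np.asarray(tc.roi_mean, dtype=float)
    else:
        y = np.asarray(tc, dtype=float)
        n = np.arange(y.size, dtype=float)
        tc = TimeCourse(pulse_index=n.astype(int), t_s=n, roi_mean=y)
    if not np.all(np.isfinite(y)):
        raise InputError("time course contains non-finite values")
    if y.size < 4:
        raise InputError("need at least 4 points to fit a switching rate")
    n = n - n[0]
    span = float(y.max() - y.min())
    scale = max(abs(y).max(), 1.0)
    if span <= flat_rtol * scale:
        tc.k_hat, tc.amplitude, tc.offset, tc.flat = 0.0, 0.0, float(y.mean()), True
        return tc
    b0 = float(y.min())
    a0 = float(y[0] - b0) or span
    pos = (y[:2] - b0) > 0
    k0 = 0.5
    if pos.all() and y[1] != y[0]:
        with np.errstate(divide="ignore", invalid="ignore"):
            g = np.log(max(y[0] - b0, 1e-30)) - np.log(max(y[1] - b0, 1e-30))
        if np.isfinite(g) and g > 0:
            k0 = float(np.clip(g, 1e-3, 5.0))

    def model(nn, a, k, b):
        return a * np.exp(-k * nn) + b

    popt, _ = optimize.curve_fit(model, n, y, p0=[a0, k0, b0],
                                 bounds=([-np.inf, 0.0, -np.inf],
                                         [np.inf, 50.0, np.inf]),
                                 maxfev=20000)
    tc.k_hat, tc.amplitude, tc.offset = float(popt[1]), float(popt[0]), float(popt[2])
    tc.flat = False
    return tc


def __getattr__(name):
    # run_pipeline lives in rspat.pipeline (it orchestrates every stage) but
    # is part of this module's surface; resolve lazily to avoid an import
    # cycle.
    if name == "run_pipeline":
        from .pipeline import run_pipeline
        return run_pipeline
    raise AttributeError(name)
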