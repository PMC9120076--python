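"""Reference experiments: self-contained, seedable analysis recipes.

Each function builds its own phantoms and configuration, runs the relevant
slice of the pipeline, and returns plain numbers.  They encode the package's
canonical validation scenarios — ON/OFF contrast of a probe inclusion,
hemoglobin background suppression, point-source localization, cycle
averaging, end-to-end concentration linearity, and the differential versus
spectral-unmixing comparison under depth-dependent fluence.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import ndimage

from .acoustics import (AcousticsConfig, RingArrayGeometry, Sinogram,
                        TransducerResponse, add_noise, simulate_acquisition)
from .diffpipe import (average_cycles, differential_image, fit_switch_rate,
                       make_state_images, noise_std_background, process_image,
                       threshold_mask)
from .phantoms import make_crosssection_phantom, make_tube_phantom
from .quant import fit_calibration, estimate_concentration, linear_unmix
from .recon import das_reconstruct, ubp_reconstruct
from .spectra_kinetics import (IlluminationSchedule, KineticsParams,
                               default_spectra, pfr_trajectory)

__all__ = [
    "onoff_contrast",
    "background_suppression",
    "recon_localization",
    "kinetics_recovery",
    "averaging_law",
    "concentration_linearity",
    "unmixing_comparison",
]


def _first_last_diff(phantom, lib, schedule, kin, geom, resp, cfg):
    """Processed ON/OFF images and their difference for cycle pulses
    (first, last) of every cycle; returns (on0, off0, averaged diff)."""
    n_pulses = schedule.pulses_per_cycle
    subset = [(c, j) for c in range(schedule.n_cycles)
              for j in (0, n_pulses - 1)]
    sinos = simulate_acquisition(phantom, lib, schedule, kin, geom,
                                 resp=resp, cfg=cfg, pulse_subset=subset)
    per_cycle, on0 = [], None
    for c in range(schedule.n_cycles):
        pair = [s for s in sinos if s.cycle_index == c]
        imgs = [ubp_reconstruct(s, phantom.shape, phantom.pixel_size_mm)
                for s in pair]
        on, off = make_state_images(imgs, m=1)
        if c == 0:
            on0, off0 = on, off
        per_cycle.append(differential_image(on, off))
    return on0, off0, average_cycles(per_cycle)


def onoff_contrast(seed: int = 1, concentration_m: float = 2e-6) -> dict:
    """ON/OFF amplitude ratio of a probe inclusion at the imaging wavelength.

    A single tube-style inclusion of purified probe (default 2 uM, the
    cell-pellet scale) is imaged noiselessly over one full photoswitching
    cycle; the first-pulse (fully ON) and last-pulse (fully OFF) frames are
    reconstructed, envelope-processed, and compared inside the inclusion
    mask.  The expected ratio is the Pfr/Pr extinction contrast at 750 nm.
    """
    lib = default_spectra()
    phantom = make_tube_phantom([concentration_m], seed=seed)
    schedule = IlluminationSchedule(n_cycles=1)
    on, off, _ = _first_last_diff(phantom, lib, schedule, KineticsParams(),
                                  RingArrayGeometry(), TransducerResponse(),
                                  AcousticsConfig(noise_std=0.0, seed=seed))
    mask = phantom.masks["tube_0"]
    on_mean = float(on[mask].mean())
    off_mean = float(off[mask].mean())
    return {"on_mean": on_mean, "off_mean": off_mean,
            "ratio": on_mean / off_mean,
            "n_pixels": int(mask.sum())}


def background_suppression(seed: int = 1, n_cycles: int = 4,
                           noise_std: float = 1e-3) -> dict:
    """Differential suppression of the non-switching hemoglobin background.

    A hemoglobin-only cross-section (vessels + perfused tissue, zero probe)
    is run through the differential pipeline.  Noiselessly the ON and OFF
    frames are identical, so the vessel differential should vanish relative
    to the ON-state vessel signal; with noise, the 3-sigma threshold mask
    should keep only the Gaussian tail fraction of pixels.
    """
    lib = default_spectra()
    phantom = make_crosssection_phantom({}, n_vessels=12,
                                        tissue_hb_total_m=3e-5,
                                        organ_hb_total_m=1e-4, seed=seed)
    geom = RingArrayGeometry()
    resp = TransducerResponse()
    kin = KineticsParams()
    # Noiseless: vessel residual relative to ON-state vessel signal.
    on, _, diff0 = _first_last_diff(phantom, lib, IlluminationSchedule(),
                                    kin, geom, resp,
                                    AcousticsConfig(noise_std=0.0, seed=seed))
    vessel = phantom.masks["vessel"]
    residual = float(np.abs(diff0[vessel]).mean() / on[vessel].mean())
    # Noisy: surviving fraction of the 3-sigma mask.
    schedule = IlluminationSchedule(n_cycles=n_cycles)
    _, _, diff = _first_last_diff(phantom, lib, schedule, kin, geom, resp,
                                  AcousticsConfig(noise_std=noise_std,
                                                  seed=seed))
    sigma = noise_std_background(diff, phantom.masks["background"])
    mask, _ = threshold_mask(diff, sigma, k=3.0)
    return {"vessel_residual_fraction": residual,
            "mask_fraction": float(mask.mean()),
            "sigma_bg": sigma}


def recon_localization(seed: int = 1, n_sources: int = 5) -> dict:
    """Forward-then-invert oracle: point sources in the central half-field.

    Reports the largest UBP peak-localization error (pixels) and the
    largest UBP/DAS peak disagreement over randomly drawn source positions.
    """
    rng = np.random.default_rng(seed)
    geom = RingArrayGeometry()
    shape, px = (256, 256), 0.1
    from .acoustics import forward_project

    max_err = 0.0
    max_disagree = 0.0
    half = min(shape) // 4   # central half-field in each dimension
    for _ in range(n_sources):
        iy = int(rng.integers(shape[0] // 2 - half, shape[0] // 2 + half))
        ix = int(rng.integers(shape[1] // 2 - half, shape[1] // 2 + half))
        p0 = np.zeros(shape)
        p0[iy, ix] = 1.0
        sino = forward_project(p0, geom, px)
        pu = np.unravel_index(np.argmax(ubp_reconstruct(sino, shape, px).pixels),
                              shape)
        pd = np.unravel_index(np.argmax(das_reconstruct(sino, shape, px).pixels),
                              shape)
        max_err = max(max_err, float(np.hypot(pu[0] - iy, pu[1] - ix)))
        max_disagree = max(max_disagree,
                           float(np.hypot(pu[0] - pd[0], pu[1] - pd[1])))
    return {"max_peak_error_px": max_err,
            "max_ubp_das_disagreement_px": max_disagree,
            "n_sources": n_sources}


def kinetics_recovery(seed: int = 1) -> dict:
    """Rate-fit accuracy and the trajectory-integrator oracle.

    (a) ``fit_switch_rate`` on a noiseless synthetic exponential must
    recover the decay rate; (b) the event-based Pfr-trajectory integrator
    must match a brute-force fine-step Euler integration of the same
    photoswitching dynamics on the default schedule.
    """
    rng = np.random.default_rng(seed)
    k_true = float(rng.uniform(0.05, 0.5))
    n = np.arange(40, dtype=float)
    y = 1.7 * np.exp(-k_true * n) + 0.3
    tc = fit_switch_rate(y)
    k_err = abs(tc.k_hat - k_true) / k_true

    schedule = IlluminationSchedule(n_cycles=2)
    kin = KineticsParams()
    traj = pfr_trajectory(schedule, kin, f0=0.0)
    f_euler = _euler_trajectory(schedule, kin, f0=0.0, dt=1e-4)
    max_df = float(np.max(np.abs(traj.f - f_euler)))
    return {"rate_rel_error": float(k_err), "k_true": k_true,
            "max_trajectory_dev": max_df}


def _euler_trajectory(schedule, kin, f0, dt=1e-4):
    """Brute-force fine-step Euler oracle for the Pfr trajectory."""
    f = float(f0)
    out = []
    n_pulses = schedule.pulses_per_cycle
    for _ in range(schedule.n_cycles):
        t = 0.0
        while t < schedule.t_on_phase - 0.5 * dt:
            f += kin.k_on * (1.0 - f) * dt
            t += dt
        pulse_ts = [j / schedule.pulse_rate for j in range(n_pulses)]
        t = 0.0
        next_pulse = 0
        while t < schedule.t_imaging_phase - 0.5 * dt:
            while (next_pulse < n_pulses
                   and pulse_ts[next_pulse] <= t + 0.5 * dt):
                out.append(f)
                f *= 1.0 - kin.delta_off_pulse
                next_pulse += 1
            if t >= schedule.t_790_delay:
                f -= kin.k_off_cw * f * dt
            t += dt
        while next_pulse < n_pulses:
            out.append(f)
            f *= 1.0 - kin.delta_off_pulse
            next_pulse += 1
    return np.asarray(out)


def averaging_law(seed: int = 1, n_cycles: int = 24, n_repeats: int = 3,
                  noise_std: float = 1e-3) -> dict:
    """1/sqrt(n) noise reduction from cycle averaging.

    Pure-noise acquisitions (empty object) are differenced per cycle and
    averaged; the background standard deviation of the n-cycle average is
    compared against the single-cycle value divided by sqrt(n), Monte-Carlo
    averaged over seeds.  Uses a reduced 128-element geometry: the scaling
    law is geometry independent.
    """
    geom = RingArrayGeometry(n_elements=128, n_samples=560)
    shape, px = (128, 128), 0.2
    resp = TransducerResponse()
    zero = np.zeros((geom.n_elements, geom.n_samples))
    ratios = []
    for rep in range(n_repeats):
        per_cycle = []
        for c in range(n_cycles):
            imgs = []
            for pulse in range(2):
                s = Sinogram(zero.copy(), geom)
                s = add_noise(s, noise_std,
                              np.random.SeedSequence([seed, rep, c, pulse]))
                imgs.append(process_image(
                    ubp_reconstruct(s, shape, px)))
            per_cycle.append(imgs[0] - imgs[1])
        sigma_1 = float(np.std(per_cycle[0], ddof=1))
        sigma_n = float(np.std(average_cycles(per_cycle), ddof=1))
        ratios.append(sigma_1 / (sigma_n * np.sqrt(n_cycles)))
    return {"mean_ratio": float(np.mean(ratios)), "n_cycles": n_cycles,
            "n_repeats": n_repeats}


def _single_tube_diff_mean(conc, lib, schedule, kin, geom, resp, cfg):
    phantom = make_tube_phantom([conc], seed=0)
    _, _, diff = _first_last_diff(phantom, lib, schedule, kin, geom, resp, cfg)
    return float(diff[phantom.masks["tube_0"]].mean())


def concentration_linearity(seed: int = 1,
                            calibration_m=(1e-8, 1e-7, 1e-6, 1e-5),
                            test_m=(5e-8, 2e-7, 5e-7, 2e-6, 5e-6)) -> dict:
    """End-to-end concentration recovery via tube calibration (noiseless).

    Calibration tubes spanning 10 nM - 10 uM are imaged one at a time in
    the sample position (matching the fixed-position side-by-side
    measurement protocol), a signal-versus-concentration line is fitted,
    and independent test tubes over 50 nM - 5 uM are quantified against it.
    Returns the regression slope and r^2 of estimated versus true
    concentration.
    """
    lib = default_spectra()
    schedule = IlluminationSchedule(n_cycles=1)
    kin = KineticsParams()
    geom = RingArrayGeometry()
    resp = TransducerResponse()
    cfg = AcousticsConfig(noise_std=0.0, seed=seed)
    cal_signals = [_single_tube_diff_mean(c, lib, schedule, kin, geom, resp, cfg)
                   for c in calibration_m]
    curve = fit_calibration(calibration_m, cal_signals)
    estimates = []
    for c in test_m:
        sig = _single_tube_diff_mean(c, lib, schedule, kin, geom, resp, cfg)
        estimates.append(estimate_concentration(sig, curve))
    from scipy import stats

    fit = stats.linregress(np.asarray(test_m), np.asarray(estimates))
    return {"slope": float(fit.slope), "r_squared": float(fit.rvalue) ** 2,
            "calibration_r_squared": curve.r_squared,
            "estimates_m": estimates}


def unmixing_comparison(seed: int = 1,
                        mu_eff=( (680.0, 0.20), (750.0, 0.10) )) -> dict:
    """Differential detection versus two-wavelength spectral unmixing.

    A perfused cross-section with probe-bearing organs is imaged under
    depth-attenuated fluence whose effective attenuation differs between
    wavelengths.  Spectral unmixing (blood + ON-state probe, assuming
    uniform fluence) is distorted by the wavelength-dependent attenuation;
    the single-wavelength differential estimate is not.  Returns the RMSE
    of each probe-concentration map against the ground truth over the body.
    """
    lib = default_spectra()
    phantom = make_crosssection_phantom(
        {"liver": 1e-6, "spleen": 5e-7}, n_vessels=10,
        tissue_hb_total_m=3e-5, organ_hb_total_m=1e-4, seed=seed)
    body = phantom.masks["body"]
    depth = ndimage.distance_transform_edt(body) * phantom.pixel_size_mm
    schedule = IlluminationSchedule(n_cycles=1)
    kin = KineticsParams()
    geom = RingArrayGeometry()
    resp = TransducerResponse()
    mu_eff = dict(mu_eff)
    wl_img = schedule.imaging_wavelength_nm

    # Reconstruction gain: processed-image amplitude per unit p0, measured
    # on a fully-ON calibration tube under uniform fluence.
    tube = make_tube_phantom([2e-6], seed=0)
    cfg0 = AcousticsConfig(noise_std=0.0, seed=seed)
    on_t, _, _ = _first_last_diff(tube, lib, schedule, kin, geom, resp, cfg0)
    from .spectra_kinetics import absorption_map

    p0_tube = cfg0.gamma * cfg0.fluence_mj_cm2 * absorption_map(
        tube, lib, wl_img, f=1.0)
    tmask = tube.masks["tube_0"]
    gain = float(on_t[tmask].mean() / p0_tube[tmask].mean())

    traj = pfr_trajectory(schedule, kin)
    f_on = traj.pulse(0, 0)
    f_off = traj.pulse(0, schedule.pulses_per_cycle - 1)

    # ON-state images at the two wavelengths under attenuated fluence.
    images = {}
    for wl, mu in mu_eff.items():
        sched_wl = replace(schedule, imaging_wavelength_nm=wl)
        cfg = AcousticsConfig(noise_std=0.0, fluence_mode="attenuated",
                              mu_eff_per_mm=mu, seed=seed)
        sinos = simulate_acquisition(phantom, lib, sched_wl, kin, geom,
                                     resp=resp, cfg=cfg,
                                     pulse_subset=[(0, 0)],
                                     depth_map_mm=depth)
        images[wl] = process_image(
            ubp_reconstruct(sinos[0], phantom.shape, phantom.pixel_size_mm))

    # Unmixing assumes uniform nominal fluence: scale = gain * Gamma * F.
    scale = gain * cfg0.gamma * cfg0.fluence_mj_cm2
    blood = {wl: 0.8 * lib.lookup("HbO2", wl) + 0.2 * lib.lookup("HbR", wl)
             for wl in mu_eff}

    class _BloodLib:
        epsilon = {"blood": None, "BphP1_Pfr": None}

        def lookup(self, sp, wl):
            return blood[wl] if sp == "blood" else lib.lookup(sp, wl)

    unmixed = linear_unmix(images, _BloodLib(), ["blood", "BphP1_Pfr"],
                           scale=scale)
    c_unmix = unmixed["BphP1_Pfr"]

    # Differential estimate at the imaging wavelength, same fluence model.
    cfg750 = AcousticsConfig(noise_std=0.0, fluence_mode="attenuated",
                             mu_eff_per_mm=mu_eff[wl_img], seed=seed)
    n_last = schedule.pulses_per_cycle - 1
    sinos = simulate_acquisition(phantom, lib, schedule, kin, geom, resp=resp,
                                 cfg=cfg750, pulse_subset=[(0, 0), (0, n_last)],
                                 depth_map_mm=depth)
    on = process_image(ubp_reconstruct(sinos[0], phantom.shape,
                                       phantom.pixel_size_mm))
    off = process_image(ubp_reconstruct(sinos[1], phantom.shape,
                                        phantom.pixel_size_mm))
    d_eps = (f_on - f_off) * (lib.lookup("BphP1_Pfr", wl_img)
                              - lib.lookup("BphP1_Pr", wl_img))
    c_diff = (on - off) / (scale * (np.log(10.0) / 10.0) * d_eps)

    truth = phantom.maps["BphP1"]
    rmse_diff = float(np.sqrt(np.mean((c_diff - truth)[body] ** 2)))
    rmse_unmix = float(np.sqrt(np.mean((c_unmix - truth)[body] ** 2)))
    return {"rmse_differential_m": rmse_diff, "rmse_unmixing_m": rmse_unmix,
            "ratio": rmse_diff / rmse_unmix}
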