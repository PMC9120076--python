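# Methods

This note documents the models behind `rspat`, the parameters that matter,
the design choices made where the design was genuinely open, and what the
synthetic data do and do not show about real acquisitions.

## Photoswitching kinetics

The switchable probe is modeled as a two-state system: the Pfr ("ON")
fraction `f ∈ [0, 1]`, with Pr = 1 − f at all times. One cycle is

* **Switching-ON phase** (default 8 s, 635 nm continuous wave):
  `df/dt = k_on (1 − f)`, solved exactly as a mono-exponential.
* **Imaging phase** (default 8 s, 750 nm pulses at 10 Hz): the sampled
  value at each pulse is the pre-pulse state — the pulse that measures the
  probe also switches it, multiplying `f` by `(1 − δ)` immediately after.
  From `t_790_delay` (default 6 s) into the phase, 790 nm continuous-wave
  light adds an exponential decay at `k_off_cw`, propagated analytically
  between pulses.

No numeric switching rates are published for this illumination geometry,
so the defaults are effective phase-level rates chosen once so that the
cycle reproduces the qualitative behaviour the method requires: `k_on =
1.0 s⁻¹` (f ≈ 0.9997 at the first imaging pulse), `δ = 0.15` per pulse and
`k_off_cw = 0.5 s⁻¹` (f < 10⁻⁵ at the last pulse). All three are
configuration values, not fitted constants. Rates are not derived from
photon flux or quantum yields (neither is available); thermal dark
reversion and photobleaching are omitted — the photoswitching is treated
as fully reversible, and the trajectory reaches a periodic steady state
from the second cycle on. The ON wavelength is a config value (default
635 nm) since the hardware description gives both 630 and 635 nm. Whether
the pulsed light's OFF-switching is per-pulse or effectively continuous is
not documented; it is modeled per-pulse, which at 80 pulses/cycle is
indistinguishable from a continuous rate of `−ln(1−δ)·rate`.

An event-based integrator computes `f` exactly at each pulse; the test
suite checks it against a brute-force Euler integration at dt = 10⁻⁴ s.

## Optical model

Molar extinction spectra for HbO2, HbR and the probe's Pfr/Pr states are
tabulated at 5 nm steps over 600–900 nm and interpolated linearly. The
hemoglobin values follow the scale and shape of standard whole-blood
compilations; the Pfr/Pr bands are Gaussian models of published
bacterial-phytochrome absorption spectra (Pfr peak ≈ 755 nm, Pr peak ≈
680 nm, Pfr/Pr contrast 11.0 at 750 nm). They are configuration data:
absolute accuracy is not claimed, only the band locations and the ≥ 5-fold
ON/OFF contrast at the imaging wavelength, which the suite asserts.

Absorption is `μ_a = ln(10) Σ ε_i(λ) c_i / 10` (mm⁻¹, concentrations in M,
ε in M⁻¹cm⁻¹) and initial pressure `p0 = Γ F μ_a` with Grüneisen Γ = 0.2
and surface fluence F = 5 mJ/cm² — pure scale factors in this
arbitrary-units pipeline, kept explicit so fluence modes stay meaningful.
Fluence is uniform by default; an exponentially depth-attenuated mode
(`F e^{−μ_eff d}`, depth measured from the body outline) exercises the
wavelength-dependent-attenuation scenario that separates differential
detection from spectral unmixing.

## Phantoms

All phantoms are 2D cross-sections on a 256×256 grid at 0.1 mm/pixel
(25.6 mm field, a mouse-trunk scale); the ring array images a thin slab, so
a single slice is the desk-scale analogue. Coordinates: origin at grid
center, y down. Generators are pure functions of (config, seed).

* **Tubes** — disk cross-sections of probe solution with zero hemoglobin,
  labeled in input order; one tube sits at the center, several sit on a
  ring ("side by side"). Default radius 3 mm, the Eppendorf scale of the
  calibration measurements — matching the calibration-object size to the
  organ size keeps the band-limited reconstruction gain comparable between
  calibration and sample.
* **Cross-section** — an elliptical body with four disjoint organ regions
  (liver, spleen, stomach, intestine) at configurable probe levels
  (~100 nM scale), discrete whole-blood vessels (2.3 mM heme, 80% SO2)
  placed randomly outside the organs, and optional diffuse capillary
  perfusion co-located with tissue (default in the pipeline configuration:
  30 µM heme in tissue, 100 µM in organs, 70% SO2). The organ hemoglobin
  content in vivo is not pinned down; it is exposed as configuration. The
  perfusion term matters: real organs carry blood in the same voxels as the
  probe, which keeps the local acoustic field coherent so the envelope
  differential is exact; a probe-only organ surrounded by strong incoherent
  vessel clutter would lose differential signal through the envelope
  nonlinearity.
* **Embryos** — disks of probe-bearing tissue placed by rejection sampling
  at 1–7 mm depth inside a maternal body with vessel background,
  reproducing the multi-embryo abdomen scenario (seven embryos by
  default).
* **Motion** — a rigid sinusoidal translation (breathing analogue) with
  bilinear map interpolation and nearest-neighbour masks.

## Acoustics and reconstruction

Desk-scale geometry: 256 point elements on a 20 mm-radius full ring,
20 MHz sampling, homogeneous c = 1.5 mm/µs — a scaled-down analogue of a
512-element, 4 cm ring scanner chosen to keep a full differential
experiment in seconds per frame on one CPU. Element directivity and
cylindrical focusing are not modeled in 2D.

The forward operator bins pixels into travel-time annuli per element
(linear split between adjacent time samples, then a 3-tap triangular
smoothing because the 0.1 mm pixel footprint is wider than the 0.075 mm
radial bin), yielding `t·M(ct)` up to a constant; the signal is its time
derivative. The transducer is a zero-phase second-order Butterworth
band-pass (4 MHz center, 80% fractional bandwidth, applied
forward-backward), and noise is i.i.d. Gaussian per sample with substreams
indexed by (cycle, pulse) so any pulse subset reproduces the corresponding
frames of a full acquisition bit for bit.

Universal back-projection uses the filtered term `b(t) = 2p − 2t ∂p/∂t`
evaluated at each pixel's travel time with inverse-distance weights; on a
full ring the solid-angle weights reduce to uniform angular weights.
Derivatives are central differences; pixels outside the ring are not
reconstructed. The delay-and-sum cross-check beamforms the per-element
signal envelope (the raw far-field signal is bipolar with a zero crossing
at the arrival time, so envelope beamforming is what makes plain DAS peak
at the source). Point sources anywhere in the central half-field localize
to ≤ 1 pixel under both methods, and they agree with each other.

The default noise level (10⁻³ pressure units, ~0.5% of the peak blood
signal) makes the single-shot differential noise comparable to the
reconstruction-artifact floor, so the default 24-cycle average is
artifact-limited — the regime of a well-averaged acquisition.

## Differential pipeline and quantification

Per frame: Hilbert envelope along image rows (the axis is configurable;
no axis is prescribed by the method description), then a 3×3 median filter
with reflecting borders. ON and OFF images are the means of the first and
last `m` processed frames of each cycle (`m = 1` by default, mirroring
"beginning and end of cycle"); the differential is ON − OFF, averaged over
cycles, with the threshold applied after averaging to the displayed map
only — raw differentials are always retained for quantification. The
threshold is one-sided at 3σ (the probe only adds ON-state signal), with σ
the sample standard deviation over the background mask outside the imaged
region.

Calibration fits signal on concentration by ordinary least squares with an
intercept (envelope images are non-negative, giving a positive floor that
the intercept absorbs). CNR is (region mean − background mean)/background
std; detection sensitivity is concentration/CNR (noise-equivalent
concentration). The optogenetic fold-ratio statistic
`(full_light − reporter_light)/(full_dark − reporter_dark)` is provided as
a scalar operation. The spectral-unmixing baseline solves the pixelwise
least-squares system `image = scale · ln10/10 · E c` under a
uniform-fluence assumption, which is exactly the assumption that
depth-dependent, wavelength-dependent attenuation violates — the
comparison experiment quantifies this as probe-map RMSE against ground
truth, with both methods sharing a single reconstruction-gain factor
measured on a calibration tube.

## Problem sizes and numerical choices

The validation experiments run at the default 256-element geometry except
the cycle-averaging statistic, which uses a 128-element, 128² geometry (the
1/√n law is geometry independent). End-to-end runs simulate only the
pulses the analysis consumes (first/last `m` of each cycle plus a strided
subset for time courses); the trajectory is always integrated over the
full schedule, and per-(cycle, pulse) noise substreams make the subset
exactly consistent with a full acquisition. Calibration and test tubes in
the linearity experiment are imaged one at a time in the sample position:
at desk scale the reconstruction streaks of a 10 µM tube would otherwise
contaminate a 10 nM neighbour by far more than its own signal, an artifact
of the reduced element count rather than of the method.

Degenerate inputs: flat time courses return a zero rate with a flag rather
than a fit; zero-σ thresholds keep strictly positive support; empty masks,
non-increasing calibration concentrations, rank-deficient unmixing systems
and sub-Nyquist band edges raise typed errors.

## Known limitations

* The forward model is the far-field circular-mean form, not a full wave
  solver; acoustic attenuation and heterogeneity are not modeled.
* Desk-scale reconstruction (256 elements) leaves a streak/clutter floor
  about 10% of a strong object's differential amplitude. Consequences:
  contrast-to-noise saturates near 10 for a 2 µM inclusion regardless of
  averaging (the hardware-scale noise-equivalent sensitivity of tens of nM
  is out of reach at this element count), and pixel-level agreement
  between the 3σ mask and the true probe support is poor (the mask halo
  from envelope blurring and band-pass ringing is large compared with a
  clean background σ). Detection is therefore validated at region level —
  region means against 3σ — and suppression as vessel-residual fractions.
* Band-limited detection suppresses the low-frequency interior of large
  uniform objects; quantification is calibrated with size-matched tubes
  and reported as region means, as in the laboratory protocol.
* Phantoms are geometric primitives, not anatomical atlases; motion is a
  rigid translation; 3D effects (out-of-plane signal, elevational focus)
  are absent. Passing tests demonstrate the correctness and internal
  consistency of the analysis chain, not hardware-level image quality.
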