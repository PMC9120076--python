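"""Calibration, CNR, sensitivity, fold ratios, spectral unmixing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rspat.errors import ConfigError, InputError, UnmixingError
from rspat.quant import (cnr, detection_sensitivity, estimate_concentration,
                         fit_calibration, light_to_dark_ratio, linear_unmix,
                         organ_relative)


class TestCalibration:
    def test_exact_linear_data(self):
        conc = np.array([1e-8, 1e-7, 1e-6])
        curve = fit_calibration(conc, 5.0 * conc)
        assert curve.slope == pytest.approx(5.0)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)
        assert curve.r_squared == pytest.approx(1.0)

    def test_offset_moves_only_intercept(self):
        conc = np.array([1e-8, 1e-7, 1e-6])
        c1 = fit_calibration(conc, 5.0 * conc)
        c2 = fit_calibration(conc, 5.0 * conc + 2.0)
        assert c2.slope == pytest.approx(c1.slope)
        assert c2.intercept == pytest.approx(c1.intercept + 2.0)

    def test_too_few_tubes_raise(self):
        with pytest.raises(InputError):
            fit_calibration([1e-7], [1.0])

    def test_non_increasing_concentrations_raise(self):
        with pytest.raises(InputError):
            fit_calibration([1e-7, 1e-8], [1.0, 2.0])

    def test_negative_slope_flagged(self):
        curve = fit_calibration([1e-8, 1e-7], [2.0, 1.0])
        assert curve.slope_warning


class TestEstimateConcentration:
    def test_round_trip_on_calibration_points(self):
        conc = np.array([1e-8, 1e-7, 1e-6, 1e-5])
        curve = fit_calibration(conc, 7.0 * conc + 0.3)
        for c in conc:
            assert estimate_concentration(7.0 * c + 0.3, curve) == \
                pytest.approx(c, rel=1e-9)

    def test_signal_at_intercept_maps_to_zero(self):
        curve = fit_calibration([1e-8, 1e-7], [1.1, 2.0])
        assert estimate_concentration(curve.intercept, curve) == \
            pytest.approx(0.0, abs=1e-15)

    def test_negative_estimates_clipped_with_default(self):
        curve = fit_calibration([1e-8, 1e-7], [1.0, 2.0])
        assert estimate_concentration(0.0, curve) == 0.0

    def test_invalid_curve_raises(self):
        curve = fit_calibration([1e-8, 1e-7], [2.0, 1.0])
        with pytest.raises(ConfigError):
            estimate_concentration(1.5, curve)


class TestCnrAndSensitivity:
    def test_equal_means_give_zero(self):
        img = np.zeros((32, 32))
        sig = np.zeros_like(img, bool)
        sig[:4, :4] = True
        bg = np.zeros_like(img, bool)
        bg[16:, :] = True
        img[bg] = np.random.default_rng(0).normal(0, 0.1, bg.sum())
        img[sig] = img[bg].mean()
        assert cnr(img, sig, bg) == pytest.approx(0.0, abs=1e-9)

    def test_constructed_value(self):
        """Signal 10 over N(0, 2) background -> CNR near 5."""
        rng = np.random.default_rng(1)
        img = np.zeros((200, 200))
        bg = np.zeros_like(img, bool)
        bg[100:, :] = True
        img[bg] = rng.normal(0, 2.0, bg.sum())
        sig = np.zeros_like(img, bool)
        sig[:50, :] = True
        img[sig] = 10.0
        assert cnr(img, sig, bg) == pytest.approx(5.0, rel=0.05)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        img = rng.normal(size=(64, 64))
        sig = np.zeros_like(img, bool)
        sig[:8, :8] = True
        bg = np.zeros_like(img, bool)
        bg[32:, 32:] = True
        assert cnr(3.0 * img + 7.0, sig, bg) == pytest.approx(
            cnr(img, sig, bg), rel=1e-9)

    def test_overlapping_masks_raise(self):
        img = np.zeros((8, 8))
        mask = np.ones((8, 8), bool)
        with pytest.raises(InputError):
            cnr(img, mask, mask)

    def test_sensitivity_formula(self):
        """2 uM at CNR 50 -> 40 nM noise-equivalent sensitivity."""
        assert detection_sensitivity(2e-6, 50.0) == pytest.approx(40e-9)

    def test_sensitivity_scales_linearly(self):
        assert detection_sensitivity(4e-6, 50.0) == \
            pytest.approx(2 * detection_sensitivity(2e-6, 50.0))

    def test_nonpositive_cnr_raises(self):
        with pytest.raises(InputError):
            detection_sensitivity(2e-6, 0.0)


class TestOrganRelative:
    def _masks(self):
        masks = {}
        for k, name in enumerate(("liver", "spleen", "stomach")):
            m = np.zeros((32, 32), bool)
            m[:, 10 * k:10 * k + 8] = True
            masks[name] = m
        return masks

    def test_reference_maps_to_one(self):
        masks = self._masks()
        img = np.zeros((32, 32))
        for name, level in (("liver", 5.0), ("spleen", 2.0), ("stomach", 1.0)):
            img[masks[name]] = level
        rel = organ_relative(img, masks, reference="liver")
        assert rel["liver"] == 1.0
        assert rel["spleen"] == pytest.approx(0.4)

    def test_missing_reference_raises(self):
        with pytest.raises(InputError):
            organ_relative(np.ones((32, 32)), self._masks(), reference="brain")

    def test_nonpositive_reference_raises(self):
        with pytest.raises(InputError):
            organ_relative(np.zeros((32, 32)), self._masks())


class TestLightToDarkRatio:
    def test_no_induction_gives_unity(self):
        assert light_to_dark_ratio(10.0, 10.0, 3.0, 3.0) == pytest.approx(1.0)

    def test_worked_arithmetic(self):
        assert light_to_dark_ratio(120.0, 20.0, 4.0, 2.0) == \
            pytest.approx(116.0 / 18.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale=st.floats(1e-3, 1e3))
    def test_common_scaling_invariance(self, scale):
        base = light_to_dark_ratio(120.0, 20.0, 4.0, 2.0)
        scaled = light_to_dark_ratio(120.0 * scale, 20.0 * scale,
                                     4.0 * scale, 2.0 * scale)
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_nonpositive_denominator_raises(self):
        with pytest.raises(InputError):
            light_to_dark_ratio(10.0, 1.0, 5.0, 2.0)


class TestOrganEstimateEndToEnd:
    def test_perfused_organ_at_100_nM_recovered_within_15_percent(self, lib):
        """Tube-calibrated, full-pipeline estimate of a 100 nM organ."""
        from rspat.acoustics import (AcousticsConfig, RingArrayGeometry,
                                     TransducerResponse)
        from rspat.experiments import _first_last_diff, _single_tube_diff_mean
        from rspat.phantoms import make_crosssection_phantom
        from rspat.spectra_kinetics import (IlluminationSchedule,
                                            KineticsParams)

        sched = IlluminationSchedule(n_cycles=1)
        kin, geom = KineticsParams(), RingArrayGeometry()
        resp, cfg = TransducerResponse(), AcousticsConfig(noise_std=0.0)
        concs = [1e-8, 1e-7, 1e-6, 1e-5]
        signals = [_single_tube_diff_mean(c, lib, sched, kin, geom, resp, cfg)
                   for c in concs]
        curve = fit_calibration(concs, signals)
        organ = make_crosssection_phantom({"liver": 1e-7}, n_vessels=0,
                                          tissue_hb_total_m=3e-5,
                                          organ_hb_total_m=1e-4, seed=0)
        _, _, diff = _first_last_diff(organ, lib, sched, kin, geom, resp, cfg)
        est = estimate_concentration(
            float(diff[organ.masks["liver"]].mean()), curve)
        assert est == pytest.approx(1e-7, rel=0.15)


class TestLinearUnmix:
    def test_single_species_single_wavelength(self, lib):
        img = np.random.default_rng(0).uniform(0, 1, (16, 16))
        eps = lib.lookup("BphP1_Pfr", 750.0) * np.log(10.0) / 10.0
        out = linear_unmix({750.0: img}, lib, ["BphP1_Pfr"])
        np.testing.assert_allclose(out["BphP1_Pfr"], img / eps)

    def test_two_species_exact_recovery(self, lib):
        rng = np.random.default_rng(1)
        c_hb = rng.uniform(0, 1e-3, (16, 16))
        c_probe = rng.uniform(0, 1e-5, (16, 16))
        images = {}
        for wl in (680.0, 750.0):
            images[wl] = (np.log(10.0) / 10.0) * (
                lib.lookup("HbO2", wl) * c_hb
                + lib.lookup("BphP1_Pfr", wl) * c_probe)
        out = linear_unmix(images, lib, ["HbO2", "BphP1_Pfr"])
        np.testing.assert_allclose(out["HbO2"], c_hb, rtol=1e-8)
        np.testing.assert_allclose(out["BphP1_Pfr"], c_probe, rtol=1e-8)

    def test_underdetermined_system_raises(self, lib):
        with pytest.raises(UnmixingError):
            linear_unmix({750.0: np.ones((4, 4))}, lib,
                         ["HbO2", "BphP1_Pfr"])
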