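"""Forward model: initial pressure, ring projection, bandwidth, noise."""

import numpy as np
import pytest
from scipy.signal import hilbert

from rspat.acoustics import (AcousticsConfig, RingArrayGeometry, Sinogram,
                             TransducerResponse, add_noise, apply_transducer,
                             forward_project, initial_pressure,
                             simulate_acquisition)
from rspat.errors import ConfigError
from rspat.phantoms import make_tube_phantom
from rspat.spectra_kinetics import IlluminationSchedule, KineticsParams

from conftest import point_source


class TestInitialPressure:
    def test_zero_absorption_zero_pressure(self):
        cfg = AcousticsConfig()
        assert np.all(initial_pressure(np.zeros((8, 8)), cfg) == 0)

    def test_doubling_fluence_doubles_pressure(self):
        mu = np.random.default_rng(0).uniform(0, 1, (8, 8))
        p1 = initial_pressure(mu, AcousticsConfig(fluence_mj_cm2=5.0))
        p2 = initial_pressure(mu, AcousticsConfig(fluence_mj_cm2=10.0))
        assert np.allclose(p2, 2 * p1)

    def test_scalar_product_hand_check(self):
        """Gamma=0.2, F=5, mu_a=1/mm at one pixel -> p0 = 1.0 there."""
        mu = np.zeros((4, 4))
        mu[1, 2] = 1.0
        p0 = initial_pressure(mu, AcousticsConfig(gamma=0.2, fluence_mj_cm2=5.0))
        assert p0[1, 2] == pytest.approx(1.0)
        assert p0.sum() == pytest.approx(1.0)

    def test_attenuated_mode_needs_depth_map(self):
        cfg = AcousticsConfig(fluence_mode="attenuated")
        with pytest.raises(ConfigError):
            initial_pressure(np.ones((4, 4)), cfg)


class TestForwardProject:
    def test_zero_pressure_zero_sinogram(self, small_geom, small_grid):
        shape, px = small_grid
        sino = forward_project(np.zeros(shape), small_geom, px)
        assert np.all(sino.data == 0)

    def test_center_source_arrives_simultaneously(self, small_geom):
        shape, px = (129, 129), 0.2   # odd grid: a pixel sits at the center
        p0 = point_source(shape, 64, 64)
        sino = forward_project(p0, small_geom, px)
        env = np.abs(hilbert(sino.data, axis=1))
        arrivals = env.argmax(axis=1)
        assert np.ptp(arrivals) <= 1

    def test_arrival_times_equal_distance_over_c(self, small_geom, small_grid):
        """Per-element arrival equals the brute-force Euclidean travel time."""
        shape, px = small_grid
        iy, ix = 40, 70
        sino = forward_project(point_source(shape, iy, ix), small_geom, px)
        env = np.abs(hilbert(sino.data, axis=1))
        pos = small_geom.element_positions()
        y = (iy - (shape[0] - 1) / 2) * px
        x = (ix - (shape[1] - 1) / 2) * px
        expected = (np.hypot(pos[:, 0] - y, pos[:, 1] - x)
                    / small_geom.c_mm_per_us / small_geom.dt_us)
        assert np.abs(env.argmax(axis=1) - expected).max() <= 1.0

    def test_linearity(self, small_geom, small_grid):
        shape, px = small_grid
        rng = np.random.default_rng(1)
        a, b = rng.uniform(0, 1, shape), rng.uniform(0, 1, shape)
        s_ab = forward_project(2.0 * a + 0.5 * b, small_geom, px)
        s_a = forward_project(a, small_geom, px)
        s_b = forward_project(b, small_geom, px)
        assert np.allclose(s_ab.data, 2.0 * s_a.data + 0.5 * s_b.data,
                           atol=1e-12)

    def test_quarter_rotation_permutes_elements(self, small_geom, small_grid):
        """Rotating p0 by 90 deg rolls the sinogram rows by -N/4."""
        shape, px = small_grid
        p0 = point_source(shape, 40, 70)
        s1 = forward_project(p0, small_geom, px)
        s2 = forward_project(np.rot90(p0, 1), small_geom, px)
        n4 = small_geom.n_elements // 4
        assert np.allclose(np.roll(s1.data, -n4, axis=0), s2.data, atol=1e-12)

    def test_insufficient_samples_raise(self):
        geom = RingArrayGeometry(n_elements=16, n_samples=100)
        with pytest.raises(ConfigError):
            forward_project(np.zeros((128, 128)), geom, 0.2)


class TestTransducer:
    def test_zero_in_zero_out(self, small_geom, transducer):
        sino = Sinogram(np.zeros((64, 560)), small_geom)
        assert np.all(apply_transducer(sino, transducer).data == 0)

    def test_center_frequency_tone_preserved(self, small_geom, transducer):
        t = np.arange(560) / small_geom.sampling_mhz
        tone = np.sin(2 * np.pi * transducer.center_mhz * t)
        sino = Sinogram(np.tile(tone, (64, 1)), small_geom)
        out = apply_transducer(sino, transducer)
        mid = slice(100, 460)  # avoid filter edge transients
        assert out.data[0, mid].std() == pytest.approx(tone[mid].std(),
                                                       rel=0.01)

    def test_dc_offset_removed(self, small_geom, transducer):
        sino = Sinogram(np.ones((64, 560)), small_geom)
        out = apply_transducer(sino, transducer)
        assert np.abs(out.data[:, 100:460]).max() < 1e-6

    def test_nyquist_violation_raises(self, transducer):
        geom = RingArrayGeometry(n_elements=16, sampling_mhz=8.0,
                                 n_samples=560)
        sino = Sinogram(np.zeros((16, 560)), geom)
        with pytest.raises(ConfigError):
            apply_transducer(sino, transducer)


class TestNoise:
    def test_zero_std_is_identity(self, small_geom):
        sino = Sinogram(np.random.default_rng(0).normal(size=(64, 560)),
                        small_geom)
        out = add_noise(sino, 0.0, seed=1)
        np.testing.assert_array_equal(out.data, sino.data)

    def test_sample_std_matches_parameter(self, small_geom):
        """Empirical std of added noise within 2% over >= 1e5 samples."""
        sino = Sinogram(np.zeros((256, 560)), RingArrayGeometry())
        out = add_noise(sino, 0.37, seed=2)
        assert out.data.std() == pytest.approx(0.37, rel=0.02)

    def test_same_seed_reproduces(self, small_geom):
        sino = Sinogram(np.zeros((64, 560)), small_geom)
        a = add_noise(sino, 0.1, seed=3)
        b = add_noise(sino, 0.1, seed=3)
        np.testing.assert_array_equal(a.data, b.data)


@pytest.fixture(scope="module")
def tiny_setup():
    geom = RingArrayGeometry(n_elements=16, n_samples=420)
    phantom = make_tube_phantom([2e-6], tube_radius_mm=2.0,
                                shape=(64, 64), pixel_size_mm=0.2, seed=0)
    return geom, phantom


class TestSimulateAcquisition:
    def test_default_rate_gives_80_pulses_per_cycle(self, lib, tiny_setup):
        """10 Hz over the 8 s imaging phase records 80 pulses."""
        geom, phantom = tiny_setup
        sinos = simulate_acquisition(phantom, lib, IlluminationSchedule(),
                                     KineticsParams(), geom,
                                     cfg=AcousticsConfig(noise_std=0.0))
        assert len(sinos) == 80
        assert [s.pulse_index for s in sinos] == list(range(80))

    def test_probe_signal_decays_within_imaging_phase(self, lib, tiny_setup):
        geom, phantom = tiny_setup
        sinos = simulate_acquisition(phantom, lib, IlluminationSchedule(),
                                     KineticsParams(), geom,
                                     cfg=AcousticsConfig(noise_std=0.0),
                                     pulse_subset=[(0, 0), (0, 40), (0, 79)])
        energies = [float(np.sum(s.data ** 2)) for s in sinos]
        assert energies[0] > energies[1] > energies[2]

    def test_non_switching_phantom_gives_identical_pulses(self, lib):
        geom = RingArrayGeometry(n_elements=16, n_samples=420)
        phantom = make_tube_phantom([1e-6], tube_radius_mm=2.0, shape=(64, 64),
                                    pixel_size_mm=0.2, seed=0)
        phantom.maps["HbO2"] = phantom.maps["BphP1"] * 1e3
        phantom.maps["BphP1"] = np.zeros_like(phantom.maps["BphP1"])
        sinos = simulate_acquisition(phantom, lib, IlluminationSchedule(),
                                     KineticsParams(), geom,
                                     cfg=AcousticsConfig(noise_std=0.0),
                                     pulse_subset=[(0, 0), (0, 79)])
        np.testing.assert_allclose(sinos[0].data, sinos[1].data, atol=1e-15)

    def test_noise_substreams_reproduce_subsets(self, lib, tiny_setup):
        """A pulse subset matches the same pulses of a larger acquisition."""
        geom, phantom = tiny_setup
        kwargs = dict(resp=None, cfg=AcousticsConfig(noise_std=1e-3, seed=9))
        full = simulate_acquisition(phantom, lib, IlluminationSchedule(),
                                    KineticsParams(), geom,
                                    pulse_subset=[(0, 0), (0, 40), (0, 79)],
                                    **kwargs)
        part = simulate_acquisition(phantom, lib, IlluminationSchedule(),
                                    KineticsParams(), geom,
                                    pulse_subset=[(0, 40)], **kwargs)
        np.testing.assert_array_equal(full[1].data, part[0].data)
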