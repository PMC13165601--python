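"""Acoustic forward model: source, arrays, solver physics, noise."""

import numpy as np
import pytest

from quct.acoustics import (AcquisitionConfig, MeasurementTensor, SolverError,
                            acquire, add_awgn, build_sensor_array,
                            ricker_pulse, simulate_shot)
from quct.phantoms import SoSMap, quantize_sos

TINY_CFG = AcquisitionConfig(grid_extent=140, pml_px=20, n_steps=300)


def homogeneous_map(c=1500.0, size=64):
    sos = np.full((size, size), c, dtype=np.float32)
    return SoSMap(sos, quantize_sos(sos))


def heterogeneous_map(size=64):
    sos = np.full((size, size), 1500.0, dtype=np.float32)
    sos[20:40, 25:50] = 2025.0
    return SoSMap(sos, quantize_sos(sos))


@pytest.fixture(scope="module")
def tiny_array():
    return build_sensor_array("circle", 16, 24.0, TINY_CFG)


@pytest.fixture(scope="module")
def homogeneous_shot(tiny_array):
    return simulate_shot(homogeneous_map(), tiny_array, 0, TINY_CFG)


class TestRicker:
    def test_unit_peak_at_center(self):
        w = ricker_pulse(0.8, 0.01, 3.2)
        t = np.arange(len(w)) * 0.01
        assert w.max() == pytest.approx(1.0, abs=1e-6)
        assert t[np.argmax(w)] == pytest.approx(1.6, abs=0.01)

    def test_nearly_zero_mean(self):
        w = ricker_pulse(0.8, 0.01, 3.2)
        assert abs(w.sum() * 0.01) < 1e-3      # integral vs unit peak

    def test_spectral_peak_at_dominant_frequency(self):
        dt = 0.01
        w = ricker_pulse(0.8, dt, 3.2)
        n = 4096
        spec = np.abs(np.fft.rfft(w, n))
        freqs = np.fft.rfftfreq(n, dt)
        assert freqs[np.argmax(spec)] == pytest.approx(0.8, abs=freqs[1])

    def test_short_duration_warns(self):
        with pytest.warns(UserWarning):
            ricker_pulse(0.8, 0.01, 1.0)


class TestSensorArrays:
    def test_default_circle_radius_is_128_px(self):
        arr = build_sensor_array("circle", 32, 64.0, AcquisitionConfig())
        center = (AcquisitionConfig().grid_extent - 1) / 2
        radii = np.hypot(arr.positions[:, 0] - center,
                         arr.positions[:, 1] - center)
        assert np.allclose(radii, 128.0, atol=1.0)

    def test_angular_spacing_11_25_degrees(self):
        arr = build_sensor_array("circle", 32, 64.0, AcquisitionConfig())
        center = (AcquisitionConfig().grid_extent - 1) / 2
        ang = np.arctan2(arr.positions[:, 1] - center,
                         -(arr.positions[:, 0] - center))
        ang = np.unwrap(ang)
        spacing = np.degrees(np.diff(ang))
        assert np.allclose(spacing, 11.25, atol=0.7)

    def test_clockwise_from_topmost(self):
        arr = build_sensor_array("circle", 32, 64.0, AcquisitionConfig())
        center = (AcquisitionConfig().grid_extent - 1) / 2
        assert arr.positions[0, 0] == pytest.approx(center - 128, abs=1)
        assert arr.positions[1, 1] > arr.positions[0, 1]   # moves rightward

    def test_square_has_8_per_side(self):
        arr = build_sensor_array("square", 32, 64.0, AcquisitionConfig())
        rows, cols = arr.positions[:, 0], arr.positions[:, 1]
        lo_r, hi_r = rows.min(), rows.max()
        lo_c, hi_c = cols.min(), cols.max()
        on_top = np.sum(rows == lo_r)
        on_bot = np.sum(rows == hi_r)
        on_lef = np.sum(cols == lo_c)
        on_rig = np.sum(cols == hi_c)
        # corners belong to two sides; every side carries 8 positions
        assert on_top == on_bot == on_lef == on_rig
        assert len(np.unique(arr.positions, axis=0)) == 32

    def test_square_needs_multiple_of_four(self):
        with pytest.raises(ValueError):
            build_sensor_array("square", 30, 64.0, AcquisitionConfig())

    def test_array_must_fit_inside_absorbing_frame(self):
        with pytest.raises(ValueError):
            build_sensor_array("circle", 16, 80.0, TINY_CFG)


class TestMeasurementTensor:
    def test_default_shape_32_1001_32(self):
        cfg = AcquisitionConfig()
        arr = build_sensor_array("circle", 32, 64.0, cfg)
        data = np.zeros((32, cfg.n_steps + 1, 32), dtype=np.float32)
        t = MeasurementTensor(data, cfg, arr)
        assert t.data.shape == (32, 1001, 32)

    def test_wrong_shape_rejected(self):
        cfg = AcquisitionConfig()
        arr = build_sensor_array("circle", 32, 64.0, cfg)
        with pytest.raises(ValueError):
            MeasurementTensor(np.zeros((32, 1000, 32), np.float32), cfg, arr)


class TestSolverPhysics:
    def test_zero_amplitude_source_stays_quiescent(self, tiny_array):
        tr = simulate_shot(homogeneous_map(), tiny_array, 0, TINY_CFG,
                           source_amplitude=0.0)
        assert np.all(tr == 0)

    def test_first_arrival_matches_travel_time(self, homogeneous_shot):
        # opposite sensor is one diameter (24 mm) away: t = 24/1.5 = 16 us
        trace = np.abs(homogeneous_shot[:, 8])
        first = np.argmax(trace > 0.05 * trace.max()) * TINY_CFG.dt_out_us
        assert abs(first - 16.0) <= AcquisitionConfig().pulse_duration_us / 2

    def test_source_amplitude_linearity(self, tiny_array, homogeneous_shot):
        tr3 = simulate_shot(homogeneous_map(), tiny_array, 0, TINY_CFG,
                            source_amplitude=3.0)
        err = np.abs(tr3 - 3.0 * homogeneous_shot).max() / np.abs(tr3).max()
        assert err < 1e-6

    def test_reciprocity_in_heterogeneous_medium(self, tiny_array):
        m = heterogeneous_map()
        a = simulate_shot(m, tiny_array, 2, TINY_CFG)[:, 11]
        b = simulate_shot(m, tiny_array, 11, TINY_CFG)[:, 2]
        assert np.linalg.norm(a - b) / np.linalg.norm(a) < 1e-3

    def test_absorbing_layer_suppresses_coda(self, homogeneous_shot):
        trace = np.abs(homogeneous_shot[:, 8])
        peak = np.argmax(trace)
        coda = trace[peak + 60:].max()
        assert coda < 0.05 * trace.max()

    def test_energy_non_increasing_after_source_cutoff(self, tiny_array):
        _, energy = simulate_shot(heterogeneous_map(), tiny_array, 0, TINY_CFG,
                                  record_energy=True)
        cutoff = int(AcquisitionConfig().pulse_duration_us
                     / TINY_CFG.dt_out_us) + 5
        post = energy[cutoff:]
        growth = np.diff(post) / np.maximum(post[:-1], 1e-300)
        assert growth.max() < 0.01

    def test_internal_step_respects_cfl_bound(self):
        # replicate the solver's step choice at the worst-case medium speed
        cfg = AcquisitionConfig()
        c_max = 2250.0
        dx = cfg.dx_mm * 1e-3
        bound = cfg.cfl_safety * dx / (c_max * np.sqrt(2.0))
        dt_max = bound * (np.sqrt(3) / 2 if cfg.spatial_order == 4 else 1.0)
        substeps = int(np.ceil(cfg.dt_out_us * 1e-6 / dt_max))
        dt_int = cfg.dt_out_us * 1e-6 / substeps
        assert substeps > 1          # naive dt_out violates CFL; must sub-step
        assert dt_int <= bound

    def test_non_positive_sos_rejected(self, tiny_array):
        sos = np.full((64, 64), 1500.0, np.float32)
        m = SoSMap(sos, quantize_sos(sos))
        m.sos[0, 0] = -1.0           # bypass constructor validation
        with pytest.raises(ValueError):
            simulate_shot(m, tiny_array, 0, TINY_CFG)

    def test_bad_source_index_rejected(self, tiny_array):
        with pytest.raises(ValueError):
            simulate_shot(homogeneous_map(), tiny_array, 99, TINY_CFG)


class TestAcquire:
    def test_round_robin_shape_and_determinism(self):
        cfg = AcquisitionConfig(grid_extent=100, pml_px=12, n_steps=80)
        arr = build_sensor_array("circle", 8, 15.0, cfg)
        m = homogeneous_map(size=32)
        t1 = acquire(m, arr, cfg)
        t2 = acquire(m, arr, cfg)
        assert t1.data.shape == (8, 81, 8)
        np.testing.assert_array_equal(t1.data, t2.data)

    def test_rotation_symmetry_in_homogeneous_medium(self):
        cfg = AcquisitionConfig(grid_extent=100, pml_px=12, n_steps=150)
        arr = build_sensor_array("circle", 8, 15.0, cfg)
        t = acquire(homogeneous_map(size=32), arr, cfg).data
        rolled = np.roll(np.roll(t, 1, axis=0), 1, axis=2)
        err = np.linalg.norm(t - rolled) / np.linalg.norm(t)
        # discrete pixel rounding breaks the symmetry slightly
        assert err < 0.35


@pytest.fixture(scope="module")
def signal():
    cfg = AcquisitionConfig()
    arr = build_sensor_array("circle", 32, 64.0, cfg)
    rng = np.random.default_rng(0)
    data = rng.normal(size=(32, 1001, 32)).astype(np.float32)
    return MeasurementTensor(data, cfg, arr)


class TestNoise:
    @pytest.mark.parametrize("snr", [20.0, 30.0, 40.0])
    def test_snr_calibration_within_tenth_db(self, signal, snr):
        noisy = add_awgn(signal, snr, rng_seed=1)
        noise = noisy.data.astype(np.float64) - signal.data
        measured = 10 * np.log10(np.mean(signal.data.astype(np.float64) ** 2)
                                 / np.mean(noise ** 2))
        assert abs(measured - snr) <= 0.1

    def test_none_means_unchanged(self, signal):
        assert add_awgn(signal, None, 0) is signal

    def test_seeds_differ_but_signal_is_common(self, signal):
        a = add_awgn(signal, 20.0, 1)
        b = add_awgn(signal, 20.0, 2)
        assert not np.array_equal(a.data, b.data)
        # the underlying signal is identical: noise realizations average out
        na, nb = a.data - signal.data, b.data - signal.data
        assert abs(np.corrcoef(na.ravel(), nb.ravel())[0, 1]) < 0.01

    def test_all_zero_tensor_rejected(self):
        cfg = AcquisitionConfig()
        arr = build_sensor_array("circle", 32, 64.0, cfg)
        zero = MeasurementTensor(np.zeros((32, 1001, 32), np.float32), cfg, arr)
        with pytest.raises(ValueError):
            add_awgn(zero, 20.0, 0)
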