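"""Forward simulator: arrival geometry, linearity, seeding, speckle RF."""

import dataclasses
import warnings

import numpy as np
import pytest

from swetof import (
    AcquisitionConfig,
    AliasingWarning,
    ConfigurationError,
    PacketOverlapWarning,
    SimulationTruth,
    demodulate,
    simulate_longitudinal_series,
    simulate_rf_ensemble,
    simulate_velocity_field,
    estimate_sws,
)
from swetof.simulate import synthesize_frames
from swetof._signal import envelope


def _quiet_sim(geometry, acquisition, truth, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_velocity_field(geometry, acquisition, truth, **kw)


class TestArrivalGeometry:
    @pytest.mark.parametrize("sws", [0.6, 1.0, 1.5])
    def test_on_axis_peaks_at_two_way_time_of_flight(self, geometry, acquisition, sws):
        """Side-packet envelope peaks at the focus within one PRF sample of 2d/c."""
        truth = SimulationTruth(true_sws=sws, noise_sigma=0.0, top_bottom_amplitude=0.0)
        field = _quiet_sim(geometry, acquisition, truth)
        row = field.values[int(np.argmin(np.abs(field.depth_axis_mm - geometry.focal_length)))]
        env = envelope(row)
        t = field.time_axis_ms
        dt = acquisition.frame_interval_ms
        for d in geometry.one_way_distances:
            expected = 2.0 * d / sws
            sel = np.abs(t - expected) <= 1.0
            t_peak = t[sel][np.argmax(env[sel])]
            assert abs(t_peak - expected) <= dt + 1e-9

    def test_zero_reflection_coefficients_remove_side_packets(self, geometry, acquisition):
        truth = SimulationTruth(true_sws=1.0, noise_sigma=0.0, reflection_coefficients=(0, 0, 0, 0))
        field = _quiet_sim(geometry, acquisition, truth)
        row = field.values[int(np.argmin(np.abs(field.depth_axis_mm - geometry.focal_length)))]
        t = field.time_axis_ms
        # no energy left near the third/fourth side arrivals (18.4, 24 ms)
        assert np.max(np.abs(row[(t > 16) & (t < 26)])) < 1e-6

    def test_linearity_of_sources(self, geometry, acquisition):
        """Field of all sources = sum of single-source fields minus the
        double-counted common (direct + face) part."""
        kw = dict(true_sws=1.0, noise_sigma=0.0)
        f_all = _quiet_sim(geometry, acquisition, SimulationTruth(reflection_coefficients=(0.6, 0.6, 0.6, 0.6), **kw))
        f_first = _quiet_sim(geometry, acquisition, SimulationTruth(reflection_coefficients=(0.6, 0, 0, 0), **kw))
        f_rest = _quiet_sim(geometry, acquisition, SimulationTruth(reflection_coefficients=(0, 0.6, 0.6, 0.6), **kw))
        f_none = _quiet_sim(geometry, acquisition, SimulationTruth(reflection_coefficients=(0, 0, 0, 0), **kw))
        np.testing.assert_allclose(
            f_all.values, f_first.values + f_rest.values - f_none.values, atol=1e-12
        )

    def test_overlap_warning_when_packets_collide(self, geometry, acquisition):
        with pytest.warns(PacketOverlapWarning):
            simulate_velocity_field(
                geometry, acquisition, SimulationTruth(true_sws=5.0, noise_sigma=0.0)
            )


class TestSeeding:
    def test_same_seed_bit_identical(self, geometry, acquisition):
        truth = SimulationTruth(true_sws=1.0, noise_sigma=0.1, rng_seed=11)
        a = _quiet_sim(geometry, acquisition, truth)
        b = _quiet_sim(geometry, acquisition, truth)
        assert np.array_equal(a.values, b.values)

    def test_different_seeds_differ_only_in_noise(self, geometry, acquisition):
        mk = lambda s: SimulationTruth(true_sws=1.0, noise_sigma=0.1, rng_seed=s)
        clean = _quiet_sim(geometry, acquisition, dataclasses.replace(mk(0), noise_sigma=0.0))
        a = _quiet_sim(geometry, acquisition, mk(0))
        b = _quiet_sim(geometry, acquisition, mk(1))
        assert not np.array_equal(a.values, b.values)
        for noisy in (a, b):
            resid = noisy.values - clean.values
            assert np.std(resid) == pytest.approx(0.1, rel=0.05)
            assert np.mean(resid) == pytest.approx(0.0, abs=2e-3)


class TestLongitudinalSeries:
    def test_single_time_point(self, geometry, acquisition):
        out = simulate_longitudinal_series(
            geometry, acquisition, SimulationTruth(noise_sigma=0.0), [("0h", 1.0)]
        )
        assert len(out) == 1

    def test_empty_trajectory_rejected(self, geometry, acquisition):
        with pytest.raises(ConfigurationError):
            simulate_longitudinal_series(geometry, acquisition, SimulationTruth(), [])

    def test_constant_trajectory_estimates_agree(self, geometry, acquisition):
        fields = simulate_longitudinal_series(
            geometry, acquisition, SimulationTruth(noise_sigma=0.02),
            [("a", 1.47), ("b", 1.47), ("c", 1.47)],
        )
        est = [estimate_sws(f).mean_sws for f in fields]
        assert np.ptp(est) < 0.05 * 1.47

    def test_decreasing_trajectory_recovered_decreasing(self, geometry, acquisition):
        trajectory = [("0h", 1.47), ("24h", 1.25), ("48h", 1.05), ("72h", 0.85)]
        fields = simulate_longitudinal_series(
            geometry, acquisition, SimulationTruth(noise_sigma=0.0), trajectory
        )
        est = [estimate_sws(f).mean_sws for f in fields]
        assert all(b < a for a, b in zip(est, est[1:]))


@pytest.fixture(scope="module")
def small_acquisition():
    """Short ensemble to keep RF synthesis cheap in unit tests."""
    return AcquisitionConfig(n_frames=40)


class TestSpeckleRF:
    def test_static_scatterers_identical_frames(self, geometry, small_acquisition):
        truth = SimulationTruth(true_sws=1.0, noise_sigma=0.0, rng_seed=1)
        rf = simulate_rf_ensemble(
            geometry, small_acquisition, truth, n_scatterers=200,
            depth_window_mm=(13.0, 15.0), velocity_scale=0.0, electronic_noise=0.0,
        )
        assert np.array_equal(rf.values[:, 0], rf.values[:, -1])

    def test_same_seed_bit_identical(self, geometry, small_acquisition):
        truth = SimulationTruth(true_sws=1.0, rng_seed=5)
        kw = dict(n_scatterers=150, depth_window_mm=(13.0, 15.0))
        a = simulate_rf_ensemble(geometry, small_acquisition, truth, **kw)
        b = simulate_rf_ensemble(geometry, small_acquisition, truth, **kw)
        assert np.array_equal(a.values, b.values)

    def test_uniform_displacement_phase_identity(self, geometry, small_acquisition):
        """A uniform per-frame displacement delta gives demodulated lag-1
        phase 4*pi*delta/lambda (pulse-echo phase-shift identity)."""
        acq = small_acquisition
        lam_mm = acq.wavelength_mm
        delta_mm = 1.0e-3  # 1 um per frame, well under lambda/8
        rng = np.random.default_rng(3)
        z0 = rng.uniform(13.0, 15.0, 300)
        amp = rng.standard_normal(300)
        disp = np.tile(delta_mm * np.arange(acq.n_frames), (300, 1))
        c_mm_s = 1000.0 * acq.compressional_sound_speed
        t0, t1 = 2 * 12.8 / c_mm_s, 2 * 15.2 / c_mm_s
        fast = t0 + np.arange(int((t1 - t0) * acq.rf_sampling_rate)) / acq.rf_sampling_rate
        values = synthesize_frames(z0, disp, amp, acq, fast)
        from swetof import RFEnsemble

        rf = RFEnsemble(values, acq.rf_sampling_rate, fast[0], geometry, acq)
        iq = demodulate(rf).values
        r = np.conj(iq[:, :-1]) * iq[:, 1:]
        # weight by echo energy; edge samples carry no signal.  One speckle
        # realization carries a spectral-centroid offset of order bw/sqrt(TB)
        # relative to the carrier, so the phase matches to a few percent here
        # (the noise-free constructed-IQ case is exact; see motion tests).
        phase = np.angle(np.sum(r))
        assert phase == pytest.approx(4 * np.pi * delta_mm / lam_mm, rel=0.03)

    def test_excessive_displacement_warns(self, geometry, small_acquisition):
        truth = SimulationTruth(true_sws=1.0, noise_sigma=0.0, rng_seed=0)
        with pytest.warns(AliasingWarning):
            simulate_rf_ensemble(
                geometry, small_acquisition, truth, n_scatterers=100,
                depth_window_mm=(13.5, 14.5), velocity_scale=0.2,
            )
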