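"""Wavefront detection, two-stage assignment, and end-to-end SWS recovery."""

import itertools

import numpy as np
import pytest

from swetof import (
    AssignmentError,
    ConfigurationError,
    NoWavefrontError,
    SimulationTruth,
    Trace,
    WavefrontCandidate,
    WavefrontSet,
    compute_sws,
    crop_around_focus,
    detect_candidates,
    directional_filter,
    estimate_sws,
    focal_trace,
    predict_arrival_times,
    simulate_velocity_field,
    stage1_assign,
    stage2_refine,
    time_to_centroid,
)


def _make_candidate(centroid, peak=None, amplitude=1.0, halfwidth=1.0):
    peak = centroid if peak is None else peak
    return WavefrontCandidate(
        peak_time=peak,
        window=(peak - halfwidth, peak + halfwidth),
        centroid_time=centroid,
        peak_amplitude=amplitude,
        prominence=amplitude,
    )


def _packet_trace(centers, amps, n=400, dt=0.2, period=1.3, sigma=0.55):
    t = np.arange(n) * dt
    v = np.zeros(n)
    for c, a in zip(centers, amps):
        v += a * np.cos(2 * np.pi * (t - c) / period) * np.exp(-0.5 * ((t - c) / sigma) ** 2)
    return Trace(time_axis_ms=t, values=v)


class TestFocalTrace:
    def test_depth_constant_field_equals_any_row(self, clean_field_1p0, geometry):
        import dataclasses

        f = dataclasses.replace(
            clean_field_1p0, values=np.tile(clean_field_1p0.values[90], (clean_field_1p0.n_depth, 1))
        )
        tr = focal_trace(f, geometry, 0.5)
        np.testing.assert_allclose(tr.values, f.values[0])

    def test_simulated_field_contains_four_side_packets(self, clean_field_1p0, geometry):
        tr = focal_trace(clean_field_1p0, geometry, 0.5)
        cands = detect_candidates(tr, exclude_before_ms=3.0, min_relative_amplitude=0.0)
        found = [c.peak_time for c in cands]
        for expected in (6.0, 12.4, 18.4, 24.0):
            assert min(abs(f - expected) for f in found) <= 0.2

    def test_zero_halfwidth_returns_nearest_row(self, clean_field_1p0, geometry):
        tr = focal_trace(clean_field_1p0, geometry, 0.0)
        idx = int(np.argmin(np.abs(clean_field_1p0.depth_axis_mm - geometry.focal_length)))
        np.testing.assert_array_equal(tr.values, clean_field_1p0.values[idx])

    def test_focus_outside_field_rejected(self, clean_field_1p0):
        from swetof import FixtureGeometry

        far = FixtureGeometry(focal_length=40.0)
        with pytest.raises(ConfigurationError):
            focal_trace(clean_field_1p0, far, 0.5)


class TestTimeToCentroid:
    def test_symmetric_packet_centroid_at_center(self):
        tr = _packet_trace([12.4], [1.0])
        assert time_to_centroid(tr, (10.9, 13.9)) == pytest.approx(12.4, abs=0.2)

    def test_right_skewed_packet_matches_bruteforce_and_is_late(self):
        t = np.arange(400) * 0.2
        v = np.where(t >= 20.0, (t - 20.0) * np.exp(-(t - 20.0) / 2.0), 0.0)
        tr = Trace(time_axis_ms=t, values=v)
        window = (19.0, 35.0)
        got = time_to_centroid(tr, window)
        # brute-force discrete centroid with the same envelope definition
        from scipy.signal import hilbert

        env = np.abs(hilbert(v))
        m = (t >= window[0]) & (t <= window[1])
        oracle = np.sum(t[m] * env[m] ** 2) / np.sum(env[m] ** 2)
        assert got == pytest.approx(oracle, rel=1e-12)
        peak_time = t[m][np.argmax(env[m])]
        assert got > peak_time

    def test_single_nonzero_sample(self):
        t = np.arange(100) * 0.2
        v = np.zeros(100)
        v[50] = 3.0
        tr = Trace(time_axis_ms=t, values=v)
        assert time_to_centroid(tr, (t[50] - 0.1, t[50] + 0.1)) == pytest.approx(t[50])

    def test_all_zero_window_rejected(self):
        tr = _packet_trace([10.0], [1.0])
        with pytest.raises(NoWavefrontError):
            time_to_centroid(tr, (60.0, 70.0))

    def test_degenerate_window_rejected(self):
        tr = _packet_trace([10.0], [1.0])
        with pytest.raises(ConfigurationError):
            time_to_centroid(tr, (12.0, 11.0))


class TestDetectCandidates:
    def test_noise_free_trace_finds_four_boundaries(self, clean_field_1p0, geometry):
        comp = directional_filter(crop_around_focus(clean_field_1p0, 2.0, None), "down")
        tr = focal_trace(comp.field, geometry, 0.5)
        cands = detect_candidates(tr, exclude_before_ms=3.0)
        assert len(cands) >= 4
        for expected in (6.0, 12.4, 18.4, 24.0):
            assert min(abs(c.peak_time - expected) for c in cands) <= 0.2

    def test_injected_spurious_peak_adds_one_candidate(self):
        base = [10.0, 20.0, 30.0, 40.0]
        tr_clean = _packet_trace(base, [1.0, 0.8, 0.7, 0.6])
        tr_spur = _packet_trace(base + [25.0], [1.0, 0.8, 0.7, 0.6, 0.5])
        n_clean = len(detect_candidates(tr_clean, exclude_before_ms=5.0))
        n_spur = len(detect_candidates(tr_spur, exclude_before_ms=5.0))
        assert n_clean == 4
        assert n_spur == 5

    def test_flat_trace_rejected(self):
        tr = Trace(time_axis_ms=np.arange(100) * 0.2, values=np.zeros(100))
        with pytest.raises(NoWavefrontError):
            detect_candidates(tr)

    def test_short_trace_rejected(self):
        tr = Trace(time_axis_ms=np.arange(10) * 0.2, values=np.ones(10))
        with pytest.raises(ConfigurationError):
            detect_candidates(tr)


class TestStage1Assign:
    def test_nearest_in_order(self):
        cands = [_make_candidate(t) for t in (6.1, 12.3, 18.5, 23.9)]
        out = stage1_assign(cands, (6.0, 12.4, 18.4, 24.0))
        assert out.arrival_times == (6.1, 12.3, 18.5, 23.9)

    def test_spurious_candidate_left_unassigned(self):
        cands = [_make_candidate(t) for t in (6.1, 9.0, 12.3, 18.5, 23.9)]
        out = stage1_assign(cands, (6.0, 12.4, 18.4, 24.0))
        assert 9.0 not in out.arrival_times

    def test_too_few_candidates(self):
        cands = [_make_candidate(t) for t in (6.0, 12.0, 18.0)]
        with pytest.raises(AssignmentError):
            stage1_assign(cands, (6.0, 12.4, 18.4, 24.0))

    def test_unorderable_assignment_rejected(self):
        # both predictions nearest to the same cluster force a time inversion
        cands = [_make_candidate(t) for t in (6.0, 6.4, 30.0, 40.0)]
        with pytest.raises(AssignmentError):
            stage1_assign(cands, (6.3, 6.1, 30.0, 40.0))


def _bruteforce_stage2(candidates, stage1_set, geometry, k):
    """Independent exhaustive enumeration of the stage-2 search space."""
    pools = []
    for ref in stage1_set.candidates:
        ranked = sorted(candidates, key=lambda c: abs(c.centroid_time - ref.centroid_time))
        pools.append(ranked[:k])
    best = None
    for combo in itertools.product(*pools):
        if len({id(c) for c in combo}) != 4:
            continue
        times = [c.centroid_time for c in combo]
        if any(b <= a for a, b in zip(times, times[1:])):
            continue
        speeds = [2.0 * d / t for d, t in zip(geometry.one_way_distances, times)]
        var = float(np.var(speeds))
        if best is None or var < best:
            best = var
    return best


class TestStage2Refine:
    def test_clean_trace_is_fixed_point(self, clean_field_1p0, geometry):
        comp = directional_filter(crop_around_focus(clean_field_1p0, 2.0, None), "down")
        tr = focal_trace(comp.field, geometry, 0.5)
        cands = detect_candidates(tr, exclude_before_ms=3.0)
        s1 = stage1_assign(cands, predict_arrival_times(geometry, 1.0))
        s2, est = stage2_refine(cands, s1, geometry)
        assert s2.arrival_times == s1.arrival_times
        assert est.speed_variance <= compute_sws(geometry, s1.arrival_times).speed_variance

    def test_swaps_out_spurious_pick_and_reduces_variance(self, geometry):
        cands = [_make_candidate(t) for t in (6.0, 9.0, 12.4, 18.4, 24.0)]
        # predictions biased so stage 1 grabs the spurious 9.0 ms peak
        s1 = stage1_assign(cands, (6.0, 9.6, 18.4, 24.0))
        assert 9.0 in s1.arrival_times
        s2, est = stage2_refine(cands, s1, geometry)
        assert s2.arrival_times == (6.0, 12.4, 18.4, 24.0)
        assert est.speed_variance < compute_sws(geometry, s1.arrival_times).speed_variance

    def test_k1_returns_stage1_unchanged(self, geometry):
        cands = [_make_candidate(t) for t in (6.1, 12.3, 18.5, 23.9)]
        s1 = stage1_assign(cands, predict_arrival_times(geometry, 1.0))
        s2, _ = stage2_refine(cands, s1, geometry, k_alternatives=1)
        assert s2.arrival_times == s1.arrival_times

    def test_matches_independent_bruteforce_on_random_sets(self, geometry):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(5, 10)
            times = np.sort(rng.uniform(4.0, 30.0, n))
            times = times[np.concatenate(([True], np.diff(times) > 0.3))]
            if times.size < 4:
                continue
            cands = [_make_candidate(float(t)) for t in times]
            pred = predict_arrival_times(geometry, float(rng.uniform(0.7, 1.5)))
            try:
                s1 = stage1_assign(cands, pred)
            except AssignmentError:
                continue
            _, est = stage2_refine(cands, s1, geometry, k_alternatives=3)
            oracle = _bruteforce_stage2(cands, s1, geometry, 3)
            assert est.speed_variance == pytest.approx(oracle, rel=1e-12)


class TestEstimateSws:
    def test_recovers_unit_speed(self, grid_estimates):
        assert grid_estimates[1.0].mean_sws == pytest.approx(1.0, rel=0.02)

    @pytest.mark.parametrize("sws", [0.47, 1.47])
    def test_recovers_cell_gel_range(self, geometry, acquisition, sws):
        """The soft cell-laden gel range (collagen 1-3 mg/ml) recovers within 3 %."""
        field = simulate_velocity_field(
            geometry, acquisition, SimulationTruth(true_sws=sws, noise_sigma=0.0)
        )
        est = estimate_sws(field)
        assert est.mean_sws == pytest.approx(sws, rel=0.03)

    def test_pure_noise_fails_loudly(self, noise_field):
        with pytest.raises(NoWavefrontError):
            estimate_sws(noise_field)

    def test_monotone_in_true_speed(self, grid_estimates):
        speeds = [grid_estimates[c].mean_sws for c in sorted(grid_estimates)]
        assert all(b > a for a, b in zip(speeds, speeds[1:]))

    def test_mean_equals_formula_applied_to_arrivals(self, grid_estimates, geometry):
        est = grid_estimates[1.2]
        direct = compute_sws(geometry, est.arrival_times)
        assert est.mean_sws == direct.mean_sws
        assert est.per_path_speeds == direct.per_path_speeds

    def test_noisy_replicates_within_5pct(self, geometry, acquisition):
        """noise_sigma = 0.1: at least 95 % of 50 seeded replicates within 5 %."""
        ok = 0
        n = 50
        for i in range(n):
            c = [0.6, 1.0, 1.4][i % 3]
            field = simulate_velocity_field(
                geometry, acquisition, SimulationTruth(true_sws=c, noise_sigma=0.1, rng_seed=i)
            )
            try:
                est = estimate_sws(field)
            except Exception:
                continue
            if abs(est.mean_sws - c) / c <= 0.05:
                ok += 1
        assert ok >= 0.95 * n

    def test_diagnostics_populated(self, grid_estimates):
        est = grid_estimates[1.0]
        assert est.initial_estimate is not None
        assert est.n_candidates_considered >= 4
        assert est.speed_variance >= 0
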