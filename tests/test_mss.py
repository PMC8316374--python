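"""Moment-scaling-spectrum closed forms, calibration and classification."""

from __future__ import annotations

import numpy as np
import pytest

from eltether.mss import (
    MSSThresholds,
    calibrate_thresholds,
    classify_motion,
    compute_mss,
    partition_tracks_by_marker,
    summarize_motion,
)
from eltether.synthetic import MotionSpec, simulate_trajectory
from eltether.tracking import Trajectory

THRESHOLDS = MSSThresholds(S_low=0.35, S_high=0.62)


def _ballistic(v=1.0, n=100, dt=0.1):
    t = np.arange(n)[:, None] * dt
    return np.hstack([v * t, 0.5 * v * t])


class TestComputeMss:
    def test_stationary_track_degenerate_slope_zero(self):
        xy = np.zeros((100, 2))
        r = compute_mss(xy, 0.1)
        assert r.degenerate
        assert r.slope == 0.0
        assert np.all(r.moments[1:] == 0)

    def test_ballistic_gammas_equal_order_slope_one(self):
        r = compute_mss(_ballistic(), 0.1)
        assert r.gamma[1:] == pytest.approx(np.arange(1, 7), abs=1e-9)
        assert r.slope == pytest.approx(1.0, abs=1e-9)

    def test_moment_zero_is_identity(self):
        r = compute_mss(_ballistic(), 0.1)
        assert np.all(r.moments[0] == 1.0)
        assert r.gamma[0] == 0.0

    def test_brownian_mean_slope_near_half(self):
        spec = MotionSpec("free", D=0.05, dt=0.1, n_frames=600, loc_noise_sigma=0.0)
        rng = np.random.default_rng(12)
        slopes = [
            compute_mss(simulate_trajectory(spec, rng).true_um, 0.1).slope
            for _ in range(150)
        ]
        assert np.mean(slopes) == pytest.approx(0.5, abs=0.05)

    def test_brownian_diffusion_coefficient_recovered(self):
        spec = MotionSpec("free", D=0.05, dt=0.1, n_frames=5000, loc_noise_sigma=0.0)
        rng = np.random.default_rng(13)
        d_est = np.mean(
            [compute_mss(simulate_trajectory(spec, rng).true_um, 0.1).D_est_um2_s
             for _ in range(20)]
        )
        assert d_est == pytest.approx(0.05, rel=0.15)

    def test_scale_invariance_of_slope(self):
        spec = MotionSpec("free", D=0.05, dt=0.1, n_frames=300)
        tr = simulate_trajectory(spec, 5)
        a = compute_mss(tr.observed_um, 0.1)
        b = compute_mss(tr.observed_um * 10.0, 0.1)
        assert b.slope == pytest.approx(a.slope, abs=1e-12)
        assert classify_motion(a, THRESHOLDS).label == classify_motion(b, THRESHOLDS).label


class TestCalibrateThresholds:
    def test_long_tracks_bracket_half(self):
        thr = calibrate_thresholds(5000, 0.1, n_sim=150, seed=3)
        assert thr.S_low < 0.5 < thr.S_high
        # with lags up to a quarter of the track, long-lag moment variance
        # keeps the null band at finite width even for long tracks
        assert thr.S_high - thr.S_low < 0.25

    def test_deterministic_under_seed(self):
        a = calibrate_thresholds(300, 0.1, n_sim=100, seed=4)
        b = calibrate_thresholds(300, 0.1, n_sim=100, seed=4)
        assert (a.S_low, a.S_high) == (b.S_low, b.S_high)

    def test_shorter_tracks_give_wider_band(self):
        short = calibrate_thresholds(100, 0.1, n_sim=200, seed=5)
        long = calibrate_thresholds(1000, 0.1, n_sim=200, seed=5)
        assert short.S_high - short.S_low > long.S_high - long.S_low


class TestClassifyMotion:
    def test_stationary_is_confined(self):
        r = compute_mss(np.zeros((100, 2)), 0.1)
        assert classify_motion(r, THRESHOLDS).label == "confined"

    def test_ballistic_is_directed(self):
        r = compute_mss(_ballistic(), 0.1)
        assert classify_motion(r, THRESHOLDS).label == "directed"

    def test_short_track_unclassified(self):
        r = compute_mss(_ballistic(n=10), 0.1)
        assert classify_motion(r, THRESHOLDS).label == "unclassified"

    def test_per_class_accuracy_with_calibrated_thresholds(self):
        dt, nf = 0.1, 300
        thr = calibrate_thresholds(nf, dt, loc_noise_um=0.02, n_sim=200, seed=7)
        rng = np.random.default_rng(11)
        specs = {
            "confined": MotionSpec("confined", D=0.05, dt=dt, n_frames=nf, R_c=0.25),
            "free": MotionSpec("free", D=0.05, dt=dt, n_frames=nf),
            "directed": MotionSpec("directed", D=0.05, dt=dt, n_frames=nf, v=1.0),
        }
        for label, spec in specs.items():
            hits = sum(
                classify_motion(
                    compute_mss(simulate_trajectory(spec, rng).observed_um, dt), thr
                ).label
                == label
                for _ in range(60)
            )
            assert hits / 60 >= 0.9, label


class TestSummarizeMotion:
    def test_proportions_and_ratio_arithmetic(self):
        from dataclasses import replace

        base = compute_mss(_ballistic(), 0.1)
        results = []
        for label, n in (("confined", 3), ("free", 1), ("directed", 1)):
            results.extend(replace(base, label=label) for _ in range(n))
        s = summarize_motion(results)["all"]
        assert s.free_plus_directed == pytest.approx(0.4)
        assert s.motile_to_confined_ratio == pytest.approx(2 / 3)
        assert sum(s.proportions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_all_confined_ratio_zero(self):
        r = classify_motion(compute_mss(np.zeros((50, 2)), 0.1), THRESHOLDS)
        s = summarize_motion([r, r])["all"]
        assert s.free_plus_directed == 0.0
        assert s.motile_to_confined_ratio == 0.0

    def test_no_confined_ratio_flagged_undefined(self):
        r = classify_motion(compute_mss(_ballistic(), 0.1), THRESHOLDS)
        assert summarize_motion([r])["all"].motile_to_confined_ratio is None

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_motion([])


class TestPartitionByMarker:
    def _track(self, x, y, n=10):
        return Trajectory(0, np.arange(n), np.full(n, x), np.full(n, y))

    def test_always_inside_is_plus_never_is_minus(self):
        masks = np.zeros((10, 32, 32), dtype=bool)
        masks[:, 10:15, 10:15] = True
        inside = self._track(12.0, 12.0)
        outside = self._track(25.0, 25.0)
        part = partition_tracks_by_marker([inside, outside], masks)
        assert part["plus"] == [inside]
        assert part["minus"] == [outside]

    def test_overlap_fraction_cutoff(self):
        masks = np.zeros((10, 32, 32), dtype=bool)
        masks[:6, 10:15, 10:15] = True  # inside 6 of 10 frames
        tr = self._track(12.0, 12.0)
        assert partition_tracks_by_marker([tr], masks, 0.5)["plus"] == [tr]
        assert partition_tracks_by_marker([tr], masks, 0.7)["minus"] == [tr]

    def test_frame_mismatch_raises(self):
        masks = np.zeros((5, 32, 32), dtype=bool)
        with pytest.raises(ValueError, match="frame"):
            partition_tracks_by_marker([self._track(3.0, 3.0, n=10)], masks)
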