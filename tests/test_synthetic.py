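"""Generator-level guarantees: calibration, bounds, determinism, ground truth."""

from __future__ import annotations

import math

import numpy as np
import pytest
from shapely.geometry import Point

from eltether.shells import peripheral_fraction
from eltether.synthetic import (
    MotionSpec,
    SceneSpec,
    circle_line_contact_percent,
    make_dispersal_scene,
    make_em_scene,
    make_pla_scene,
    render_movie,
    simulate_trajectory,
)


class TestSimulateTrajectory:
    def test_zero_diffusion_zero_noise_is_static(self):
        spec = MotionSpec("free", D=0.0, dt=0.1, n_frames=50, loc_noise_sigma=0.0)
        tr = simulate_trajectory(spec, 1)
        assert np.all(tr.true_um == tr.true_um[0])
        assert np.all(tr.observed_um == tr.true_um)

    def test_brownian_step_variance_calibrated(self):
        spec = MotionSpec("free", D=0.05, dt=0.1, n_frames=10_001, loc_noise_sigma=0.0)
        tr = simulate_trajectory(spec, 2)
        msq = np.mean(np.diff(tr.true_um, axis=0) ** 2)
        assert msq == pytest.approx(2 * 0.05 * 0.1, rel=0.05)

    def test_confined_positions_never_exceed_radius(self):
        spec = MotionSpec(
            "confined", D=0.1, dt=0.1, n_frames=5000, R_c=0.25, loc_noise_sigma=0.0
        )
        tr = simulate_trajectory(spec, 3)
        assert np.linalg.norm(tr.true_um, axis=1).max() <= 0.25 + 1e-12

    def test_confined_noise_tail_documented(self):
        spec = MotionSpec(
            "confined", D=0.1, dt=0.1, n_frames=2000, R_c=0.25, loc_noise_sigma=0.02
        )
        tr = simulate_trajectory(spec, 3)
        # noisy positions may exceed R_c, but only by a localization-noise tail
        assert np.linalg.norm(tr.observed_um, axis=1).max() <= 0.25 + 6 * 0.02

    def test_directed_shows_linear_drift(self):
        spec = MotionSpec("directed", D=0.0, dt=0.1, n_frames=100, v=1.0, loc_noise_sigma=0.0)
        tr = simulate_trajectory(spec, 4)
        dist = np.linalg.norm(tr.true_um[-1])
        assert dist == pytest.approx(1.0 * 0.1 * 99, rel=1e-9)

    def test_seeded_determinism(self):
        spec = MotionSpec("confined", D=0.05, dt=0.1, n_frames=100, R_c=0.3)
        a = simulate_trajectory(spec, 9)
        b = simulate_trajectory(spec, 9)
        assert np.array_equal(a.observed_um, b.observed_um)

    @pytest.mark.parametrize(
        ("kwargs", "field"),
        [
            (dict(model="free", D=-1.0, dt=0.1, n_frames=10), "D"),
            (dict(model="free", D=0.1, dt=0.0, n_frames=10), "dt"),
            (dict(model="free", D=0.1, dt=0.1, n_frames=1), "n_frames"),
            (dict(model="confined", D=0.1, dt=0.1, n_frames=10), "R_c"),
            (dict(model="directed", D=0.1, dt=0.1, n_frames=10), "v"),
            (dict(model="hovering", D=0.1, dt=0.1, n_frames=10), "model"),
        ],
    )
    def test_invalid_spec_names_offending_field(self, kwargs, field):
        with pytest.raises(ValueError, match=field):
            MotionSpec(**kwargs)


class TestRenderMovie:
    def test_empty_scene_is_pure_background(self):
        scene = SceneSpec(shape_px=(32, 32), poisson_noise=False, background=50.0)
        stack, truth = render_movie(scene)
        assert np.all(stack.data == 50.0)
        assert truth.positions_um.shape[0] == 0

    def test_static_particle_argmax_at_true_pixel(self):
        spec = MotionSpec("free", D=0.0, dt=0.1, n_frames=5, loc_noise_sigma=0.0)
        scene = SceneSpec(
            shape_px=(40, 40),
            motions=[spec],
            start_positions_um=np.array([[2.03, 1.27]]),
            poisson_noise=False,
        )
        stack, truth = render_movie(scene)
        for t in range(stack.n_frames):
            iy, ix = np.unravel_index(np.argmax(stack.data[t, 0]), (40, 40))
            assert (ix, iy) == (round(2.03 / 0.1), round(1.27 / 0.1))

    def test_render_deterministic_under_seed(self):
        def build():
            m = [MotionSpec("free", D=0.02, dt=0.1, n_frames=10)]
            return SceneSpec(shape_px=(48, 48), motions=m, rng_seed=7, er_network_amplitude=30.0)

        s1, t1 = render_movie(build())
        s2, t2 = render_movie(build())
        assert np.array_equal(s1.data, s2.data)
        assert np.array_equal(t1.positions_um, t2.positions_um)

    def test_particle_leaving_frame_is_named(self):
        spec = MotionSpec("directed", D=0.0, dt=0.1, n_frames=50, v=2.0, loc_noise_sigma=0.0)
        scene = SceneSpec(
            shape_px=(32, 32),
            motions=[spec],
            start_positions_um=np.array([[1.6, 1.6]]),
        )
        with pytest.raises(ValueError, match="particle 0"):
            render_movie(scene)

    def test_contact_plan_requires_second_channel(self):
        from eltether.synthetic import ContactDwell

        m = [MotionSpec("free", D=0.01, dt=0.1, n_frames=10)]
        with pytest.raises(ValueError, match="second"):
            SceneSpec(shape_px=(32, 32), motions=m, contact_plan=[ContactDwell(0, 0.0, 0.5)])


class TestDispersalScene:
    outline = Point(12.0, 12.0).buffer(10.0, quad_segs=64)

    @pytest.mark.parametrize("target", [0.0, 1.0])
    def test_extreme_targets_exact(self, target):
        _, _, true_frac, _, _ = make_dispersal_scene(self.outline, target, 100, seed=1)
        assert true_frac == target

    def test_recount_of_placements_matches_recorded_fraction(self):
        img, mask, true_frac, shells, pts = make_dispersal_scene(
            self.outline, 0.5, 200, seed=3
        )
        labels = shells.labels[
            np.round(pts[:, 1]).astype(int), np.round(pts[:, 0]).astype(int)
        ]
        assert np.all(labels > 0)
        recount = np.mean(labels >= 3)
        assert recount == true_frac

    def test_measured_fraction_tracks_truth(self):
        img, mask, true_frac, shells, _ = make_dispersal_scene(self.outline, 0.3, 200, seed=5)
        res = peripheral_fraction(img, shells, background_threshold=1.0)
        assert res.fraction == pytest.approx(true_frac, abs=0.02)

    def test_too_small_outline_raises(self):
        tiny = Point(4.0, 4.0).buffer(3.0, quad_segs=32)
        with pytest.raises(ValueError, match="inner shells"):
            make_dispersal_scene(tiny, 0.5, 10, seed=1)


class TestEMScene:
    def test_no_er_percent_zero(self):
        contours, analytic = make_em_scene([((0.0, 0.0), 250.0)], [])
        assert analytic == [0.0]
        assert len(contours.el) == 1 and len(contours.er) == 0

    def test_tangent_line_closed_form(self):
        expected = 100 * math.acos((250 - 30) / 250) / math.pi
        assert circle_line_contact_percent(250, 250, 30) == pytest.approx(expected)

    def test_closed_form_matches_dense_sampling_oracle(self):
        # brute-force oracle: >= 1e5 boundary points vs the analytic arc
        R, cutoff = 250.0, 30.0
        theta = np.linspace(0, 2 * math.pi, 200_000, endpoint=False)
        for d in (0.0, 100.0, 250.0, 270.0, 300.0):
            dist = np.abs(d - R * np.cos(theta))
            oracle = 100.0 * np.mean(dist <= cutoff)
            assert circle_line_contact_percent(R, d, cutoff) == pytest.approx(oracle, abs=0.01)

    def test_degenerate_er_segment_rejected(self):
        bad = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="zero-length"):
            make_em_scene([((0.0, 0.0), 100.0)], [bad])


class TestPLAScene:
    def test_empty_spec_blank_image(self):
        img, truth = make_pla_scene([], seed=1, background=0.0)
        assert truth.pla_count == 0
        assert np.all(img == 0)

    def test_three_isolated_dots(self):
        img, truth = make_pla_scene(
            [((20, 20), 8), ((60, 60), 8), ((100, 40), 8)], seed=1
        )
        assert truth.pla_count == 3
        assert truth.pla_touching == [False, False, False]

    def test_size_filter_in_ground_truth(self):
        # two 8-px dots sharing an edge plus one 4-px dot: the small dot is
        # excluded by the >= 5 px rule, touching dots still count separately
        img, truth = make_pla_scene(
            [((20, 20), 8), ((20, 23), 8), ((80, 80), 4)], seed=1
        )
        assert truth.pla_count == 2
        assert truth.pla_touching[:2] == [True, True]
        assert truth.pla_areas_px == [8, 8, 4]

    def test_exact_planted_areas(self):
        img, truth = make_pla_scene([((30, 30), 13), ((70, 70), 5)], seed=2, background=0.0)
        assert int((img > 0).sum()) == 18

    def test_subpixel_area_error(self):
        with pytest.raises(ValueError, match=">= 1"):
            make_pla_scene([((10, 10), 0)], seed=1)
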