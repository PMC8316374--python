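"""Contact persistence, z-stack counting, ER association, marker subsets."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eltether.contacts import (
    classify_marker_overlap,
    detect_contacts,
    detect_contacts_zstack,
    events_from_cooccurrence,
    score_er_association,
)
from eltether.stack import ImageStack


class TestPersistenceSemantics:
    def test_ten_second_rule_at_2p4s_frames(self):
        # 4 frames = 9.6 s -> rejected; 5 frames = 12.0 s -> accepted
        four = np.array([True] * 4 + [False] * 6)
        five = np.array([True] * 5 + [False] * 5)
        _, acc4 = events_from_cooccurrence(four, 2.4, 10.0)
        _, acc5 = events_from_cooccurrence(five, 2.4, 10.0)
        assert (acc4, acc5) == (0, 1)

    def test_no_cooccurrence_no_events(self):
        events, acc = events_from_cooccurrence(np.zeros(20, bool), 2.4, 10.0)
        assert events == [] and acc == 0

    def test_warning_when_threshold_exceeds_recording(self):
        with pytest.warns(UserWarning, match="recording length"):
            events_from_cooccurrence(np.ones(3, bool), 1.0, 10.0)

    @pytest.mark.filterwarnings("ignore:min_duration_s exceeds")
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        plan=st.lists(st.booleans(), min_size=1, max_size=60),
        min_frames=st.integers(1, 10),
    )
    def test_accepted_events_never_shorter_than_threshold(self, plan, min_frames):
        dt = 2.4
        min_s = min_frames * dt
        present = np.array(plan)
        events, accepted = events_from_cooccurrence(present, dt, min_s)
        assert all(e.duration_s >= min_s for e in events if e.accepted(min_s))
        # accepted count equals the number of True-runs of >= min_frames
        runs, n = [], 0
        for v in list(present) + [False]:
            n = n + 1 if v else (runs.append(n) or 0) if n else 0
        assert accepted == sum(1 for r in runs if r >= min_frames)
        # total frames covered by events equals total True frames
        assert sum(e.end_frame - e.start_frame + 1 for e in events) == present.sum()

    @pytest.mark.filterwarnings("ignore:min_duration_s exceeds")
    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(plan=st.lists(st.booleans(), min_size=1, max_size=60))
    def test_accepted_count_monotone_in_threshold(self, plan):
        present = np.array(plan)
        counts = [
            events_from_cooccurrence(present, 2.4, thr)[1]
            for thr in (2.4, 7.2, 12.0, 24.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestDetectContacts:
    def test_dwell_plan_recovered_from_rendered_movie(self, contact_scene):
        scene, stack, truth = contact_scene
        events, accepted = detect_contacts(stack, "SNX19", "EL", min_duration_s=10.0)
        dt = scene.frame_interval_s
        planted_long = sum(
            1
            for d in truth.contact_intervals
            if (round(d.end_s / dt) - round(d.start_s / dt) + 1) * dt >= 10.0
        )
        assert accepted == planted_long == 6
        # no accepted event maps to a planted dwell shorter than 10 s
        for e in events:
            if e.accepted(10.0):
                hit = [
                    d
                    for d in truth.contact_intervals
                    if d.start_s <= (e.start_frame + 0.5) * dt <= d.end_s + dt
                ]
                assert hit and max(x.duration_s for x in hit) + dt >= 10.0

    def test_accepted_monotone_in_min_duration(self, contact_scene):
        _, stack, _ = contact_scene
        counts = [
            detect_contacts(stack, "SNX19", "EL", min_duration_s=thr)[1]
            for thr in (5.0, 10.0, 20.0, 40.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_blank_snx_channel_no_events(self):
        rng = np.random.default_rng(0)
        data = rng.poisson(100.0, size=(8, 2, 64, 64)).astype(float)
        stack = ImageStack(data, 0.1, 2.4, ("EL", "SNX19"))
        events, accepted = detect_contacts(
            stack, "SNX19", "EL", snx_threshold=("absolute", 1e6)
        )
        assert events == [] and accepted == 0


def _zstack(contact_slices_per_pair, n_z=6, shape=(64, 64)):
    """Build a two-channel z-stack with disc pairs overlapping in given slices."""
    data = np.zeros((n_z, 2, *shape))
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    for i, slices in enumerate(contact_slices_per_pair):
        cy, cx = 10 + 11 * (i % 5), 10 + 11 * (i // 5)
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= 9
        for z in range(n_z):
            data[z, 0][disc] = 200.0  # EL present in every slice
            if z in slices:
                data[z, 1][disc] = 200.0  # tether signal only in contact slices
    return ImageStack(data, 0.1, 0.0 if n_z == 1 else 1.0, ("EL", "SNX19"))


class TestZStackContacts:
    kwargs = dict(snx_threshold=("absolute", 100.0), el_threshold=("absolute", 100.0))

    def test_single_slice_overlap_not_counted(self):
        stack = _zstack([{2}])
        _, count = detect_contacts_zstack(stack, "SNX19", "EL", **self.kwargs)
        assert count == 0

    def test_two_consecutive_slices_counted_once(self):
        stack = _zstack([{2, 3}])
        _, count = detect_contacts_zstack(stack, "SNX19", "EL", **self.kwargs)
        assert count == 1

    def test_five_planted_contacts_counted(self):
        stack = _zstack([{0, 1}, {2, 3}, {3, 4}, {1, 2, 3}, {4, 5}, {2}, {5}])
        _, count = detect_contacts_zstack(stack, "SNX19", "EL", **self.kwargs)
        assert count == 5

    def test_single_slice_stack_rejected(self):
        stack = _zstack([set()], n_z=1)
        with pytest.raises(ValueError, match="detect_contacts"):
            detect_contacts_zstack(stack, "SNX19", "EL", **self.kwargs)


class TestERAssociation:
    def _masks_and_er(self, k):
        masks = np.zeros((10, 32, 32), dtype=bool)
        masks[:, 10:14, 10:14] = True
        er = np.zeros((10, 32, 32))
        er[:k, 12, 12] = 50.0  # ER visible inside the mask in k frames
        return masks, er

    @pytest.mark.parametrize("k", [0, 3, 8, 10])
    def test_percent_is_ten_times_k(self, k):
        masks, er = self._masks_and_er(k)
        score = score_er_association(masks, er, er_threshold=10.0)
        assert score.percent == 10.0 * k

    def test_intensity_rescaling_above_threshold_invariant(self):
        masks, er = self._masks_and_er(7)
        a = score_er_association(masks, er, er_threshold=10.0)
        b = score_er_association(masks, er * 40.0, er_threshold=10.0)
        assert a.percent == b.percent

    def test_frame_count_mismatch_raises(self):
        masks, er = self._masks_and_er(5)
        with pytest.raises(ValueError, match="10"):
            score_er_association(masks[:7], er[:7], er_threshold=10.0)


class TestMarkerOverlap:
    def _masks(self):
        shape = (64, 64)
        m = {}
        for name, sl in (
            ("LAMP1", np.s_[10:30, 10:30]),
            ("RAB5A", np.s_[20:40, 20:40]),
            ("Dextran", np.s_[25:35, 25:35]),
        ):
            mask = np.zeros(shape, dtype=bool)
            mask[sl] = True
            m[name] = mask
        return m

    def test_subset_labels(self):
        masks = self._masks()
        pts = np.array([[27.0, 27.0], [12.0, 12.0], [50.0, 50.0], [22.0, 38.0]])
        table = classify_marker_overlap(pts, masks)
        assert table.subset_counts[frozenset({"LAMP1", "RAB5A", "Dextran"})] == 1
        assert table.subset_counts[frozenset({"LAMP1"})] == 1
        assert table.subset_counts[frozenset()] == 1
        assert table.subset_counts[frozenset({"RAB5A"})] == 1

    def test_percentages_sum_to_hundred(self, rng):
        masks = self._masks()
        pts = rng.uniform(0, 63, size=(40, 2))
        table = classify_marker_overlap(pts, masks)
        assert sum(table.percentages.values()) == pytest.approx(100.0)
        assert table.total == 40

    def test_planted_composition_recovered(self):
        masks = self._masks()
        pts = np.array([[27.0, 27.0]] * 5 + [[12.0, 12.0]] * 3)
        table = classify_marker_overlap(pts, masks)
        assert table.subset_counts[frozenset({"LAMP1", "RAB5A", "Dextran"})] == 5
        assert table.subset_counts[frozenset({"LAMP1"})] == 3
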