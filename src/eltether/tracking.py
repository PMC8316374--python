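"""Linking per-frame detections into trajectories.

Frame-to-frame correspondence is solved globally per frame pair by Hungarian
assignment on squared displacement, with a hard gate at ``max_disp_px``.
Tracks whose particle briefly disappears can be closed over gaps of up to
``max_gap_frames`` missing frames; tracks shorter than ``min_track_len``
detections are discarded.  Assignment ties are broken by detection order, so
linking is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = ["Trajectory", "link_detections", "tracks_to_frame"]


@dataclass
class Trajectory:
    """A linked trajectory: strictly increasing frames with (x, y) in px."""

    id: int
    frames: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    channel: int = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x_px = np.asarray(self.x_px, dtype=float)
        self.y_px = np.asarray(self.y_px, dtype=float)
        if len(self.frames) < 2:
            raise ValueError("a trajectory needs >= 2 points")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("trajectory frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x_px, self.y_px])

    def xy_um(self, pixel_size_um: float) -> np.ndarray:
        return self.xy * pixel_size_um


@dataclass
class _OpenTrack:
    points: list[tuple[int, float, float]] = field(default_factory=list)

    @property
    def last_frame(self) -> int:
        return self.points[-1][0]

    @property
    def last_xy(self) -> tuple[float, float]:
        return self.points[-1][1], self.points[-1][2]


def link_detections(
    detections: pd.DataFrame,
    max_disp_px: float = 5.0,
    max_gap_frames: int = 0,
    min_track_len: int = 20,
    channel: int = 0,
) -> list[Trajectory]:
    """Link a detection table (columns frame, x_px, y_px) into trajectories.

    Per frame, open tracks whose last detection lies within the gap window
    compete for the new detections via Hungarian assignment on squared
    distance; candidate links farther than ``max_disp_px * (gap + 1)`` are
    forbidden.  Unmatched detections seed new tracks.  Every detection is
    used at most once.
    """
    if max_disp_px <= 0:
        raise ValueError("max_disp_px must be > 0")
    if max_gap_frames < 0:
        raise ValueError("max_gap_frames must be >= 0")
    required = {"frame", "x_px", "y_px"}
    if not required.issubset(detections.columns):
        raise ValueError(f"detection table must have columns {sorted(required)}")
    if len(detections) == 0:
        return []
    det = detections.sort_values(["frame", "y_px", "x_px"], kind="stable").reset_index(drop=True)
    dup_cols = ["frame", "x_px", "y_px"] + (["channel"] if "channel" in det.columns else [])
    if det.duplicated(subset=dup_cols).any():
        raise ValueError("duplicate detections (same frame, coordinates and channel)")

    open_tracks: list[_OpenTrack] = []
    closed: list[_OpenTrack] = []
    for frame, grp in det.groupby("frame", sort=True):
        frame = int(frame)
        pts = grp[["x_px", "y_px"]].to_numpy(dtype=float)
        # retire tracks that can no longer be extended
        still_open = []
        for tr in open_tracks:
            if frame - tr.last_frame > max_gap_frames + 1:
                closed.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open

        assigned_det = np.zeros(len(pts), dtype=bool)
        if open_tracks and len(pts):
            last = np.array([tr.last_xy for tr in open_tracks])
            gaps = np.array([frame - tr.last_frame for tr in open_tracks])
            d2 = ((last[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
            limit2 = (max_disp_px * gaps) ** 2  # displacement budget scales with gap
            big = 1e12
            cost = np.where(d2 <= limit2[:, None], d2, big)
            rows, cols = linear_sum_assignment(cost)
            for r, c in zip(rows, cols):
                if cost[r, c] >= big:
                    continue
                open_tracks[r].points.append((frame, float(pts[c, 0]), float(pts[c, 1])))
                assigned_det[c] = True
        for c in np.flatnonzero(~assigned_det):
            open_tracks.append(_OpenTrack([(frame, float(pts[c, 0]), float(pts[c, 1]))]))

    closed.extend(open_tracks)
    trajectories = []
    tid = 0
    for tr in closed:
        if len(tr.points) < max(min_track_len, 2):
            continue
        pts_arr = np.array(tr.points)
        trajectories.append(
            Trajectory(tid, pts_arr[:, 0].astype(int), pts_arr[:, 1], pts_arr[:, 2], channel)
        )
        tid += 1
    trajectories.sort(key=lambda t: (t.frames[0], t.y_px[0], t.x_px[0]))
    for new_id, t in enumerate(trajectories):
        t.id = new_id
    return trajectories


def tracks_to_frame(
    tracks: list[Trajectory], pixel_size_um: float, frame_interval_s: float
) -> pd.DataFrame:
    """Flatten trajectories to a long table with physical units."""
    rows = []
    for tr in tracks:
        for f, x, y in zip(tr.frames, tr.x_px, tr.y_px):
            rows.append(
                (tr.id, int(f), f * frame_interval_s, x, y, x * pixel_size_um, y * pixel_size_um)
            )
    return pd.DataFrame(
        rows, columns=["track_id", "frame", "time_s", "x_px", "y_px", "x_um", "y_um"]
    )
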