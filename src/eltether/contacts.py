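"""Contact calling, ER-association scoring and marker co-occurrence.

A contact between a bright tether-protein accumulation and an endolysosome
(EL) is called when their thresholded masks share at least one pixel.
Co-occurrence is linked across frames by EL-object mask overlap, and an event
is accepted as a true contact only if it persists for at least
``min_duration_s`` (10 s by default) — transient encounters are rejected.
Event duration counts both endpoint frames: a pair visible in frames
``start..end`` lasted ``(end - start + 1)`` frame intervals.

The same persistence logic applied across z instead of t counts contacts in
fixed-cell z-stacks, where a true contact is expected in at least two
consecutive slices.

ER association of a followed EL is scored over a fixed window of frames
(10 frames at 2.4 s intervals by default): the fraction of frames in which
any suprathreshold ER signal falls inside the EL mask, expressed as a
percentage of time associated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.measure import label as sk_label

from .detection import threshold_accumulations
from .stack import ImageStack

__all__ = [
    "ContactEvent",
    "AssociationScore",
    "MarkerOverlapTable",
    "events_from_cooccurrence",
    "detect_contacts",
    "detect_contacts_zstack",
    "score_er_association",
    "classify_marker_overlap",
]


@dataclass(frozen=True)
class ContactEvent:
    """One co-occurrence interval between an accumulation and an EL object."""

    cell_id: str
    event_id: int
    start_frame: int
    end_frame: int
    frame_interval_s: float

    def __post_init__(self) -> None:
        if self.end_frame < self.start_frame:
            raise ValueError("event ends before it starts")

    @property
    def duration_s(self) -> float:
        return (self.end_frame - self.start_frame + 1) * self.frame_interval_s

    def accepted(self, min_duration_s: float) -> bool:
        return self.duration_s >= min_duration_s


@dataclass(frozen=True)
class AssociationScore:
    """Fraction of followed frames in which an EL shows ER signal inside it."""

    el_id: str
    n_frames_followed: int
    n_frames_with_er: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_frames_with_er <= self.n_frames_followed:
            raise ValueError("frames with ER must lie in [0, frames followed]")

    @property
    def percent(self) -> float:
        return 100.0 * self.n_frames_with_er / self.n_frames_followed


@dataclass
class MarkerOverlapTable:
    """Counts of puncta per marker subset (the co-occurrence Venn table)."""

    subset_counts: dict[frozenset, int]

    @property
    def total(self) -> int:
        return sum(self.subset_counts.values())

    @property
    def percentages(self) -> dict[frozenset, float]:
        n = self.total
        return {k: 100.0 * v / n for k, v in self.subset_counts.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("+".join(sorted(k)) if k else "(none)", v, 100.0 * v / self.total)
            for k, v in sorted(self.subset_counts.items(), key=lambda kv: sorted(kv[0]))
        ]
        return pd.DataFrame(rows, columns=["subset", "count", "percent"])


def events_from_cooccurrence(
    present: np.ndarray,
    frame_interval_s: float,
    min_duration_s: float = 10.0,
    max_gap_frames: int = 0,
    cell_id: str = "cell",
) -> tuple[list[ContactEvent], int]:
    """Turn a per-frame boolean co-occurrence series into contact events.

    Runs of ``True`` separated by at most ``max_gap_frames`` missing frames
    form one event.  Returns all events plus the count of accepted ones
    (duration >= ``min_duration_s``).
    """
    present = np.asarray(present, dtype=bool)
    if present.ndim != 1:
        raise ValueError("co-occurrence series must be 1-D")
    if frame_interval_s <= 0:
        raise ValueError("frame_interval_s must be > 0")
    if min_duration_s > len(present) * frame_interval_s:
        warnings.warn(
            "min_duration_s exceeds the recording length; no event can be accepted",
            stacklevel=2,
        )
    events: list[ContactEvent] = []
    start = None
    last_on = None
    eid = 0
    for t, on in enumerate(present):
        if on:
            if start is None:
                start = t
            elif t - last_on > max_gap_frames + 1:
                events.append(ContactEvent(cell_id, eid, start, last_on, frame_interval_s))
                eid += 1
                start = t
            last_on = t
    if start is not None:
        events.append(ContactEvent(cell_id, eid, start, last_on, frame_interval_s))
    accepted = sum(1 for e in events if e.accepted(min_duration_s))
    return events, accepted


def _object_masks(binary: np.ndarray, min_area_px: int = 1) -> list[np.ndarray]:
    labels = sk_label(binary, connectivity=2)
    out = []
    for i in range(1, labels.max() + 1):
        m = labels == i
        if m.sum() >= min_area_px:
            out.append(m)
    return out


def _remove_small(binary: np.ndarray, min_area_px: int) -> np.ndarray:
    if min_area_px <= 1:
        return binary
    labels = sk_label(binary, connectivity=2)
    if labels.max() == 0:
        return binary
    areas = np.bincount(labels.ravel())
    keep = areas >= min_area_px
    keep[0] = False
    return keep[labels]


def detect_contacts(
    stack: ImageStack,
    snx_channel: int | str,
    el_channel: int | str,
    min_duration_s: float = 10.0,
    max_gap_frames: int = 0,
    snx_threshold: tuple[str, float] = ("percentile", 99.5),
    el_threshold: tuple[str, float] = ("percentile", 99.0),
    min_object_px: int = 4,
    cell_id: str = "cell",
) -> tuple[list[ContactEvent], int]:
    """Call persistent accumulation-EL contacts in a two-channel recording.

    Per frame, the accumulation mask (bright foci above the reticular
    background) is intersected with segmented EL objects; an EL object
    overlapping an accumulation in one frame continues the same event in the
    next frame if its mask overlaps the event's previous EL mask.  Events
    must persist ``min_duration_s`` to be accepted.  Connected regions
    smaller than ``min_object_px`` in either mask are discarded as shot-noise
    specks (diffraction-limited objects cover many pixels).
    """
    if stack.frame_interval_s <= 0:
        raise ValueError("stack must carry a positive frame interval")
    snx_masks = threshold_accumulations(
        stack, snx_channel, method=snx_threshold[0], level=snx_threshold[1]
    ).masks
    el_masks = threshold_accumulations(
        stack, el_channel, method=el_threshold[0], level=el_threshold[1]
    ).masks
    snx_masks = np.stack([_remove_small(m, min_object_px) for m in snx_masks])
    el_masks = np.stack([_remove_small(m, min_object_px) for m in el_masks])

    if min_duration_s > stack.n_frames * stack.frame_interval_s:
        warnings.warn(
            "min_duration_s exceeds the recording length; no event can be accepted",
            stacklevel=2,
        )

    active: list[dict] = []  # {mask, start, last}
    finished: list[tuple[int, int]] = []
    for t in range(stack.n_frames):
        contact_objs = [
            m for m in _object_masks(el_masks[t]) if (m & snx_masks[t]).any()
        ]
        matched_new = [False] * len(contact_objs)
        still_active = []
        for ev in active:
            hit = None
            for i, m in enumerate(contact_objs):
                if not matched_new[i] and (m & ev["mask"]).any():
                    hit = i
                    break
            if hit is not None:
                matched_new[hit] = True
                ev["mask"] = contact_objs[hit]
                ev["last"] = t
                still_active.append(ev)
            elif t - ev["last"] <= max_gap_frames:
                still_active.append(ev)  # tolerate a dropout
            else:
                finished.append((ev["start"], ev["last"]))
        active = still_active
        for i, m in enumerate(contact_objs):
            if not matched_new[i]:
                active.append({"mask": m, "start": t, "last": t})
    finished.extend((ev["start"], ev["last"]) for ev in active)

    events = [
        ContactEvent(cell_id, i, s, e, stack.frame_interval_s)
        for i, (s, e) in enumerate(sorted(finished))
    ]
    accepted = sum(1 for e in events if e.accepted(min_duration_s))
    return events, accepted


def detect_contacts_zstack(
    stack: ImageStack,
    snx_channel: int | str,
    el_channel: int | str,
    min_consecutive_z: int = 2,
    snx_threshold: tuple[str, float] = ("percentile", 99.5),
    el_threshold: tuple[str, float] = ("percentile", 99.0),
    min_object_px: int = 4,
    cell_id: str = "cell",
) -> tuple[list[ContactEvent], int]:
    """Count contacts in a fixed-cell z-stack: persistence across z slices.

    The stack's first axis is read as z.  The per-slice overlap logic is the
    same as :func:`detect_contacts`; a contact is counted when it appears in
    at least ``min_consecutive_z`` consecutive slices.
    """
    if stack.n_frames < 2:
        raise ValueError(
            "z-stack contact counting needs >= 2 slices; use detect_contacts for time-lapse"
        )
    zstack = ImageStack(
        stack.data,
        pixel_size_um=stack.pixel_size_um,
        frame_interval_s=1.0,  # slice index stands in for time
        channel_names=stack.channel_names,
    )
    events, _ = detect_contacts(
        zstack,
        snx_channel,
        el_channel,
        min_duration_s=float(min_consecutive_z),
        max_gap_frames=0,
        snx_threshold=snx_threshold,
        el_threshold=el_threshold,
        min_object_px=min_object_px,
        cell_id=cell_id,
    )
    accepted = sum(1 for e in events if e.accepted(float(min_consecutive_z)))
    return events, accepted


def score_er_association(
    el_masks: np.ndarray,
    er_frames: np.ndarray,
    er_threshold: float,
    el_id: str = "el",
    n_frames_followed: int = 10,
) -> AssociationScore:
    """Percent of followed frames with ER signal inside the EL mask.

    ``el_masks`` is (n, y, x) boolean, one mask per followed frame (exactly
    ``n_frames_followed``); ``er_frames`` the matching ER-channel frames.
    A frame scores positive when any ER pixel above ``er_threshold`` lies
    inside that frame's EL mask.
    """
    masks = np.asarray(el_masks, dtype=bool)
    er = np.asarray(er_frames, dtype=float)
    if masks.shape[0] != n_frames_followed:
        raise ValueError(
            f"expected {n_frames_followed} EL masks, got {masks.shape[0]}"
        )
    if er.shape != masks.shape:
        raise ValueError("ER frames must align with EL masks frame by frame")
    hits = int(sum(bool(((er[t] > er_threshold) & masks[t]).any()) for t in range(len(masks))))
    return AssociationScore(el_id, n_frames_followed, hits)


def classify_marker_overlap(
    puncta_xy_px: np.ndarray,
    marker_masks: dict[str, np.ndarray],
) -> MarkerOverlapTable:
    """Label each punctum with the subset of marker masks containing it.

    All masks must share one shape (the common frame).  A punctum belongs to
    a marker when the mask is true at its (rounded) position.  The table
    includes the empty subset, and subset percentages sum to 100.
    """
    pts = np.asarray(puncta_xy_px, dtype=float).reshape(-1, 2)
    if not marker_masks:
        raise ValueError("need at least one marker mask")
    shapes = {m.shape for m in marker_masks.values()}
    if len(shapes) != 1:
        raise ValueError("marker masks must share one shape")
    ny, nx = shapes.pop()
    counts: dict[frozenset, int] = {}
    for x, y in pts:
        iy = int(round(y))
        ix = int(round(x))
        if not (0 <= iy < ny and 0 <= ix < nx):
            raise ValueError(f"punctum ({x}, {y}) outside the frame")
        subset = frozenset(
            name for name, mask in marker_masks.items() if mask[iy, ix]
        )
        counts[subset] = counts.get(subset, 0) + 1
    return MarkerOverlapTable(counts)


def events_to_frame(events: list[ContactEvent], min_duration_s: float) -> pd.DataFrame:
    """Flatten contact events to the CSV schema."""
    rows = [
        (e.cell_id, e.event_id, e.start_frame, e.end_frame, e.duration_s, e.accepted(min_duration_s))
        for e in events
    ]
    return pd.DataFrame(
        rows,
        columns=["cell_id", "event_id", "start_frame", "end_frame", "duration_s", "accepted"],
    )
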