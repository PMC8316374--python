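"""ER-endolysosome contact fraction from traced serial-section EM contours.

Endolysosome (EL) membranes are traced as closed polygons and ER membranes as
polylines, in nanometres, one set per ~50 nm serial section.  Membrane
apposition at or below a cutoff (30 nm by default) defines a contact.  For
each EL the boundary is resampled finely, the minimum curve-to-curve distance
to the ER is evaluated at each sample, and the arc length within the cutoff
is accumulated, with linear interpolation where the distance profile crosses
the cutoff between samples.  Perimeters and contact lengths are summed over
all sections that captured the EL before dividing — percentages are never
averaged per section — and results are aggregated as an unweighted per-cell
mean over ELs.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LinearRing, LineString, MultiLineString
from shapely.ops import unary_union

__all__ = [
    "EMContourSet",
    "EMResult",
    "circle_polygon",
    "measure_section",
    "measure_contour_set",
    "el_contact_percent",
    "per_cell_mean",
]

_CSV_COLUMNS = ["section_id", "object_type", "object_id", "vertex_index", "x_nm", "y_nm", "closed"]


def circle_polygon(
    center: tuple[float, float], radius: float, n_vertices: int = 720
) -> np.ndarray:
    """Vertices (n, 2) of a regular polygon approximating a circle, in nm."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    theta = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    return np.column_stack(
        [center[0] + radius * np.cos(theta), center[1] + radius * np.sin(theta)]
    )


@dataclass
class EMContourSet:
    """Traced contours for a set of serial sections.

    ``el`` maps ``(section_id, el_id)`` to a closed polygon (n, 2) in nm;
    ``er`` maps ``(section_id, er_id)`` to a polyline (n, 2) in nm.
    """

    el: dict[tuple[int, str], np.ndarray] = field(default_factory=dict)
    er: dict[tuple[int, str], np.ndarray] = field(default_factory=dict)
    section_thickness_nm: float = 50.0

    def add_el(self, section_id: int, el_id: str, polygon: np.ndarray) -> None:
        poly = np.asarray(polygon, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
            raise ValueError("EL polygon must be (n>=3, 2)")
        if not np.isfinite(poly).all():
            raise ValueError("EL polygon coordinates must be finite")
        self.el[(int(section_id), str(el_id))] = poly

    def add_er(self, section_id: int, er_id: str, polyline: np.ndarray) -> None:
        pl = np.asarray(polyline, dtype=float)
        if pl.ndim != 2 or pl.shape[1] != 2 or len(pl) < 2:
            raise ValueError("ER polyline must be (n>=2, 2)")
        if not np.isfinite(pl).all():
            raise ValueError("ER polyline coordinates must be finite")
        self.er[(int(section_id), str(er_id))] = pl

    def sections_for_el(self, el_id: str) -> list[int]:
        return sorted(s for (s, e) in self.el if e == el_id)

    def el_ids(self) -> list[str]:
        return sorted({e for (_, e) in self.el})

    def er_in_section(self, section_id: int) -> list[np.ndarray]:
        return [pl for (s, _), pl in sorted(self.er.items()) if s == section_id]

    def to_frame(self) -> pd.DataFrame:
        """Flatten to the exchange table (one row per vertex)."""
        rows = []
        for (sec, oid), poly in sorted(self.el.items()):
            for i, (x, y) in enumerate(poly):
                rows.append((sec, "EL", oid, i, x, y, 1))
        for (sec, oid), pl in sorted(self.er.items()):
            for i, (x, y) in enumerate(pl):
                rows.append((sec, "ER", oid, i, x, y, 0))
        return pd.DataFrame(rows, columns=_CSV_COLUMNS)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, section_thickness_nm: float = 50.0) -> "EMContourSet":
        missing = [c for c in _CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"contour table missing columns {missing}")
        out = cls(section_thickness_nm=section_thickness_nm)
        for (sec, otype, oid), grp in df.groupby(["section_id", "object_type", "object_id"]):
            pts = grp.sort_values("vertex_index")[["x_nm", "y_nm"]].to_numpy(dtype=float)
            if otype == "EL":
                out.add_el(int(sec), str(oid), pts)
            elif otype == "ER":
                out.add_er(int(sec), str(oid), pts)
            else:
                raise ValueError(f"unknown object_type {otype!r}")
        return out


@dataclass
class EMResult:
    """Per-EL summed perimeter / contact length and derived percentage."""

    el_id: str
    perimeter_nm: float
    contact_nm: float

    @property
    def percent(self) -> float:
        return 100.0 * self.contact_nm / self.perimeter_nm


def _resample_ring(ring: LinearRing, step_nm: float) -> tuple[np.ndarray, np.ndarray]:
    """Sample the ring at arc-length spacing <= step; return points and arclengths."""
    length = ring.length
    n = max(int(math.ceil(length / step_nm)), 8)
    s = np.linspace(0.0, length, n, endpoint=False)
    pts = shapely.get_coordinates(shapely.line_interpolate_point(ring, s))
    return pts, s


def measure_section(
    el_polygon: np.ndarray,
    er_polylines: list[np.ndarray],
    cutoff_nm: float = 30.0,
    resample_step_nm: float = 5.0,
) -> tuple[float, float]:
    """Perimeter and ER-contact length of one EL in one section, in nm.

    The EL boundary is resampled at <= ``resample_step_nm``; each sample's
    minimum distance to the union of ER polylines is computed, and the
    contact length sums the boundary arcs where that distance is <= cutoff,
    with sub-sample crossings located by linear interpolation of the distance
    profile.  With no ER traced in the section the contact length is zero.
    """
    poly = np.asarray(el_polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
        raise ValueError("EL polygon must be (n>=3, 2)")
    if cutoff_nm <= 0:
        raise ValueError("cutoff_nm must be > 0")
    ring = LinearRing(poly)
    if not ring.is_valid or not ring.is_simple:
        raise ValueError("EL polygon is self-intersecting or degenerate")
    perimeter = float(ring.length)
    if not er_polylines:
        return perimeter, 0.0

    lines = []
    for pl in er_polylines:
        pl = np.asarray(pl, dtype=float)
        seg = np.diff(pl, axis=0)
        if np.any(np.hypot(seg[:, 0], seg[:, 1]) == 0):
            raise ValueError("degenerate (zero-length) ER polyline segment")
        lines.append(LineString(pl))
    er_union = unary_union(MultiLineString(lines)) if len(lines) > 1 else lines[0]

    pts, _ = _resample_ring(ring, resample_step_nm)
    dist = shapely.distance(er_union, shapely.points(pts))

    n = len(pts)
    step = perimeter / n
    inside = dist <= cutoff_nm
    contact = 0.0
    # integrate over the closed sample cycle; fractional arcs at crossings
    f = cutoff_nm - dist  # >= 0 inside contact
    for i in range(n):
        j = (i + 1) % n
        if inside[i] and inside[j]:
            contact += step
        elif inside[i] != inside[j]:
            # linear zero crossing of f between samples
            denom = f[i] - f[j]
            frac = f[i] / denom if denom != 0 else 0.5
            contact += step * (frac if inside[i] else 1.0 - frac)
    return perimeter, min(contact, perimeter)


def el_contact_percent(
    sections: list[tuple[float, float]], el_id: str = "el"
) -> EMResult:
    """Aggregate per-section (perimeter, contact) pairs for one EL.

    Sums all perimeters and all contact lengths across sections, then divides
    (x100).  Never averages per-section percentages.
    """
    if not sections:
        raise ValueError("need at least one section")
    perim = float(sum(p for p, _ in sections))
    contact = float(sum(c for _, c in sections))
    if perim <= 0:
        raise ValueError("summed perimeter is zero")
    if contact > perim + 1e-9:
        raise ValueError("summed contact exceeds summed perimeter")
    return EMResult(el_id, perim, min(contact, perim))


def measure_contour_set(
    contours: EMContourSet,
    cutoff_nm: float = 30.0,
    resample_step_nm: float = 5.0,
) -> list[EMResult]:
    """Measure every EL in a contour set across all its sections."""
    results = []
    for el_id in contours.el_ids():
        per_section = []
        for sec in contours.sections_for_el(el_id):
            per_section.append(
                measure_section(
                    contours.el[(sec, el_id)],
                    contours.er_in_section(sec),
                    cutoff_nm,
                    resample_step_nm,
                )
            )
        results.append(el_contact_percent(per_section, el_id))
    return results


def per_cell_mean(results: list[EMResult], cell_of_el: dict[str, str]) -> dict[str, float]:
    """Unweighted mean contact percentage over the ELs of each cell."""
    unassigned = [r.el_id for r in results if r.el_id not in cell_of_el]
    if unassigned:
        raise ValueError(f"ELs without a cell assignment: {unassigned}")
    by_cell: dict[str, list[float]] = defaultdict(list)
    for r in results:
        by_cell[cell_of_el[r.el_id]].append(r.percent)
    return {cell: float(np.mean(vals)) for cell, vals in sorted(by_cell.items())}
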