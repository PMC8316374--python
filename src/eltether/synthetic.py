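"""Ground-truthed synthetic scenes for every analysis stage.

Real acquisitions behind the quantifications this package implements are not
publicly deposited, so each stage is validated against simulated inputs whose
ground truth is known by construction:

* trajectories with confined / free / directed kinetics (reflected Brownian
  in a disc, Brownian, Brownian plus constant drift);
* rendered time-lapse movies: diffraction-limited spots (pixel-integrated
  2-D Gaussians) over a reticular ER-like line network, with Poisson photon
  noise and Gaussian read noise, optionally with a second channel carrying
  co-moving accumulations during planned dwell intervals;
* dispersal stills with puncta placed to a target peripheral fraction;
* serial-section EM contour sets (circle + line geometries) with a
  closed-form contact percentage;
* proximity-ligation-style dot images with exact planted areas.

Every generator takes an explicit seed and is byte-identical under it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import Voronoi
from scipy.special import erf
from shapely.geometry import Polygon
from skimage.draw import line as draw_line
from skimage.draw import polygon as draw_polygon

from .em import EMContourSet, circle_polygon
from .shells import ShellMap, build_shells
from .stack import ImageStack

__all__ = [
    "MotionSpec",
    "ContactDwell",
    "SceneSpec",
    "GroundTruth",
    "SimulatedTrack",
    "simulate_trajectory",
    "render_movie",
    "make_dispersal_scene",
    "make_em_scene",
    "make_pla_scene",
    "circle_line_contact_percent",
    "reticular_background",
]

MOTION_MODELS = ("confined", "free", "directed")


@dataclass(frozen=True)
class MotionSpec:
    """Parameters of one simulated particle's motion.

    model
        ``"free"`` — Brownian motion with per-axis increment variance
        ``2*D*dt``; ``"directed"`` — Brownian plus constant-speed drift in a
        fixed random direction; ``"confined"`` — Brownian reflected at the
        boundary of a disc of radius ``R_c``.
    D : µm²/s, v : µm/s, R_c : µm, dt : s, loc_noise_sigma : µm
    """

    model: str
    D: float
    dt: float
    n_frames: int
    v: float = 0.0
    R_c: float = 0.0
    loc_noise_sigma: float = 0.02

    def __post_init__(self) -> None:
        if self.model not in MOTION_MODELS:
            raise ValueError(f"model must be one of {MOTION_MODELS}; got {self.model!r}")
        if self.D < 0:
            raise ValueError(f"D must be >= 0; got {self.D}")
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0; got {self.dt}")
        if self.n_frames < 2:
            raise ValueError(f"n_frames must be >= 2; got {self.n_frames}")
        if self.model == "confined" and self.R_c <= 0:
            raise ValueError("R_c must be > 0 for confined motion")
        if self.model == "directed" and self.v <= 0:
            raise ValueError("v must be > 0 for directed motion")
        if self.loc_noise_sigma < 0:
            raise ValueError(f"loc_noise_sigma must be >= 0; got {self.loc_noise_sigma}")


@dataclass(frozen=True)
class SimulatedTrack:
    """One simulated trajectory with its ground truth.

    ``true_um`` are the physical positions (before localization noise);
    ``observed_um`` adds i.i.d. Gaussian localization error per frame, applied
    after confinement reflection, so observed positions may slightly exceed
    the confinement radius.
    """

    true_um: np.ndarray  # (n_frames, 2) as (x, y)
    observed_um: np.ndarray
    label: str
    spec: MotionSpec


def simulate_trajectory(spec: MotionSpec, seed: int | np.random.Generator) -> SimulatedTrack:
    """Simulate one 2-D trajectory starting at the origin.

    Reflection for confined motion is applied radially about the disc centre
    (the origin): a proposed position at radius ``r > R_c`` is mapped to
    radius ``2*R_c - r`` along the same ray, iterated until inside.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = spec.n_frames
    step_sd = math.sqrt(2.0 * spec.D * spec.dt)
    steps = rng.normal(0.0, step_sd, size=(n - 1, 2)) if step_sd > 0 else np.zeros((n - 1, 2))

    if spec.model == "directed":
        theta = rng.uniform(0.0, 2.0 * math.pi)
        drift = spec.v * spec.dt * np.array([math.cos(theta), math.sin(theta)])
        pos = np.vstack([np.zeros(2), np.cumsum(steps + drift, axis=0)])
    elif spec.model == "free":
        pos = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
    else:  # confined: reflect each step at the disc boundary
        pos = np.zeros((n, 2))
        p = np.zeros(2)
        for i in range(1, n):
            p = p + steps[i - 1]
            r = float(np.hypot(*p))
            while r > spec.R_c:
                p = p * ((2.0 * spec.R_c - r) / r)
                r = float(np.hypot(*p))
            pos[i] = p

    noise = (
        rng.normal(0.0, spec.loc_noise_sigma, size=pos.shape)
        if spec.loc_noise_sigma > 0
        else np.zeros_like(pos)
    )
    return SimulatedTrack(pos, pos + noise, spec.model, spec)


@dataclass(frozen=True)
class ContactDwell:
    """A planned accumulation dwell on one particle, in seconds."""

    particle: int
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.end_s < self.start_s:
            raise ValueError("dwell end before start")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class SceneSpec:
    """Full specification of a rendered two-channel time-lapse scene.

    Amplitudes are peak pixel values (above background) of the rendered
    Gaussian spots.  ``contact_plan`` lists which particles additionally
    carry a bright accumulation in the second channel, and when.
    """

    shape_px: tuple[int, int]  # (ny, nx)
    pixel_size_um: float = 0.1
    psf_sigma_px: float = 1.3
    channels: tuple[str, ...] = ("EL",)
    motions: list[MotionSpec] = field(default_factory=list)
    start_positions_um: np.ndarray | None = None  # (n_particles, 2) (x, y)
    contact_plan: list[ContactDwell] = field(default_factory=list)
    spot_amplitude: float = 100.0
    accumulation_amplitude: float = 300.0
    background: float = 100.0
    er_network_amplitude: float = 0.0
    er_network_seeds: int = 60
    poisson_noise: bool = True
    read_noise_sd: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.psf_sigma_px <= 0:
            raise ValueError("psf_sigma_px must be > 0")
        if self.motions:
            dts = {m.dt for m in self.motions}
            nfs = {m.n_frames for m in self.motions}
            if len(dts) > 1 or len(nfs) > 1:
                raise ValueError("all particles must share dt and n_frames")
        if self.contact_plan and len(self.channels) < 2:
            raise ValueError("a contact plan requires a second (accumulation) channel")

    @property
    def n_frames(self) -> int:
        return self.motions[0].n_frames if self.motions else 1

    @property
    def frame_interval_s(self) -> float:
        return self.motions[0].dt if self.motions else 0.0


@dataclass
class GroundTruth:
    """Everything the generators know that the analyses must recover."""

    positions_um: np.ndarray | None = None  # (n_particles, n_frames, 2) (x, y)
    motion_labels: list[str] = field(default_factory=list)
    contact_intervals: list[ContactDwell] = field(default_factory=list)
    dispersal_fraction: float | None = None
    puncta_xy_px: np.ndarray | None = None
    pla_count: int | None = None
    pla_areas_px: list[int] = field(default_factory=list)
    pla_touching: list[bool] = field(default_factory=list)
    em_percent: float | None = None


def _integrated_gaussian_peak_factor(sigma: float) -> float:
    """Peak pixel fraction of total flux for a pixel-centred integrated Gaussian."""
    half = erf(0.5 / (sigma * math.sqrt(2.0)))
    return half * half


def add_spot(
    img: np.ndarray, x_px: float, y_px: float, sigma: float, peak_amplitude: float
) -> None:
    """Add a pixel-integrated 2-D Gaussian spot to ``img`` in place.

    The model integrates the Gaussian over each pixel (error-function form),
    so sub-pixel localization against this rendering is unbiased.  The spot is
    scaled so that a spot centred exactly on a pixel has that pixel at
    ``peak_amplitude`` above the existing image.
    """
    ny, nx = img.shape
    flux = peak_amplitude / _integrated_gaussian_peak_factor(sigma)
    w = max(4, int(math.ceil(5 * sigma)))
    x0, x1 = int(math.floor(x_px)) - w, int(math.floor(x_px)) + w + 1
    y0, y1 = int(math.floor(y_px)) - w, int(math.floor(y_px)) + w + 1
    x0c, x1c, y0c, y1c = max(x0, 0), min(x1, nx), max(y0, 0), min(y1, ny)
    if x0c >= x1c or y0c >= y1c:
        return
    s2 = sigma * math.sqrt(2.0)
    xs = np.arange(x0c, x1c)
    ys = np.arange(y0c, y1c)
    gx = 0.5 * (erf((xs + 0.5 - x_px) / s2) - erf((xs - 0.5 - x_px) / s2))
    gy = 0.5 * (erf((ys + 0.5 - y_px) / s2) - erf((ys - 0.5 - y_px) / s2))
    img[y0c:y1c, x0c:x1c] += flux * np.outer(gy, gx)


def reticular_background(
    shape_px: tuple[int, int],
    amplitude: float,
    n_seeds: int,
    psf_sigma_px: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """A reticular ER-like line network: blurred Voronoi ridge edges.

    The edges of a random Voronoi tessellation give a connected polygonal
    network resembling peripheral ER tubules; blurring by the PSF makes its
    intensity profile comparable to in-focus tubule fluorescence.
    """
    ny, nx = shape_px
    img = np.zeros((ny, nx), dtype=float)
    if amplitude <= 0 or n_seeds < 4:
        return img
    pts = rng.uniform(low=[-0.2 * nx, -0.2 * ny], high=[1.2 * nx, 1.2 * ny], size=(n_seeds, 2))
    vor = Voronoi(pts)
    for a, b in vor.ridge_vertices:
        if a == -1 or b == -1:
            continue
        xa, ya = vor.vertices[a]
        xb, yb = vor.vertices[b]
        if not all(map(math.isfinite, (xa, ya, xb, yb))):
            continue
        # clip to a margin box before rasterizing
        if max(abs(xa), abs(xb)) > 4 * nx or max(abs(ya), abs(yb)) > 4 * ny:
            continue
        rr, cc = draw_line(int(round(ya)), int(round(xa)), int(round(yb)), int(round(xb)))
        keep = (rr >= 0) & (rr < ny) & (cc >= 0) & (cc < nx)
        img[rr[keep], cc[keep]] = 1.0
    img = ndimage.gaussian_filter(img, psf_sigma_px)
    if img.max() > 0:
        img *= amplitude / img.max()
    return img


def _fit_starts(
    scene: SceneSpec, rel_positions: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Choose start positions so each particle's whole path stays in frame.

    ``rel_positions`` are trajectories relative to their own origin; a start
    is drawn uniformly from the rectangle of offsets that keeps the path's
    bounding box inside the frame with a PSF-sized margin.
    """
    ny, nx = scene.shape_px
    margin = 6 * scene.psf_sigma_px * scene.pixel_size_um
    hi_x = (nx - 1) * scene.pixel_size_um - margin
    hi_y = (ny - 1) * scene.pixel_size_um - margin
    starts = np.zeros((len(scene.motions), 2))
    for i, rel in enumerate(rel_positions):
        lo = margin - rel.min(axis=0)
        hi = np.array([hi_x, hi_y]) - rel.max(axis=0)
        if np.any(hi < lo):
            raise ValueError(
                f"particle {i} wanders farther than the frame allows "
                f"(path extent {np.ptp(rel, axis=0)} um)"
            )
        starts[i] = rng.uniform(lo, hi)
    return starts


def render_movie(scene: SceneSpec) -> tuple[ImageStack, GroundTruth]:
    """Render a scene to a calibrated image stack plus its ground truth.

    Particle positions are simulated first (in µm, relative to their start
    positions), then rendered frame by frame; the contact plan adds a
    brighter accumulation spot in the second channel during each dwell.
    Background and the reticular network are added before noise; Poisson
    photon noise and Gaussian read noise are applied last.

    Raises
    ------
    ValueError
        If any particle's true position leaves the frame, naming the particle
        and frame.
    """
    rng = np.random.default_rng(scene.rng_seed)
    ny, nx = scene.shape_px
    n_frames = scene.n_frames
    n_particles = len(scene.motions)
    n_channels = len(scene.channels)

    rel_positions = np.zeros((n_particles, n_frames, 2))
    labels: list[str] = []
    for i, mspec in enumerate(scene.motions):
        tr = simulate_trajectory(mspec, rng)
        rel_positions[i] = tr.true_um
        labels.append(tr.label)

    if scene.start_positions_um is not None:
        starts = np.asarray(scene.start_positions_um, dtype=float)
        if starts.shape != (n_particles, 2):
            raise ValueError(f"start_positions_um must be ({n_particles}, 2)")
    else:
        starts = _fit_starts(scene, rel_positions, rng)
    positions = rel_positions + starts[:, None, :]

    # validate positions stay in frame (pixel-centre convention: valid
    # coordinates span [0, n-1] pixels)
    pos_px = positions / scene.pixel_size_um
    bad = (
        (pos_px[..., 0] < 0)
        | (pos_px[..., 0] > nx - 1)
        | (pos_px[..., 1] < 0)
        | (pos_px[..., 1] > ny - 1)
    )
    if bad.any():
        p, f = np.argwhere(bad)[0]
        raise ValueError(f"particle {p} leaves the frame at frame {f}")

    for dwell in scene.contact_plan:
        if not 0 <= dwell.particle < n_particles:
            raise ValueError(f"contact plan names unknown particle {dwell.particle}")
        if dwell.end_s > (n_frames - 1) * scene.frame_interval_s + 1e-9:
            raise ValueError(f"dwell on particle {dwell.particle} extends past the movie")

    bg = np.full((ny, nx), float(scene.background))
    if scene.er_network_amplitude > 0:
        bg = bg + reticular_background(
            scene.shape_px,
            scene.er_network_amplitude,
            scene.er_network_seeds,
            scene.psf_sigma_px,
            rng,
        )

    dt = scene.frame_interval_s
    data = np.zeros((n_frames, n_channels, ny, nx), dtype=float)
    for t in range(n_frames):
        frame0 = bg.copy()
        for i in range(n_particles):
            add_spot(frame0, pos_px[i, t, 0], pos_px[i, t, 1], scene.psf_sigma_px, scene.spot_amplitude)
        data[t, 0] = frame0
        if n_channels > 1:
            frame1 = bg.copy()
            t_s = t * dt
            for dwell in scene.contact_plan:
                if dwell.start_s - 1e-9 <= t_s <= dwell.end_s + 1e-9:
                    i = dwell.particle
                    add_spot(
                        frame1,
                        pos_px[i, t, 0],
                        pos_px[i, t, 1],
                        scene.psf_sigma_px,
                        scene.accumulation_amplitude,
                    )
            data[t, 1] = frame1
            for c in range(2, n_channels):
                data[t, c] = bg

    if scene.poisson_noise:
        data = rng.poisson(data).astype(float)
    if scene.read_noise_sd > 0:
        data = data + rng.normal(0.0, scene.read_noise_sd, size=data.shape)
    data = np.clip(data, 0, None)

    stack = ImageStack(
        data,
        pixel_size_um=scene.pixel_size_um,
        frame_interval_s=dt if n_frames > 1 else max(dt, 0.0),
        channel_names=scene.channels,
    )
    truth = GroundTruth(
        positions_um=positions,
        motion_labels=labels,
        contact_intervals=list(scene.contact_plan),
    )
    return stack, truth


def _rasterize_polygon_um(
    outline_um: Polygon, pixel_size_um: float, pad_px: int = 2
) -> np.ndarray:
    """Rasterize a polygon given in µm onto a pixel grid with a small pad."""
    minx, miny, maxx, maxy = outline_um.bounds
    if minx < 0 or miny < 0:
        raise ValueError("outline must lie in the positive quadrant (µm coordinates)")
    ny = int(math.ceil(maxy / pixel_size_um)) + 1 + pad_px
    nx = int(math.ceil(maxx / pixel_size_um)) + 1 + pad_px
    xs, ys = np.asarray(outline_um.exterior.coords).T
    rr, cc = draw_polygon(ys / pixel_size_um, xs / pixel_size_um, shape=(ny, nx))
    mask = np.zeros((ny, nx), dtype=bool)
    mask[rr, cc] = True
    return mask


def make_dispersal_scene(
    outline_um: Polygon,
    target_peripheral_fraction: float,
    n_puncta: int,
    seed: int,
    pixel_size_um: float = 0.1,
    psf_sigma_px: float = 1.3,
    amplitude: float = 200.0,
    step_um: float = 2.0,
    n_shells: int = 5,
    placement_margin_px: int = 4,
) -> tuple[np.ndarray, np.ndarray, float, ShellMap, np.ndarray]:
    """Render a still with puncta split between peripheral and inner shells.

    ``round(target * n_puncta)`` puncta are placed (uniformly over pixels) in
    the outer-three-shell region and the rest in the inner-two-shell region,
    keeping a margin from the region border so rendered spot intensity stays
    within its region.  The returned true fraction is recomputed from the
    actual placements, not the target.

    Returns ``(image, cell_mask, true_fraction, shell_map, puncta_xy_px)``
    where the last element holds the placed (x, y) sub-pixel positions.
    """
    if not outline_um.is_valid or outline_um.is_empty:
        raise ValueError("outline must be a valid, non-empty polygon")
    if not 0.0 <= target_peripheral_fraction <= 1.0:
        raise ValueError("target_peripheral_fraction must lie in [0, 1]")
    if n_puncta < 1:
        raise ValueError("n_puncta must be >= 1")

    rng = np.random.default_rng(seed)
    mask = _rasterize_polygon_um(outline_um, pixel_size_um)
    shell_map = build_shells(mask, pixel_size_um, step_um, n_shells)
    outer = shell_map.labels >= 3
    inner = (shell_map.labels >= 1) & (shell_map.labels <= 2)
    if not inner.any():
        raise ValueError("outline too small to contain the inner shells at this step")

    # stay clear of region borders so PSF bleed does not cross regions
    struct = np.ones((3, 3), dtype=bool)
    outer_core = ndimage.binary_erosion(outer, struct, iterations=placement_margin_px)
    inner_core = ndimage.binary_erosion(inner, struct, iterations=placement_margin_px)
    outer_core = outer_core if outer_core.any() else outer
    inner_core = inner_core if inner_core.any() else inner

    n_out = int(round(target_peripheral_fraction * n_puncta))
    n_in = n_puncta - n_out
    img = np.zeros(mask.shape, dtype=float)
    placed: list[tuple[float, float]] = []
    for region, count in ((outer_core, n_out), (inner_core, n_in)):
        idx = np.flatnonzero(region.ravel())
        if count > 0 and idx.size == 0:
            raise ValueError("placement region is empty")
        for flat in rng.choice(idx, size=count, replace=True) if count else []:
            y, x = divmod(int(flat), mask.shape[1])
            xs = x + rng.uniform(-0.45, 0.45)
            ys = y + rng.uniform(-0.45, 0.45)
            add_spot(img, xs, ys, psf_sigma_px, amplitude)
            placed.append((xs, ys))
    true_fraction = n_out / n_puncta
    return img, mask, true_fraction, shell_map, np.array(placed).reshape(-1, 2)


def circle_line_contact_percent(radius: float, line_distance: float, cutoff: float) -> float:
    """Closed-form percent of a circle's boundary within ``cutoff`` of a line.

    The line is an infinite straight line at perpendicular distance
    ``line_distance`` from the circle centre.  A boundary point at polar angle
    θ (measured from the foot of the perpendicular) lies at distance
    ``|line_distance - radius*cosθ|`` from the line, so the contact arc is
    the θ-range where ``cosθ`` falls in
    ``[(line_distance - cutoff)/radius, (line_distance + cutoff)/radius]``.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    lo = max((line_distance - cutoff) / radius, -1.0)
    hi = min((line_distance + cutoff) / radius, 1.0)
    if lo > hi:
        return 0.0
    frac = (math.acos(lo) - math.acos(hi)) / math.pi
    return 100.0 * frac


def make_em_scene(
    el_circles: list[tuple[tuple[float, float], float]],
    er_polylines: list[np.ndarray],
    cutoff_nm: float = 30.0,
    section_id: int = 0,
    el_ids: list[str] | None = None,
    n_circle_vertices: int = 720,
) -> tuple[EMContourSet, list[float]]:
    """Build a one-section EM contour set from circles and line segments.

    Each endolysosome is a circle (centre, radius, nm) discretized to a
    polygon; ER membranes are polylines.  For each circle the analytic
    contact percentage is computed against the *first* ER polyline treated as
    an infinite straight line (the fixture geometry this generator supports);
    with no ER the analytic percent is 0.

    Returns the contour set and the per-EL analytic percentages.
    """
    for pl in er_polylines:
        pl = np.asarray(pl, dtype=float)
        if len(pl) < 2:
            raise ValueError("ER polyline needs >= 2 vertices")
        seg = np.diff(pl, axis=0)
        if np.any(np.hypot(seg[:, 0], seg[:, 1]) == 0):
            raise ValueError("degenerate (zero-length) ER polyline segment")

    ids = el_ids or [f"el{i}" for i in range(len(el_circles))]
    contours = EMContourSet()
    analytic: list[float] = []
    for el_id, (center, radius) in zip(ids, el_circles):
        if radius <= 0:
            raise ValueError("circle radius must be > 0")
        contours.add_el(section_id, el_id, circle_polygon(center, radius, n_circle_vertices))
        if er_polylines:
            a = np.asarray(er_polylines[0][0], dtype=float)
            b = np.asarray(er_polylines[0][-1], dtype=float)
            d = _point_line_distance(np.asarray(center, dtype=float), a, b)
            analytic.append(circle_line_contact_percent(radius, d, cutoff_nm))
        else:
            analytic.append(0.0)
    for j, pl in enumerate(er_polylines):
        contours.add_er(section_id, f"er{j}", np.asarray(pl, dtype=float))
    return contours, analytic


def _point_line_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Perpendicular distance from ``p`` to the infinite line through a, b."""
    d = b - a
    q = p - a
    return float(abs(d[0] * q[1] - d[1] * q[0]) / np.hypot(*d))


def make_pla_scene(
    dot_spec: list[tuple[tuple[int, int], int]],
    seed: int,
    shape_px: tuple[int, int] = (128, 128),
    amplitude: float = 200.0,
    background: float = 10.0,
    noise_sd: float = 0.0,
    min_size_px: int = 5,
) -> tuple[np.ndarray, GroundTruth]:
    """Render filled dots with exact pixel areas for PLA counting tests.

    ``dot_spec`` lists ``((y, x) centre, area_px)`` per dot.  Each dot's
    footprint is the ``area_px`` pixels nearest its centre (ties broken
    deterministically by (distance, y, x)), so planted areas are exact.
    Touching dots are permitted and flagged in the ground truth; the
    ground-truth count includes only dots with area >= ``min_size_px``.
    """
    ny, nx = shape_px
    rng = np.random.default_rng(seed)
    img = np.full(shape_px, float(background))
    footprints: list[np.ndarray] = []
    for (cy, cx), area in dot_spec:
        if area < 1:
            raise ValueError(f"dot area must be >= 1 px; got {area}")
        if not (0 <= cy < ny and 0 <= cx < nx):
            raise ValueError(f"dot centre ({cy}, {cx}) outside the frame")
        r = int(math.ceil(math.sqrt(area))) + 2
        yy, xx = np.mgrid[max(cy - r, 0) : min(cy + r + 1, ny), max(cx - r, 0) : min(cx + r + 1, nx)]
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        order = np.lexsort((xx.ravel(), yy.ravel(), d2.ravel()))
        take = order[:area]
        fp = np.stack([yy.ravel()[take], xx.ravel()[take]], axis=1)
        if len(fp) < area:
            raise ValueError(f"dot at ({cy}, {cx}) does not fit in the frame")
        footprints.append(fp)
        img[fp[:, 0], fp[:, 1]] = amplitude

    touching = []
    masks = []
    for fp in footprints:
        m = np.zeros(shape_px, dtype=bool)
        m[fp[:, 0], fp[:, 1]] = True
        masks.append(m)
    for i, m in enumerate(masks):
        dil = ndimage.binary_dilation(m, np.ones((3, 3), dtype=bool))
        touch = any(j != i and (dil & masks[j]).any() for j in range(len(masks)))
        touching.append(touch)

    if noise_sd > 0:
        img = np.clip(img + rng.normal(0.0, noise_sd, img.shape), 0, None)

    areas = [len(fp) for fp in footprints]
    truth = GroundTruth(
        pla_count=sum(1 for a in areas if a >= min_size_px),
        pla_areas_px=areas,
        pla_touching=touching,
    )
    return img, truth
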