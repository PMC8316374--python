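"""Sub-pixel puncta detection and accumulation thresholding.

Diffraction-limited puncta are found as band-pass-filtered local maxima and
refined by least-squares fitting of pixel-integrated 2-D Gaussians (the same
image model used by the renderer, so localization is unbiased).  When a
candidate's single-Gaussian fit leaves a structured residual, or two
candidates fall within one fit window, a two-component fit resolves
near-neighbour spots — the "multiple Gaussians" refinement.

Accumulation thresholding isolates bright foci standing above the dimmer
reticular ER-resident signal: a spatially structured background is removed by
morphological opening (a rolling-ball equivalent) before the threshold is
taken, by default as a percentile of the remaining nonzero intensities.

Coordinate convention: 0-based pixel indices, x = column, y = row, with
pixel centres at integer coordinates.  Physical positions are obtained by
multiplying with the pixel size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import least_squares
from scipy.special import erf
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops_table
from skimage.morphology import disk, opening

from .stack import ImageStack

__all__ = [
    "Detection",
    "AccumulationMask",
    "detect_spots",
    "detect_spots_frame",
    "threshold_accumulations",
    "segment_objects",
    "robust_background_sd",
]


@dataclass(frozen=True)
class Detection:
    """One fitted punctum (sub-pixel, pixel-centre convention)."""

    frame: int
    channel: int
    x_px: float
    y_px: float
    amplitude: float
    sigma_px: float
    background: float
    residual: float


@dataclass
class AccumulationMask:
    """Per-frame binary masks of bright accumulations plus the threshold used."""

    masks: np.ndarray  # (t, y, x) bool
    method: str
    level: float
    thresholds: np.ndarray  # per-frame resolved absolute threshold


def robust_background_sd(frame: np.ndarray) -> float:
    """Robust noise scale: 1.4826 x median absolute deviation from the median."""
    med = np.median(frame)
    return float(1.4826 * np.median(np.abs(frame - med)))


def _integrated_gaussian_window(
    params: np.ndarray, xs: np.ndarray, ys: np.ndarray, n_components: int
) -> np.ndarray:
    """Pixel-integrated Gaussian mixture over a window; params layout:
    [bg, (flux, x0, y0, sigma) per component]."""
    bg = params[0]
    model = np.full((len(ys), len(xs)), bg)
    for k in range(n_components):
        flux, x0, y0, sigma = params[1 + 4 * k : 5 + 4 * k]
        s2 = abs(sigma) * math.sqrt(2.0)
        gx = 0.5 * (erf((xs + 0.5 - x0) / s2) - erf((xs - 0.5 - x0) / s2))
        gy = 0.5 * (erf((ys + 0.5 - y0) / s2) - erf((ys - 0.5 - y0) / s2))
        model += flux * np.outer(gy, gx)
    return model


def _peak_factor(sigma: float) -> float:
    h = erf(0.5 / (sigma * math.sqrt(2.0)))
    return h * h


def _fit_window(
    window: np.ndarray,
    x_off: int,
    y_off: int,
    starts: list[tuple[float, float]],
    expected_sigma: float,
) -> tuple[list[tuple[float, float, float, float]], float, float]:
    """Fit 1 or 2 integrated Gaussians + flat background to a window.

    Returns (per-component (x, y, amplitude, sigma) in full-image coords,
    background, RMS residual).
    """
    ys = np.arange(window.shape[0], dtype=float)
    xs = np.arange(window.shape[1], dtype=float)
    bg0 = float(window.min())
    p0 = [bg0]
    lb = [-np.inf]
    ub = [np.inf]
    pf = _peak_factor(expected_sigma)
    for sx, sy in starts:
        amp0 = max(float(window[int(round(sy)), int(round(sx))]) - bg0, 1e-3)
        p0 += [amp0 / pf, sx, sy, expected_sigma]
        lb += [0.0, -1.0, -1.0, 0.3 * expected_sigma]
        ub += [np.inf, window.shape[1], window.shape[0], 3.0 * expected_sigma]

    def resid(p: np.ndarray) -> np.ndarray:
        return (_integrated_gaussian_window(p, xs, ys, len(starts)) - window).ravel()

    sol = least_squares(resid, p0, bounds=(lb, ub), method="trf", max_nfev=200)
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    comps = []
    for k in range(len(starts)):
        flux, x0, y0, sigma = sol.x[1 + 4 * k : 5 + 4 * k]
        sigma = abs(float(sigma))
        comps.append((float(x0) + x_off, float(y0) + y_off, float(flux) * _peak_factor(sigma), sigma))
    return comps, float(sol.x[0]), rms


def detect_spots_frame(
    frame: np.ndarray,
    min_amplitude: float | None = None,
    expected_sigma_px: float = 1.3,
    max_fit_residual: float | None = None,
    frame_index: int = 0,
    channel_index: int = 0,
) -> list[Detection]:
    """Detect puncta in a single frame.

    Candidates are local maxima of the band-pass-filtered image (difference
    of Gaussians at sigma and 3*sigma) above ``min_amplitude`` (default:
    5x the robust background sd).  Each candidate is fit in a window of
    half-width ``ceil(3.5*sigma)``; candidates sharing a window are fit
    jointly with two components, and a lone candidate whose single-component
    residual exceeds ``max_fit_residual`` is retried with a second component
    seeded at the residual maximum.
    """
    img = np.asarray(frame, dtype=float)
    if not np.isfinite(img).all():
        raise ValueError("frame contains non-finite pixels")
    if img.max() == img.min():
        return []
    noise_sd = robust_background_sd(img)
    if min_amplitude is None:
        # 5x the robust noise sd; on (near-)noiseless frames fall back to a
        # fraction of the dynamic range so flat background never triggers
        min_amplitude = max(5.0 * noise_sd, 0.1 * (img.max() - img.min()))
    if max_fit_residual is None:
        max_fit_residual = max(3.0 * noise_sd, 1e-6)

    bp = ndimage.gaussian_filter(img, expected_sigma_px) - ndimage.gaussian_filter(
        img, 3.0 * expected_sigma_px
    )
    # peak response of the DoG to a spot of width sigma and peak amplitude A
    # is A * (pf(sqrt(2) sigma) - pf(sqrt(10) sigma)) / pf(sigma)
    pf = _peak_factor
    s = expected_sigma_px
    atten = (pf(s * math.sqrt(2.0)) - pf(s * math.sqrt(10.0))) / pf(s)
    coords = peak_local_max(
        bp,
        min_distance=max(1, int(round(expected_sigma_px))),
        threshold_abs=0.5 * min_amplitude * atten,
        exclude_border=False,
    )
    if len(coords) == 0:
        return []

    half = int(math.ceil(3.5 * expected_sigma_px))
    ny, nx = img.shape
    # group candidates that fall within one fit window
    order = np.lexsort((coords[:, 1], coords[:, 0]))
    coords = coords[order]
    used = np.zeros(len(coords), dtype=bool)
    detections: list[Detection] = []
    for i in range(len(coords)):
        if used[i]:
            continue
        group = [i]
        used[i] = True
        for j in range(len(coords)):
            if used[j] or j == i:
                continue
            if (
                abs(int(coords[j, 0]) - int(coords[i, 0])) <= half
                and abs(int(coords[j, 1]) - int(coords[i, 1])) <= half
                and len(group) < 2
            ):
                group.append(j)
                used[j] = True
        cy = int(round(np.mean([coords[g, 0] for g in group])))
        cx = int(round(np.mean([coords[g, 1] for g in group])))
        y0, y1 = max(cy - half, 0), min(cy + half + 1, ny)
        x0, x1 = max(cx - half, 0), min(cx + half + 1, nx)
        window = img[y0:y1, x0:x1]
        starts = [(float(coords[g, 1] - x0), float(coords[g, 0] - y0)) for g in group]
        comps, bg, rms = _fit_window(window, x0, y0, starts, expected_sigma_px)
        if len(starts) == 1 and rms > max_fit_residual:
            # structured residual: look for a secondary maximum and refit
            model = _integrated_gaussian_window(
                np.array([bg, comps[0][2] / _peak_factor(comps[0][3]), comps[0][0] - x0, comps[0][1] - y0, comps[0][3]]),
                np.arange(window.shape[1], dtype=float),
                np.arange(window.shape[0], dtype=float),
                1,
            )
            res_img = window - model
            ry, rx = np.unravel_index(int(np.argmax(res_img)), res_img.shape)
            if res_img[ry, rx] > 0.5 * min_amplitude:
                comps2, bg2, rms2 = _fit_window(
                    window, x0, y0, starts + [(float(rx), float(ry))], expected_sigma_px
                )
                if rms2 < rms:
                    comps, bg, rms = comps2, bg2, rms2
        for x, y, amp, sigma in comps:
            if amp < min_amplitude or not (0 <= x < nx and 0 <= y < ny):
                continue
            detections.append(
                Detection(frame_index, channel_index, x, y, amp, sigma, bg, rms)
            )
    detections.sort(key=lambda d: (d.y_px, d.x_px))
    return detections


def detect_spots(
    stack: ImageStack,
    channel: int | str,
    min_amplitude: float | None = None,
    expected_sigma_px: float = 1.3,
    max_fit_residual: float | None = None,
) -> pd.DataFrame:
    """Detect puncta in every frame of one channel of a stack.

    Returns a table with columns frame, channel, x_px, y_px, x_um, y_um,
    amplitude, sigma_px, background, residual.
    """
    c = stack.channel_index(channel)
    rows = []
    for t in range(stack.n_frames):
        for d in detect_spots_frame(
            stack.data[t, c],
            min_amplitude=min_amplitude,
            expected_sigma_px=expected_sigma_px,
            max_fit_residual=max_fit_residual,
            frame_index=t,
            channel_index=c,
        ):
            rows.append(
                (
                    d.frame,
                    d.channel,
                    d.x_px,
                    d.y_px,
                    d.x_px * stack.pixel_size_um,
                    d.y_px * stack.pixel_size_um,
                    d.amplitude,
                    d.sigma_px,
                    d.background,
                    d.residual,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "frame",
            "channel",
            "x_px",
            "y_px",
            "x_um",
            "y_um",
            "amplitude",
            "sigma_px",
            "background",
            "residual",
        ],
    )


def threshold_accumulations(
    frames: np.ndarray | ImageStack,
    channel: int | str | None = None,
    method: str = "percentile",
    level: float = 99.0,
    opening_radius_px: int = 6,
) -> AccumulationMask:
    """Binary masks of bright accumulations standing above the reticular signal.

    The spatially structured background is estimated per frame by greyscale
    opening with a disk of ``opening_radius_px`` and subtracted; the
    threshold is then applied to the residual image:

    - ``percentile``: ``level``-th percentile of the positive residual
      intensities (level in (0, 100));
    - ``otsu``: Otsu's threshold of the residual;
    - ``absolute``: ``level`` as an absolute intensity on the raw frame.
    """
    if isinstance(frames, ImageStack):
        if channel is None:
            raise ValueError("channel required when passing an ImageStack")
        arr = frames.data[:, frames.channel_index(channel)]
    else:
        arr = np.asarray(frames, dtype=float)
        if arr.ndim == 2:
            arr = arr[None]
    if method not in ("percentile", "otsu", "absolute"):
        raise ValueError(f"unknown threshold method {method!r}")
    if method == "percentile" and not 0 < level < 100:
        raise ValueError("percentile level must lie in (0, 100)")
    if method == "absolute" and level < 0:
        raise ValueError("absolute level must be >= 0")

    masks = np.zeros(arr.shape, dtype=bool)
    thresholds = np.zeros(arr.shape[0])
    selem = disk(opening_radius_px)
    for t in range(arr.shape[0]):
        frame = arr[t]
        if method == "absolute":
            thr = level
            masks[t] = frame > thr
        else:
            residual = frame - opening(frame, selem)
            if method == "percentile":
                positive = residual[residual > 0]
                thr = float(np.percentile(positive, level)) if positive.size else np.inf
            else:
                if frame.max() == frame.min():
                    raise ValueError("degenerate (constant) channel for Otsu threshold")
                thr = float(threshold_otsu(residual))
            masks[t] = residual > thr
        thresholds[t] = thr
    return AccumulationMask(masks, method, level, thresholds)


def segment_objects(mask: np.ndarray) -> tuple[np.ndarray, pd.DataFrame]:
    """8-connected labelling of a binary mask with a centroid/area table."""
    m = np.asarray(mask, dtype=bool)
    labels = sk_label(m, connectivity=2)
    if labels.max() == 0:
        return labels, pd.DataFrame(columns=["label", "centroid_y", "centroid_x", "area_px"])
    props = regionprops_table(labels, properties=("label", "centroid", "area"))
    table = pd.DataFrame(
        {
            "label": props["label"],
            "centroid_y": props["centroid-0"],
            "centroid_x": props["centroid-1"],
            "area_px": props["area"].astype(int),
        }
    ).sort_values("label", ignore_index=True)
    return labels, table
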