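"""Radial shell analysis of endolysosome dispersal.

A cell mask is partitioned into five concentric shells by iteratively
shrinking the outline inward in 2 µm steps: shell 5 is the outermost 2 µm
band, shell 1 the perinuclear remainder.  The peripheral fraction is the
thresholded organelle signal in shells 3-5 divided by the signal over the
whole cell; in wild-type cells most lysosomes sit in shells 1-2, so this
fraction rises when endolysosomes disperse toward the cell edge.

The inward shrinking is implemented with a Euclidean distance transform
rather than iterated binary erosion, so the 2 µm band edges are accurate to
the pixel grid regardless of structuring-element shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["ShellMap", "DispersalResult", "build_shells", "peripheral_fraction"]


@dataclass
class ShellMap:
    """Label image of concentric shells: 0 outside the cell, 1..n_shells inside.

    Shell 1 is the innermost (perinuclear) region; shell ``n_shells`` touches
    the mask boundary.  Shell ``k`` (for k >= 2) holds pixels whose Euclidean
    distance to the cell boundary lies in ``((n-k)*step, (n-k+1)*step]`` µm;
    shell 1 absorbs all remaining interior pixels.
    """

    labels: np.ndarray
    step_um: float
    pixel_size_um: float
    n_shells: int = 5
    qc_flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def cell_mask(self) -> np.ndarray:
        return self.labels > 0

    def shell_mask(self, k: int) -> np.ndarray:
        if not 1 <= k <= self.n_shells:
            raise ValueError(f"shell id {k} out of range 1..{self.n_shells}")
        return self.labels == k


@dataclass
class DispersalResult:
    """Peripheral-dispersal statistic for one cell."""

    cell_id: str
    signal_per_shell: np.ndarray  # index 0 = shell 1
    qc_flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def total_signal(self) -> float:
        return float(self.signal_per_shell.sum())

    @property
    def peripheral_signal(self) -> float:
        # outer three shells (shells 3-5 of 5)
        return float(self.signal_per_shell[2:].sum())

    @property
    def fraction(self) -> float:
        return self.peripheral_signal / self.total_signal


def _boundary_distance_um(mask: np.ndarray, pixel_size_um: float) -> np.ndarray:
    """Distance from each interior pixel centre to the mask outline, in µm.

    The Euclidean distance transform measures centre-to-centre distance to the
    nearest background pixel; the mask outline runs along pixel edges, half a
    pixel closer, so half a pixel is subtracted (floored at 0).
    """
    edt = ndimage.distance_transform_edt(mask)
    return np.maximum(edt - 0.5, 0.0) * pixel_size_um


def build_shells(
    cell_mask: np.ndarray,
    pixel_size_um: float,
    step_um: float = 2.0,
    n_shells: int = 5,
) -> ShellMap:
    """Partition a single-cell mask into ``n_shells`` concentric bands.

    Parameters
    ----------
    cell_mask
        Boolean mask of one cell (a single connected component).
    pixel_size_um
        Pixel size in µm.
    step_um
        Width of each band (default 2 µm).
    n_shells
        Number of shells (default 5).

    Returns
    -------
    ShellMap
        Shells 1..n partitioning the mask exactly.  If the cell is too thin
        for the innermost shell(s) to be non-empty, the map is still returned
        with a ``thin-cell`` QC flag instead of raising.
    """
    mask = np.asarray(cell_mask, dtype=bool)
    if not mask.any():
        raise ValueError("cell mask is empty")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    _, n_comp = ndimage.label(mask)
    if n_comp != 1:
        raise ValueError(f"cell mask must be a single connected component; got {n_comp}")

    dist = _boundary_distance_um(mask, pixel_size_um)
    labels = np.zeros(mask.shape, dtype=np.uint8)
    # shell n (outermost): dist in [0, step]; shell k: ((n-k)*step, (n-k+1)*step]
    # shell 1 absorbs everything deeper than (n-1)*step.
    for k in range(n_shells, 1, -1):
        lo = (n_shells - k) * step_um
        hi = lo + step_um
        band = mask & (dist > lo if k < n_shells else dist >= 0) & (dist <= hi)
        labels[band] = k
    labels[mask & (dist > (n_shells - 1) * step_um)] = 1

    flags: list[str] = []
    empty = [k for k in range(1, n_shells + 1) if not (labels == k).any()]
    if empty:
        flags.append("empty-shell:" + ",".join(map(str, empty)))
    if dist.max() <= (n_shells - 1) * step_um:
        flags.append("thin-cell")
    return ShellMap(labels, step_um, pixel_size_um, n_shells, tuple(flags))


def peripheral_fraction(
    intensity: np.ndarray,
    shells: ShellMap,
    background_threshold: float = 0.0,
    cell_id: str = "cell",
    measure: str = "intensity",
) -> DispersalResult:
    """Fraction of organelle signal in the outer three shells.

    A background threshold is applied first (pixels at or below it contribute
    nothing), mirroring thresholding away camera background before measuring
    total cellular signal.

    Parameters
    ----------
    intensity
        Intensity image, same shape as the shell map.
    shells
        Output of :func:`build_shells`.
    background_threshold
        Intensities <= this value are zeroed before summation.
    measure
        ``"intensity"`` sums thresholded intensities per shell;
        ``"area"`` counts suprathreshold pixels instead.

    Raises
    ------
    ValueError
        If shapes mismatch or the total suprathreshold signal is zero, in
        which case the fraction is undefined.
    """
    img = np.asarray(intensity, dtype=float)
    if img.shape != shells.labels.shape:
        raise ValueError(
            f"intensity shape {img.shape} != shell map shape {shells.labels.shape}"
        )
    if measure not in ("intensity", "area"):
        raise ValueError(f"unknown measure {measure!r}")
    above = img > background_threshold
    signal = img * above if measure == "intensity" else above.astype(float)
    sums = ndimage.sum_labels(
        signal, shells.labels, index=np.arange(1, shells.n_shells + 1)
    )
    sums = np.asarray(sums, dtype=float)
    if sums.sum() <= 0:
        raise ValueError(
            "total signal after thresholding is zero; peripheral fraction undefined"
        )
    return DispersalResult(cell_id, sums, shells.qc_flags)
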