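"""Reading and writing the pipeline's file formats.

Movies travel as multi-page TIFF in ``(t, c, y, x)`` order with a JSON
sidecar (``<stem>.json``) holding the physical calibration, channel names
and generator seed; calibration is never defaulted silently — a stack
without a sidecar requires explicit overrides.  Tables are plain CSV, EM
contour sets the flat vertex table defined in :mod:`eltether.em`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .em import EMContourSet
from .stack import ImageStack

__all__ = ["read_stack", "write_stack", "read_em_csv", "write_em_csv"]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_stack(stack: ImageStack, path: str | Path, seed: int | None = None) -> None:
    """Write a stack as 16-bit TIFF plus a JSON calibration sidecar."""
    path = Path(path)
    data = stack.data
    if data.max() > np.iinfo(np.uint16).max:
        raise ValueError("intensities exceed the 16-bit range")
    tifffile.imwrite(path, np.round(data).astype(np.uint16), metadata={"axes": "TCYX"})
    sidecar = {
        "pixel_size_um": stack.pixel_size_um,
        "frame_interval_s": stack.frame_interval_s,
        "channel_names": list(stack.channel_names),
    }
    if seed is not None:
        sidecar["seed"] = int(seed)
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))


def read_stack(
    path: str | Path,
    pixel_size_um: float | None = None,
    frame_interval_s: float | None = None,
    channel_names: tuple[str, ...] | None = None,
) -> ImageStack:
    """Read a TIFF stack, normalizing axes to ``(t, c, y, x)``.

    Calibration comes from the JSON sidecar when present; explicit arguments
    override it.  A stack with neither sidecar nor overrides raises — the
    physical calibration is required, never silently defaulted.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        axes = tf.series[0].axes if tf.series else ""
    if data.dtype.kind not in "uif":
        raise ValueError(f"unsupported TIFF sample type {data.dtype}")
    data = np.asarray(data, dtype=float)

    if data.ndim == 2:  # single still, single channel
        data = data[None, None]
    elif data.ndim == 3:
        # 'CYX' means a multi-channel still; anything else is a single-channel stack
        if axes.upper().startswith("C"):
            data = data[None, :, :, :]
        else:
            data = data[:, None, :, :]
    elif data.ndim == 4:
        if axes and axes.upper() not in ("TCYX", "ZCYX", "QCYX"):
            raise ValueError(
                f"ambiguous 4-D TIFF axes {axes!r}; expected (t, c, y, x) order"
            )
    else:
        raise ValueError(f"cannot interpret TIFF with {data.ndim} dimensions")

    sidecar = _sidecar_path(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    dt = frame_interval_s if frame_interval_s is not None else meta.get("frame_interval_s")
    names = channel_names if channel_names is not None else meta.get("channel_names")
    if px is None:
        raise ValueError(f"no pixel size for {path.name}: provide a sidecar or an override")
    if dt is None:
        if data.shape[0] > 1:
            raise ValueError(
                f"no frame interval for multi-frame stack {path.name}: "
                "provide a sidecar or an override"
            )
        dt = 0.0
    return ImageStack(data, float(px), float(dt), tuple(names) if names else ())


def write_em_csv(contours: EMContourSet, path: str | Path) -> None:
    contours.to_frame().to_csv(path, index=False)


def read_em_csv(path: str | Path, section_thickness_nm: float = 50.0) -> EMContourSet:
    return EMContourSet.from_frame(pd.read_csv(path), section_thickness_nm)
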