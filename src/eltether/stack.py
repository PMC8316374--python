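"""Calibrated multi-channel image stacks.

The in-memory container for every image-based analysis in this package is a
``(t, c, y, x)`` array with physical calibration attached: pixel size in
micrometres and frame interval in seconds.  Still images are stacks with a
single time point; z-stacks reuse the same layout with the first axis read as
z (slice) instead of t.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageStack"]


@dataclass
class ImageStack:
    """A calibrated ``(t, c, y, x)`` intensity array.

    Parameters
    ----------
    data
        Non-negative, finite intensities indexed ``(t, c, y, x)``.
    pixel_size_um
        Lateral pixel size in micrometres (must be positive).
    frame_interval_s
        Time between consecutive frames in seconds.  Required to be positive
        whenever the stack has more than one frame; a still image may carry 0.
    channel_names
        One name per channel, e.g. ``("EL", "SNX19")``.
    """

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    channel_names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"ImageStack data must be (t, c, y, x); got shape {self.data.shape}"
            )
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"all dimensions must be >= 1; got {self.data.shape}")
        if not np.isfinite(self.data).all():
            raise ValueError("ImageStack intensities must be finite")
        if self.data.min() < 0:
            raise ValueError("ImageStack intensities must be >= 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.n_frames > 1 and self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0 for multi-frame stacks")
        if self.frame_interval_s < 0:
            raise ValueError("frame_interval_s must be >= 0")
        if not self.channel_names:
            self.channel_names = tuple(f"ch{i}" for i in range(self.n_channels))
        else:
            self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.n_channels:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.n_channels} channels"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def channel_index(self, channel: int | str) -> int:
        """Resolve a channel given by index or name to its index."""
        if isinstance(channel, str):
            try:
                return self.channel_names.index(channel)
            except ValueError:
                raise KeyError(
                    f"channel {channel!r} not in {self.channel_names}"
                ) from None
        c = int(channel)
        if not 0 <= c < self.n_channels:
            raise KeyError(f"channel index {c} out of range [0, {self.n_channels})")
        return c

    def frame(self, t: int, channel: int | str) -> np.ndarray:
        """Return a single ``(y, x)`` frame."""
        return self.data[t, self.channel_index(channel)]
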