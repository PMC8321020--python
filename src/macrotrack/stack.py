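"""In-memory container for a two-channel time-lapse image stack."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: default acquisition metadata for the spinning-disk movies this package
#: was written for: one frame every 10 s, 0.21 um square pixels.
DEFAULT_FRAME_INTERVAL = 10.0
DEFAULT_PIXEL_SIZE = 0.21

DEFAULT_CHANNEL_MAP = {"red": 0, "green": 1}


@dataclass
class FrameStack:
    """Ordered image frames plus acquisition metadata.

    Parameters
    ----------
    frames:
        Array of shape ``(n_frames, rows, cols, channels)``.  The red channel
        carries the nuclear label, the green channel the microtubule label;
        which index is which is recorded in ``channel_map``.
    frame_interval:
        Seconds between consecutive frames.
    pixel_size:
        Lateral pixel size in micrometres.
    """

    frames: np.ndarray
    frame_interval: float = DEFAULT_FRAME_INTERVAL
    pixel_size: float = DEFAULT_PIXEL_SIZE
    channel_map: dict = field(default_factory=lambda: dict(DEFAULT_CHANNEL_MAP))

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4:
            raise ValueError(
                "frames must be a (n_frames, rows, cols, channels) array, "
                f"got shape {self.frames.shape}"
            )
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        """(rows, cols) of every frame."""
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def n_channels(self) -> int:
        return self.frames.shape[3]

    def channel(self, name_or_index) -> np.ndarray:
        """All frames of one channel, by role name ('red'/'green') or index."""
        if isinstance(name_or_index, str):
            idx = self.channel_map[name_or_index]
        else:
            idx = int(name_or_index)
        return self.frames[..., idx]

    def frame(self, t: int) -> np.ndarray:
        return self.frames[t]
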