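"""Multi-channel time-lapse stack container and TIFF round-trip.

Movies are stored as multi-page TIFF, frame-major with channels interleaved
(frame 0 channel 0, frame 0 channel 1, ...), float32, with acquisition
metadata (channel roles, pixel size, frame interval) serialized as JSON in
the image description so a written stack reads back losslessly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ChannelStack", "read_stack", "write_stack"]

DEFAULT_CHANNELS = ("clathrin", "P", "S", "dynamin")


@dataclass
class ChannelStack:
    """Time-ordered multi-channel image stack.

    ``frames`` has shape (T, C, H, W); ``channels`` names each channel role
    in order (e.g. clathrin, P, S, dynamin); ``pixel_size`` is in nm and
    ``frame_interval`` in seconds.
    """

    frames: np.ndarray
    channels: tuple[str, ...]
    pixel_size: float
    frame_interval: float = 2.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4:
            raise ValueError("frames must have shape (T, C, H, W)")
        if self.frames.shape[1] != len(self.channels):
            raise ValueError(
                f"{self.frames.shape[1]} channel planes but "
                f"{len(self.channels)} channel names"
            )
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")
        self.channels = tuple(self.channels)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.frames.shape

    def channel(self, name: str) -> np.ndarray:
        """(T, H, W) view of one named channel."""
        try:
            idx = self.channels.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}; have {self.channels}") from None
        return self.frames[:, idx]


def write_stack(stack: ChannelStack, path: str | Path) -> None:
    """Write a stack as frame-major channel-interleaved float32 multi-page TIFF."""
    t, c, h, w = stack.frames.shape
    pages = stack.frames.reshape(t * c, h, w).astype(np.float32)
    meta = {
        "polcurve": {
            "channels": list(stack.channels),
            "pixel_size_nm": stack.pixel_size,
            "frame_interval_s": stack.frame_interval,
            "n_frames": t,
        }
    }
    tifffile.imwrite(
        path, pages, description=json.dumps(meta), photometric="minisblack"
    )


def read_stack(
    path: str | Path, channels: tuple[str, ...] | None = None
) -> ChannelStack:
    """Read a multi-page TIFF into a ChannelStack.

    If the file carries polcurve metadata it is used; otherwise ``channels``
    must be given and the page count must divide evenly by the channel count.
    """
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        desc = tif.pages[0].description or ""
    meta = None
    if desc:
        try:
            meta = json.loads(desc).get("polcurve")
        except (json.JSONDecodeError, AttributeError):
            meta = None
    if meta is not None:
        channels = tuple(meta["channels"])
        pixel_size = float(meta["pixel_size_nm"])
        frame_interval = float(meta["frame_interval_s"])
    else:
        if channels is None:
            raise ValueError("TIFF has no polcurve metadata; pass channels explicitly")
        pixel_size, frame_interval = 1.0, 1.0
    if pages.ndim == 2:
        pages = pages[None]
    n_c = len(channels)
    if pages.shape[0] % n_c:
        raise ValueError(
            f"page count {pages.shape[0]} not divisible by {n_c} channels"
        )
    t = pages.shape[0] // n_c
    frames = pages.reshape(t, n_c, *pages.shape[1:]).astype(np.float64)
    return ChannelStack(frames, channels, pixel_size, frame_interval)
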