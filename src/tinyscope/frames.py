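"""Core image containers shared by every analysis module.

A :class:`Frame` is a 2-D grayscale or RGB intensity grid plus the sensor
bit depth and free-form acquisition metadata (exposure time, timestamp,
axial position, ...).  :class:`FocusStack` and :class:`TimelapseSeries`
are thin ordered collections of frames with the invariants the analysis
code relies on (monotonic z, increasing timestamps, matching shapes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

# Rec. 709 luminance weights for RGB -> gray conversion.
LUMA_WEIGHTS = np.array([0.2126, 0.7152, 0.0722])


@dataclass
class Frame:
    """A single camera frame.

    Parameters
    ----------
    pixels
        ``(H, W)`` grayscale or ``(H, W, 3)`` RGB array with values in
        ``[0, 2**bit_depth - 1]``.
    bit_depth
        Sensor quantization depth (8 for the OV2640-class sensors this
        toolkit targets; 16 supported for processed data).
    metadata
        Free-form acquisition metadata.  Keys used by the toolkit:
        ``exposure_ms``, ``timestamp_s``, ``z_position_um``.
    """

    pixels: np.ndarray
    bit_depth: int = 8
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.size == 0:
            raise ValueError("frame must be non-empty")
        if self.pixels.ndim not in (2, 3) or (
            self.pixels.ndim == 3 and self.pixels.shape[2] != 3
        ):
            raise ValueError(
                f"frame must be 2-D grayscale or (H, W, 3) RGB, got shape "
                f"{self.pixels.shape}"
            )
        if self.bit_depth < 1:
            raise ValueError("bit_depth must be >= 1")
        lo = float(np.min(self.pixels))
        hi = float(np.max(self.pixels))
        if lo < 0 or hi > self.max_value:
            raise ValueError(
                f"pixel values [{lo}, {hi}] outside [0, {self.max_value}] "
                f"for bit depth {self.bit_depth}"
            )

    @property
    def max_value(self) -> float:
        return float(2**self.bit_depth - 1)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape

    @property
    def is_rgb(self) -> bool:
        return self.pixels.ndim == 3

    def luminance(self) -> np.ndarray:
        """Return the frame as a 2-D float array (Rec. 709 weights for RGB)."""
        px = self.pixels.astype(float)
        if px.ndim == 2:
            return px
        return px @ LUMA_WEIGHTS

    def to_uint8(self) -> np.ndarray:
        """Rescale to 8 bits (for codecs that only accept 8-bit input)."""
        if self.bit_depth == 8:
            return np.asarray(np.round(self.pixels), dtype=np.uint8)
        scaled = self.pixels.astype(float) * (255.0 / self.max_value)
        return np.asarray(np.round(scaled), dtype=np.uint8)


@dataclass
class FocusStack:
    """Frames ordered by lens/stage axial position.

    ``entries`` is an ordered list of ``(z_position_um, Frame)``; z must be
    strictly monotonic and all frames must share one shape.
    """

    entries: list[tuple[float, Frame]]

    def __post_init__(self) -> None:
        if len(self.entries) < 2:
            raise ValueError("focus stack needs at least 2 entries")
        z = np.array([e[0] for e in self.entries], dtype=float)
        dz = np.diff(z)
        if not (np.all(dz > 0) or np.all(dz < 0)):
            raise ValueError("z positions must be strictly monotonic")
        shapes = {e[1].pixels.shape for e in self.entries}
        if len(shapes) != 1:
            raise ValueError(f"all frames must share one shape, got {shapes}")

    @property
    def z_positions(self) -> np.ndarray:
        return np.array([e[0] for e in self.entries], dtype=float)

    @property
    def frames(self) -> list[Frame]:
        return [e[1] for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def reversed(self) -> "FocusStack":
        return FocusStack(list(self.entries)[::-1])


@dataclass
class TimelapseSeries:
    """An ordered timelapse: frames plus timestamps in seconds since start."""

    frames: list[Frame]
    timestamps: Sequence[float]

    def __post_init__(self) -> None:
        if len(self.frames) < 2:
            raise ValueError("timelapse needs at least 2 frames")
        if len(self.frames) != len(self.timestamps):
            raise ValueError("one timestamp per frame required")
        t = np.asarray(self.timestamps, dtype=float)
        if not np.all(np.diff(t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        shapes = {f.pixels.shape for f in self.frames}
        if len(shapes) != 1:
            raise ValueError(f"all frames must share one shape, got {shapes}")
        self.timestamps = t

    def __len__(self) -> int:
        return len(self.frames)
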