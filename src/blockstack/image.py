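"""8-bit RGB raster with a physical pixel size.

Coordinate convention used throughout the package: pixel centers sit at
integer coordinates, origin at the top-left pixel, x rightward, y downward,
0-based.  A continuous pixel coordinate u corresponds to the physical
position (u + 0.5) · pixel_size_mm from the image edge.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image


def quantize_u8(arr: np.ndarray) -> np.ndarray:
    """Round half up and clip to [0, 255], returning uint8."""
    return np.clip(np.floor(np.asarray(arr, dtype=np.float64) + 0.5), 0, 255).astype(np.uint8)


@dataclass
class RasterImage:
    """A 2D RGB raster with 8-bit channels and square pixels of known physical size."""

    pixels: np.ndarray  # H x W x 3, uint8
    pixel_size_mm: float

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"pixels must be H x W x 3, got shape {self.pixels.shape}")
        if self.pixels.dtype != np.uint8:
            raise ValueError(f"pixels must be uint8, got {self.pixels.dtype}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must have at least one row and one column")
        if not self.pixel_size_mm > 0:
            raise ValueError(f"pixel_size_mm must be > 0, got {self.pixel_size_mm}")
        self.pixel_size_mm = float(self.pixel_size_mm)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def dims(self) -> tuple[int, int]:
        """(width, height) in pixels."""
        return (self.width, self.height)

    def copy(self) -> "RasterImage":
        return RasterImage(self.pixels.copy(), self.pixel_size_mm)

    def to_file(self, path: str | Path) -> None:
        """Write as PNG/JPEG depending on suffix (PNG is lossless and preferred)."""
        Image.fromarray(self.pixels).save(str(path))

    @classmethod
    def from_file(cls, path: str | Path, pixel_size_mm: float) -> "RasterImage":
        with Image.open(str(path)) as im:
            arr = np.asarray(im.convert("RGB"))
        return cls(arr.copy(), pixel_size_mm)
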