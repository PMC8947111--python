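"""Image containers and file I/O.

Grayscale rasters become :class:`GrayImage` (float pixels on [0, 1]; 16-bit
inputs are divided by 65535, 8-bit by 255), three-channel rasters become
:class:`RgbImage`.  The physical calibration (``um_per_px``) travels with the
image.  TIFF is read/written through :mod:`tifffile`, PNG through
:mod:`imageio`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile


@dataclass
class GrayImage:
    """2-D intensity raster on [0, 1] with optional μm/pixel calibration."""

    pixels: np.ndarray
    um_per_px: float | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("GrayImage requires a 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("GrayImage contains non-finite values")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("GrayImage values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class RgbImage:
    """(h, w, 3) raster on [0, 1], channel order red, green, blue."""

    pixels: np.ndarray
    um_per_px: float | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[-1] != 3:
            raise ValueError("RgbImage requires an (h, w, 3) array")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("RgbImage values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


def _to_unit_float(arr: np.ndarray) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    arr = arr.astype(float)
    return np.clip(arr, 0.0, 1.0)


def read_image(path, um_per_px: float | None = None) -> GrayImage | RgbImage:
    """Load a TIFF/PNG as a GrayImage (2-D) or RgbImage (3-channel)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(iio.imread(path))
    if arr.ndim == 3 and arr.shape[-1] == 4:  # drop alpha
        arr = arr[..., :3]
    data = _to_unit_float(arr)
    if data.ndim == 2:
        return GrayImage(data, um_per_px)
    if data.ndim == 3 and data.shape[-1] == 3:
        return RgbImage(data, um_per_px)
    raise ValueError(f"unsupported image layout {arr.shape} in {path}")


def write_image(path, image) -> None:
    """Write a GrayImage/RgbImage or raw array.  TIFF grayscale is saved as
    16-bit, everything else as 8-bit."""
    path = Path(path)
    arr = image.pixels if isinstance(image, (GrayImage, RgbImage)) else np.asarray(image)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        if arr.ndim == 2:
            tifffile.imwrite(path, np.round(np.clip(arr, 0, 1) * 65535).astype(np.uint16))
        else:
            tifffile.imwrite(path, np.round(np.clip(arr, 0, 1) * 255).astype(np.uint8))
    else:
        iio.imwrite(path, np.round(np.clip(arr, 0, 1) * 255).astype(np.uint8))


def write_label_map(path, labels) -> None:
    """Persist a label map losslessly as 16-bit TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(labels).astype(np.uint16))
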