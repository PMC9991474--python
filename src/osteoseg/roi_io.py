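"""Raster image I/O, grayscale conversion, and fixed-size ROI extraction.

Periapical radiographs arrive as BMP (often indexed-color) or PNG rasters.
The analysis operates on a fixed 300x400-pixel region of interest (ROI)
placed in the trabecular area; the ROI window is anchored at its top-left
corner, uses 0-based (row, col) coordinates, and is half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

#: Default ROI geometry used throughout the pipeline.
ROI_HEIGHT = 300
ROI_WIDTH = 400


class RoiError(ValueError):
    """Raised when an ROI window does not fit inside its source image."""


@dataclass(frozen=True)
class RoiSpec:
    """A rectangular window: top-left corner (0-based) plus height and width."""

    start_row: int
    start_col: int
    height: int = ROI_HEIGHT
    width: int = ROI_WIDTH

    def __post_init__(self) -> None:
        if self.start_row < 0 or self.start_col < 0:
            raise RoiError(
                f"ROI start must be nonnegative, got ({self.start_row}, {self.start_col})"
            )
        if self.height < 1 or self.width < 1:
            raise RoiError(f"ROI size must be positive, got {self.height}x{self.width}")


@dataclass
class RoiImage:
    """A single-channel 0-255 intensity grid with provenance metadata."""

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        pix = np.asarray(self.pixels)
        if pix.ndim != 2:
            raise ValueError(f"RoiImage expects a 2-D grid, got shape {pix.shape}")
        if pix.size == 0:
            raise ValueError("RoiImage must contain at least one pixel")
        if pix.min() < 0 or pix.max() > 255:
            raise ValueError("RoiImage intensities must lie in [0, 255]")
        self.pixels = pix.astype(np.uint8)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_pixels(self) -> int:
        return self.pixels.size


def read_image(path: str | Path) -> np.ndarray:
    """Decode a BMP or PNG image losslessly.

    Grayscale images come back as a 2-D uint8 array; color images as HxWx3
    RGB.  Indexed-color (palette) images are resolved through their palette
    to RGB so no intensity information is silently remapped.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            if im.mode == "P":
                im = im.convert("RGB")
            elif im.mode not in ("L", "RGB"):
                im = im.convert("RGB" if ("A" in im.mode or len(im.getbands()) > 1) else "L")
            arr = np.asarray(im)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - wrap decoder errors with the path
        raise OSError(f"cannot read image {path}: {exc}") from exc
    return arr


def write_image(image: RoiImage | np.ndarray, path: str | Path) -> None:
    """Write a grayscale or RGB array as 8-bit BMP or PNG (by extension)."""
    arr = image.pixels if isinstance(image, RoiImage) else np.asarray(image, dtype=np.uint8)
    Image.fromarray(arr).save(Path(path))


# ITU-R BT.601 luma weights; the conversion rule must be fixed so that
# feature vectors are comparable across images.
_BT601 = np.array([0.299, 0.587, 0.114])


def to_grayscale(image: np.ndarray | RoiImage, source_id: str = "") -> RoiImage:
    """Convert a decoded image to a single-channel 0-255 RoiImage.

    Already-grayscale input passes through unchanged.  RGB input is reduced
    with BT.601 luma weights (0.299, 0.587, 0.114), rounded half-up.
    """
    if isinstance(image, RoiImage):
        return RoiImage(image.pixels, source_id=source_id or image.source_id)
    arr = np.asarray(image)
    if arr.ndim == 2:
        return RoiImage(arr, source_id=source_id)
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        luma = arr[..., :3].astype(np.float64) @ _BT601
        return RoiImage(np.clip(np.floor(luma + 0.5), 0, 255), source_id=source_id)
    raise ValueError(f"unsupported image shape {arr.shape}")


def extract_roi(image: np.ndarray | RoiImage, spec: RoiSpec, source_id: str = "") -> RoiImage:
    """Extract the half-open window ``[start_row, start_row+height) x [start_col, ...)``.

    Raises :class:`RoiError` with the offending coordinates if the window
    does not fit inside the image.
    """
    arr = image.pixels if isinstance(image, RoiImage) else np.asarray(image)
    h, w = arr.shape[:2]
    end_row = spec.start_row + spec.height
    end_col = spec.start_col + spec.width
    if end_row > h or end_col > w:
        raise RoiError(
            f"ROI window rows [{spec.start_row}, {end_row}) x cols [{spec.start_col}, {end_col}) "
            f"exceeds image of size {h}x{w}"
        )
    window = arr[spec.start_row : end_row, spec.start_col : end_col]
    if window.ndim == 3:
        return to_grayscale(window, source_id=source_id)
    return RoiImage(window, source_id=source_id)
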