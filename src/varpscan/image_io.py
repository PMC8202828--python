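"""Reading specimen images and normalizing them to 8-bit grayscale.

Digitization stations produce JPEG/PNG/TIFF files, frequently RGB and
frequently carrying an EXIF orientation tag; everything downstream works on a
single-channel 8-bit raster, so this module is the only place pixel formats
are negotiated.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from PIL import Image, ImageOps


@dataclasses.dataclass(frozen=True)
class GrayImage:
    """An 8-bit grayscale raster.

    Row index is y (increasing downward), column index is x (increasing
    rightward), matching the usual raster convention.
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"GrayImage requires a 2-D array, got shape {px.shape}")
        if px.size == 0:
            raise ValueError("zero-area image")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def smaller_dim(self) -> int:
        """min(height, width); governs the proposal-vector extension rule."""
        return min(self.pixels.shape)


def _to_gray(arr: np.ndarray) -> np.ndarray:
    """BT.601 luma with round-half-away-from-zero, as 8-bit."""
    if arr.ndim == 2:
        return arr.astype(np.uint8)
    rgb = arr[..., :3].astype(np.float64)
    luma = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
    # np.round ties to even; luma of integer inputs never lands exactly on .5
    # except for pure grays, where both conventions agree, but floor(x+0.5)
    # pins the convention down regardless.
    return np.floor(luma + 0.5).astype(np.uint8)


def load_grayscale(path: str | Path) -> GrayImage:
    """Read a JPEG/PNG/TIFF raster and return it as 8-bit grayscale.

    RGB inputs are converted with BT.601 luma weights (0.299R + 0.587G +
    0.114B, rounded half away from zero); already-gray inputs pass through
    unchanged.  An EXIF orientation tag, if present, is applied first so the
    physical layout of the sheet is what downstream geometry sees.  16-bit
    inputs are reduced to 8-bit by right shift.

    Raises
    ------
    OSError
        If the file is missing or not a decodable raster (message names the
        path).
    ValueError
        If the decoded image has zero area.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im = ImageOps.exif_transpose(im)
            arr = np.asarray(im)
    except (OSError, SyntaxError) as exc:
        raise OSError(f"cannot read image file {path}: {exc}") from exc
    if arr.size == 0:
        raise ValueError(f"zero-area image: {path}")
    if arr.dtype == np.uint16:
        arr = (arr >> 8).astype(np.uint8)
    elif arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    elif arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]
    return GrayImage(_to_gray(arr))


def save_grayscale(image: GrayImage, path: str | Path) -> None:
    """Write the raster as a single-channel file (PNG/TIFF are lossless)."""
    Image.fromarray(image.pixels, mode="L").save(Path(path))
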