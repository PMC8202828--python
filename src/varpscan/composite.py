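"""Sampling pixels along proposal vectors into the composite image.

Each proposal vector is rasterized with 8-connected Bresenham traversal and
the intensities it crosses become one *column* of a small composite matrix:
width = number of vectors, height = longest scanline, shorter columns padded
with white below.  Differently angled scanlines end up sharing a single
vertical axis, which is what lets a purely column-wise decoder read barcodes
at any original orientation — and the composite is a tiny fraction of the
source image's pixels.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from skimage.draw import line as _bresenham_line

from .contour_proposals import ProposalVector
from .image_io import GrayImage, save_grayscale

__all__ = ["CompositeImage", "sample_line", "build_composite", "resolution_reduction"]

PAD_VALUE = 255  # white: a quiet zone can only terminate a symbol, never fabricate one


@dataclasses.dataclass(frozen=True)
class CompositeImage:
    """Column-stacked scanline matrix with per-column provenance."""

    pixels: np.ndarray  # uint8, (height, width)
    column_sources: tuple[ProposalVector, ...]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def sample_line(
    image: GrayImage, p0: tuple[float, float], p1: tuple[float, float]
) -> np.ndarray:
    """Intensities of the raster cells traversed from p0 to p1.

    Endpoints (x, y) are rounded to the nearest cell and traversed with
    Bresenham's algorithm (8-connected); intensities are taken from the cells
    as-is, with no interpolation — bar-width *ratios* carry a barcode's
    content, and uniform stretching along an oblique line preserves them.
    Endpoints must already be clipped to image bounds (caller's contract).
    """
    x0, y0 = int(round(p0[0])), int(round(p0[1]))
    x1, y1 = int(round(p1[0])), int(round(p1[1]))
    for x, y in ((x0, y0), (x1, y1)):
        if not (0 <= x < image.width and 0 <= y < image.height):
            raise ValueError(f"endpoint ({x}, {y}) outside {image.width}x{image.height} image")
    if (x0, y0) == (x1, y1):
        raise ValueError("p0 == p1 after rounding: not a line")
    rr, cc = _bresenham_line(y0, x0, y1, x1)
    return image.pixels[rr, cc]


def build_composite(
    image: GrayImage, vectors: list[ProposalVector]
) -> CompositeImage | None:
    """Stack the scanline of each vector as one column, white-padded.

    Returns None when ``vectors`` is empty — the distinct "no proposals"
    signal, so callers can report "no barcode found" without scanning
    anything.
    """
    if not vectors:
        return None
    columns = [sample_line(image, v.p0, v.p1) for v in vectors]
    height = max(len(c) for c in columns)
    pixels = np.full((height, len(columns)), PAD_VALUE, dtype=np.uint8)
    for i, col in enumerate(columns):
        pixels[: len(col), i] = col
    return CompositeImage(pixels=pixels, column_sources=tuple(vectors))


def resolution_reduction(image: GrayImage, comp: CompositeImage) -> float:
    """Fraction of source pixels avoided: 1 - composite_px / source_px."""
    return 1.0 - comp.pixels.size / (image.height * image.width)


def write_debug_composite(comp: CompositeImage, path: str | Path) -> None:
    """Write the composite as PNG plus a sidecar JSON of column sources."""
    path = Path(path)
    save_grayscale(GrayImage(comp.pixels), path)
    sources = [
        {"column": i, "p0": list(v.p0), "p1": list(v.p1)}
        for i, v in enumerate(comp.column_sources)
    ]
    path.with_suffix(".json").write_text(json.dumps(sources, indent=1))
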