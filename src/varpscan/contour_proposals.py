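"""Rectangle-contour detection and scan-vector proposal.

A 1-D barcode is a stack of solid rectangles (the bars).  Rather than trying
to localize the whole barcode, we detect anything rectangle-shaped in the
binarized image — individual bars, label blocks, rulers — and emit, for each
one, a line segment ("proposal vector") perpendicular to its long axis,
centered on its centroid and extended to a length proportional to the image's
smaller dimension.  A vector seeded on any bar of a barcode then crosses the
entire bar pattern regardless of the barcode's in-plane rotation, and false
positives merely add cheap extra scanlines downstream.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
import scipy.ndimage as ndi
from shapely.geometry import Polygon
from skimage.filters import threshold_local, threshold_otsu
from skimage.measure import approximate_polygon, find_contours

from .image_io import GrayImage

__all__ = [
    "ProposalConfig",
    "RectContour",
    "ProposalVector",
    "detect_rectangles",
    "vector_from_rect",
    "propose_vectors",
]


@dataclasses.dataclass(frozen=True)
class ProposalConfig:
    """Knobs for rectangle filtering and vector extension.

    extension_fraction is the per-side extension relative to the image's
    smaller dimension (the ``--extension_value`` CLI flag); the total nominal
    vector length is ``floor(2 * extension_fraction * smaller_dim)`` pixels,
    i.e. one-sixth of the smaller dimension on each side of the centroid at
    the default.  The rectangle filter is deliberately permissive: it has to
    admit individual barcode bars (tiny, high aspect) through whole label
    blocks, while rejecting speck noise and the full sheet.
    """

    extension_fraction: float = 1.0 / 6.0
    min_rect_area_frac: float = 5e-6
    max_rect_area_frac: float = 1e-2
    approx_epsilon_frac: float = 0.04
    binarization: str = "otsu"  # "otsu" | "adaptive"
    min_fill_ratio: float = 0.8
    adaptive_block_size: int = 51
    adaptive_offset: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 < self.extension_fraction <= 0.5:
            raise ValueError("extension_fraction must be in (0, 0.5]")
        if not 0.0 <= self.min_rect_area_frac < self.max_rect_area_frac <= 1.0:
            raise ValueError("need 0 <= min_rect_area_frac < max_rect_area_frac <= 1")
        if self.binarization not in ("otsu", "adaptive"):
            raise ValueError(f"unknown binarization {self.binarization!r}")
        if not 0.0 < self.approx_epsilon_frac < 0.5:
            raise ValueError("approx_epsilon_frac out of range")


@dataclasses.dataclass(frozen=True)
class RectContour:
    """A rectangle-like contour, reported via its minimum-area bounding box.

    corners are 4 ordered (x, y) points; orientation_deg is the angle of the
    long edge in [0, 180) measured from the +x axis.
    """

    corners: np.ndarray
    area: float
    long_edge_len: float
    short_edge_len: float
    orientation_deg: float

    @property
    def centroid(self) -> tuple[float, float]:
        c = self.corners.mean(axis=0)
        return (float(c[0]), float(c[1]))


@dataclasses.dataclass(frozen=True)
class ProposalVector:
    """An oriented segment along which pixels will be sampled."""

    p0: tuple[float, float]
    p1: tuple[float, float]
    source_rect: RectContour | None = None

    @property
    def length_px(self) -> float:
        return math.hypot(self.p1[0] - self.p0[0], self.p1[1] - self.p0[1])


def nominal_vector_length(smaller_dim: int, extension_fraction: float) -> int:
    """Total scan length in pixels: floor(2 * fraction * smaller_dim).

    With the default one-sixth fraction a 4000-px smaller dimension gives
    floor(4000/3) = 1333.
    """
    return int(math.floor(2.0 * extension_fraction * smaller_dim))


def _binarize(image: GrayImage, config: ProposalConfig) -> np.ndarray:
    px = image.pixels
    if int(px.max()) - int(px.min()) < 16:
        return np.zeros(px.shape, dtype=bool)
    if config.binarization == "otsu":
        thr = threshold_otsu(px)
        return px <= thr  # foreground (light) is px > thr; dark is the rest
    local = threshold_local(
        px, block_size=config.adaptive_block_size, method="mean",
        offset=config.adaptive_offset,
    )
    return px < local


def _is_convex_quad(verts: np.ndarray) -> bool:
    n = len(verts)
    signs = []
    for i in range(n):
        a = verts[(i + 1) % n] - verts[i]
        b = verts[(i + 2) % n] - verts[(i + 1) % n]
        cross = a[0] * b[1] - a[1] * b[0]
        if abs(cross) > 1e-9:
            signs.append(cross > 0)
    return len(set(signs)) <= 1


def _rect_from_polygon(poly: Polygon) -> RectContour | None:
    mrr = poly.minimum_rotated_rectangle
    if mrr.geom_type != "Polygon":
        return None
    corners = np.asarray(mrr.exterior.coords[:4], dtype=float)
    e0 = float(np.hypot(*(corners[1] - corners[0])))
    e1 = float(np.hypot(*(corners[2] - corners[1])))
    if e0 >= e1:
        long_len, short_len = e0, e1
        d = corners[1] - corners[0]
    else:
        long_len, short_len = e1, e0
        d = corners[2] - corners[1]
    orientation = math.degrees(math.atan2(d[1], d[0])) % 180.0
    return RectContour(
        corners=corners,
        area=float(poly.area),
        long_edge_len=long_len,
        short_edge_len=short_len,
        orientation_deg=orientation,
    )


def detect_rectangles(image: GrayImage, config: ProposalConfig | None = None) -> list[RectContour]:
    """Find every rectangle-like dark contour in the image.

    The image is binarized (Otsu global threshold, or adaptive mean as
    configured), connected dark components within the configured area band
    are traced, and a component survives if its polygon approximation has
    exactly 4 vertices, is convex, and fills at least ``min_fill_ratio`` of
    its minimum-area bounding rectangle.  Survivors are reported via that
    bounding rectangle.  Being contour-based, detection is unaffected by the
    in-plane rotation of the rectangles (up to rasterization effects).
    """
    config = config or ProposalConfig()
    dark = _binarize(image, config)
    if not dark.any():
        return []
    labels, n_labels = ndi.label(dark, structure=np.ones((3, 3), dtype=int))
    if n_labels == 0:
        return []
    counts = np.bincount(labels.ravel())
    image_area = image.height * image.width
    lo = config.min_rect_area_frac * image_area
    hi = config.max_rect_area_frac * image_area
    slices = ndi.find_objects(labels)

    rects: list[RectContour] = []
    for lab in range(1, n_labels + 1):
        if not lo <= counts[lab] <= hi:
            continue
        slc = slices[lab - 1]
        mask = np.pad(labels[slc] == lab, 1)
        contours = find_contours(mask.astype(float), 0.5)
        if not contours:
            continue
        contour = max(contours, key=len)  # (row, col) points, closed
        closed = np.vstack([contour, contour[:1]])
        perimeter = float(np.hypot(*np.diff(closed, axis=0).T).sum())
        # For elongated contours (barcode bars) a perimeter-relative epsilon
        # exceeds the short side and collapses the polygon, so clamp it to a
        # fraction of the short-side estimate 2*area/perimeter.
        area_est = 0.5 * abs(
            np.sum(closed[:-1, 0] * closed[1:, 1] - closed[1:, 0] * closed[:-1, 1])
        )
        short_est = 2.0 * area_est / perimeter if perimeter > 0 else 1.0
        tol = max(1.0, min(config.approx_epsilon_frac * perimeter, 0.6 * short_est))
        approx = approximate_polygon(contour, tolerance=tol)
        if np.allclose(approx[0], approx[-1]):
            approx = approx[:-1]
        # 4 vertices ideally; rasterization of rotated rectangles can leave a
        # residual staircase corner or two, so 5-6 convex vertices also pass
        # (non-rectangles that survive this are caught by the fill ratio).
        if not 4 <= len(approx) <= 6 or not _is_convex_quad(approx):
            continue
        # back to absolute (x, y): col + x-offset, row + y-offset; -1 for pad
        xy = np.empty_like(contour)
        xy[:, 0] = contour[:, 1] + slc[1].start - 1
        xy[:, 1] = contour[:, 0] + slc[0].start - 1
        poly = Polygon(xy)
        if not poly.is_valid:
            poly = poly.buffer(0)
            if poly.geom_type != "Polygon" or poly.is_empty:
                continue
        rect = _rect_from_polygon(poly)
        if rect is None or rect.area <= 0:
            continue
        mrr_area = rect.long_edge_len * rect.short_edge_len
        if mrr_area <= 0 or rect.area / mrr_area < config.min_fill_ratio:
            continue
        rects.append(rect)
    return rects


def _clip_segment(
    p0: np.ndarray, p1: np.ndarray, width: int, height: int
) -> tuple[np.ndarray, np.ndarray] | None:
    """Liang-Barsky clip of the segment to [0, width-1] x [0, height-1]."""
    d = p1 - p0
    t0, t1 = 0.0, 1.0
    for coord, lim in ((0, float(width - 1)), (1, float(height - 1))):
        if abs(d[coord]) < 1e-12:
            if not 0.0 <= p0[coord] <= lim:
                return None
            continue
        t_lo = (0.0 - p0[coord]) / d[coord]
        t_hi = (lim - p0[coord]) / d[coord]
        if t_lo > t_hi:
            t_lo, t_hi = t_hi, t_lo
        t0 = max(t0, t_lo)
        t1 = min(t1, t_hi)
    if t0 > t1:
        return None
    return p0 + t0 * d, p0 + t1 * d


def vector_from_rect(
    rect: RectContour, image: GrayImage, config: ProposalConfig | None = None
) -> ProposalVector | None:
    """Build the scan vector for one rectangle.

    The vector runs perpendicular to the rectangle's long edges (through the
    midpoints of the opposite long-edge pair), centered on the centroid, with
    nominal total length ``floor(2 * extension_fraction * smaller_dim)``;
    endpoints are clipped to image bounds.  Degenerate rectangles (an edge of
    ~zero length) yield None with a warning.
    """
    config = config or ProposalConfig()
    if rect.short_edge_len < 1e-6 or rect.long_edge_len < 1e-6:
        warnings.warn("skipping degenerate rectangle (zero-length edge)", stacklevel=2)
        return None
    theta = math.radians(rect.orientation_deg + 90.0)  # perpendicular to long edge
    u = np.array([math.cos(theta), math.sin(theta)])
    c = np.asarray(rect.centroid)
    n_cells = nominal_vector_length(image.smaller_dim, config.extension_fraction)
    half = (n_cells - 1) / 2.0
    clipped = _clip_segment(c - half * u, c + half * u, image.width, image.height)
    if clipped is None:
        warnings.warn("skipping vector entirely outside image bounds", stacklevel=2)
        return None
    p0, p1 = clipped
    if np.hypot(*(p1 - p0)) < 1.0:
        warnings.warn("skipping degenerate (sub-pixel) clipped vector", stacklevel=2)
        return None
    return ProposalVector(p0=(float(p0[0]), float(p0[1])),
                          p1=(float(p1[0]), float(p1[1])),
                          source_rect=rect)


def propose_vectors(
    image: GrayImage, config: ProposalConfig | None = None
) -> list[ProposalVector]:
    """detect_rectangles then vector_from_rect, in deterministic order.

    Vectors are sorted by their source rectangle's centroid (y, then x);
    degenerate rectangles are dropped.  Duplicate/overlapping vectors are
    deliberately not merged — extra columns in the composite are cheap and
    merging would add failure modes.
    """
    config = config or ProposalConfig()
    rects = detect_rectangles(image, config)
    rects.sort(key=lambda r: (round(r.centroid[1], 3), round(r.centroid[0], 3)))
    vectors = []
    for rect in rects:
        v = vector_from_rect(rect, image, config)
        if v is not None:
            vectors.append(v)
    return vectors
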