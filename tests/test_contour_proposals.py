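import math

import numpy as np
import pytest
from skimage.transform import rotate as sk_rotate

from varpscan import (
    GrayImage,
    ProposalConfig,
    detect_rectangles,
    propose_vectors,
    vector_from_rect,
)
from varpscan.contour_proposals import nominal_vector_length

from conftest import bar_centers


def test_config_validation():
    with pytest.raises(ValueError):
        ProposalConfig(extension_fraction=0.0)
    with pytest.raises(ValueError):
        ProposalConfig(min_rect_area_frac=0.5, max_rect_area_frac=0.1)
    with pytest.raises(ValueError):
        ProposalConfig(binarization="magic")


def test_uniform_image_has_no_rectangles(white_image):
    assert detect_rectangles(white_image) == []
    assert propose_vectors(white_image) == []


def test_five_bars_detected_with_correct_length(bars_image):
    rects = detect_rectangles(bars_image)
    assert len(rects) == 5
    for r in rects:
        assert r.long_edge_len == pytest.approx(60, abs=2)
        assert r.short_edge_len == pytest.approx(8, abs=2)
        assert min(r.orientation_deg, 180 - r.orientation_deg) == pytest.approx(
            90, abs=2
        ) or r.orientation_deg == pytest.approx(90, abs=2)
    xs = sorted(r.centroid[0] for r in rects)
    assert np.allclose(xs, bar_centers(), atol=1.5)


@pytest.mark.parametrize("angle", [30, 75, 145])
def test_detection_is_rotation_invariant(bars_image, angle):
    rot = sk_rotate(bars_image.pixels, angle, resize=False, order=1, cval=1.0,
                    mode="constant")
    img = GrayImage(np.clip(np.round(rot * 255), 0, 255).astype(np.uint8))
    rects = detect_rectangles(img)
    assert len(rects) == 5
    # skimage rotates CCW on screen; with y down that subtracts from the angle
    expected = (90 - angle) % 180
    for r in rects:
        dev = abs(r.orientation_deg - expected)
        assert min(dev, 180 - dev) <= 2


def test_vector_perpendicular_centered_and_sized(bars_image):
    cfg = ProposalConfig()
    rects = detect_rectangles(bars_image, cfg)
    rect = min(rects, key=lambda r: abs(r.centroid[0] - 490))
    v = vector_from_rect(rect, bars_image, cfg)
    # bar long axis is vertical, so the vector is horizontal through the centroid
    assert abs(v.p0[1] - 500) < 1.5 and abs(v.p1[1] - 500) < 1.5
    # nominal traversal = floor(2 * smaller_dim / 6) = 333 cells, so the
    # Euclidean endpoint separation is 332 px
    assert nominal_vector_length(1000, cfg.extension_fraction) == 333
    assert v.length_px == pytest.approx(332, abs=1)
    mid = ((v.p0[0] + v.p1[0]) / 2, (v.p0[1] + v.p1[1]) / 2)
    assert math.hypot(mid[0] - rect.centroid[0], mid[1] - rect.centroid[1]) <= 1


def test_nominal_length_matches_worked_example():
    # 4000-px smaller dimension with the default one-sixth fraction -> 1333
    assert nominal_vector_length(4000, 1.0 / 6.0) == 1333
    # and is a function of the image dimension only, never rectangle size
    assert nominal_vector_length(2000, 1.0 / 6.0) == 666


def test_vector_clipped_at_border():
    img = np.full((1000, 1000), 255, dtype=np.uint8)
    img[470:530, 6:14] = 0  # centroid 10 px from the left border
    gi = GrayImage(img)
    cfg = ProposalConfig()
    [v] = propose_vectors(gi, cfg)
    assert min(v.p0[0], v.p1[0]) == pytest.approx(0, abs=0.51)
    assert v.length_px < nominal_vector_length(1000, cfg.extension_fraction) - 1


@pytest.mark.parametrize("angle", [0, 20, 55, 110, 160])
def test_vector_angle_tracks_bar_perpendicular(angle):
    """A vector from a synthetic bar deviates <= 2 deg from the bar's perpendicular."""
    img = np.full((800, 800), 255, dtype=np.uint8)
    img[360:440, 396:404] = 0
    rot = sk_rotate(img, angle, resize=False, order=1, cval=1.0, mode="constant")
    gi = GrayImage(np.clip(np.round(rot * 255), 0, 255).astype(np.uint8))
    vecs = propose_vectors(gi)
    assert vecs
    bar_axis = (90 - angle) % 180
    for v in vecs:
        vec_angle = math.degrees(
            math.atan2(v.p1[1] - v.p0[1], v.p1[0] - v.p0[0])
        ) % 180
        dev = abs((vec_angle - bar_axis) % 180 - 90)
        assert min(dev, 180 - dev) <= 2


def test_propose_vectors_deterministic_and_ordered(bars_image):
    a = propose_vectors(bars_image)
    b = propose_vectors(bars_image)
    assert [(v.p0, v.p1) for v in a] == [(v.p0, v.p1) for v in b]
    keys = [(round(v.source_rect.centroid[1], 3), round(v.source_rect.centroid[0], 3))
            for v in a]
    assert keys == sorted(keys)
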