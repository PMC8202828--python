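import numpy as np
import pytest

from varpscan import (
    GrayImage,
    ProposalVector,
    build_composite,
    resolution_reduction,
    sample_line,
)


def _bresenham_cells(x0, y0, x1, y1):
    """Independent 8-connected Bresenham enumeration (test oracle)."""
    cells = []
    dx, dy = abs(x1 - x0), abs(y1 - y0)
    sx, sy = (1 if x1 > x0 else -1), (1 if y1 > y0 else -1)
    err = dx - dy
    x, y = x0, y0
    while True:
        cells.append((x, y))
        if (x, y) == (x1, y1):
            return cells
        e2 = 2 * err
        if e2 > -dy:
            err -= dy
            x += sx
        if e2 < dx:
            err += dx
            y += sy


def test_horizontal_sample_constant_field():
    img = GrayImage(np.full((20, 30), 50, dtype=np.uint8))
    vals = sample_line(img, (5, 10), (15, 10))
    assert len(vals) == 11 and (vals == 50).all()


def test_checkerboard_diagonal_matches_bresenham_oracle():
    board = (np.indices((4, 4)).sum(axis=0) % 2) * 255
    img = GrayImage(board.astype(np.uint8))
    vals = sample_line(img, (0, 0), (3, 3))
    expected = [board[y, x] for x, y in _bresenham_cells(0, 0, 3, 3)]
    np.testing.assert_array_equal(vals, expected)


@pytest.mark.parametrize("p0,p1", [((2, 3), (17, 11)), ((0, 14), (19, 0))])
def test_oblique_sample_matches_bresenham_oracle(p0, p1):
    rng = np.random.default_rng(5)
    img = GrayImage(rng.integers(0, 256, (15, 20), dtype=np.uint8))
    vals = sample_line(img, p0, p1)
    expected = [img.pixels[y, x] for x, y in _bresenham_cells(p0[0], p0[1], p1[0], p1[1])]
    np.testing.assert_array_equal(vals, expected)


def test_sample_line_contract_errors():
    img = GrayImage(np.zeros((10, 10), dtype=np.uint8))
    with pytest.raises(ValueError):
        sample_line(img, (0, 0), (12, 0))  # unclipped endpoint
    with pytest.raises(ValueError):
        sample_line(img, (3, 3), (3.2, 3.2))  # degenerate after rounding


def _hvec(x0, x1, y):
    return ProposalVector(p0=(x0, y), p1=(x1, y))


def test_composite_padding_and_column_identity():
    img = GrayImage(np.tile(np.arange(100, dtype=np.uint8), (100, 1)))
    vecs = [_hvec(41, 50, 10), _hvec(41, 60, 20), _hvec(41, 70, 30)]  # 10/20/30 cells
    comp = build_composite(img, vecs)
    assert (comp.width, comp.height) == (3, 30)
    assert (comp.pixels[10:, 0] == 255).all() and (comp.pixels[20:, 1] == 255).all()
    np.testing.assert_array_equal(
        comp.pixels[:10, 0], sample_line(img, vecs[0].p0, vecs[0].p1)
    )
    single = build_composite(img, [vecs[2]])
    assert single.width == 1
    np.testing.assert_array_equal(
        single.pixels[:, 0], sample_line(img, vecs[2].p0, vecs[2].p1)
    )


def test_empty_vector_list_is_distinct_signal():
    img = GrayImage(np.zeros((10, 10), dtype=np.uint8))
    assert build_composite(img, []) is None


def test_permuting_vectors_permutes_columns():
    rng = np.random.default_rng(9)
    img = GrayImage(rng.integers(0, 256, (200, 200), dtype=np.uint8))
    vecs = [_hvec(70, 130 + i, 20 * i + 10) for i in range(5)]
    comp = build_composite(img, vecs)
    perm = [3, 0, 4, 1, 2]
    comp_p = build_composite(img, [vecs[i] for i in perm])
    np.testing.assert_array_equal(comp_p.pixels, comp.pixels[:, perm])


def test_worked_example_dimensions_and_reduction():
    """200 unclipped default vectors in 4000x6000 -> 200x1333, 98.9% reduction."""
    img = GrayImage(np.full((4000, 6000), 255, dtype=np.uint8))
    vecs = [_hvec(2334, 2334 + 1332, 1000 + 10 * i) for i in range(200)]
    comp = build_composite(img, vecs)
    assert (comp.width, comp.height) == (200, 1333)
    red = resolution_reduction(img, comp)
    assert round(100 * red, 1) == 98.9


def test_reduction_formula():
    img = GrayImage(np.zeros((10, 10), dtype=np.uint8))
    comp = build_composite(img, [_hvec(0, 9, 5)])  # 10-cell column
    assert resolution_reduction(img, comp) == pytest.approx(1 - 10 / 100)
    # ten such vectors tile the full pixel count -> zero reduction
    comp10 = build_composite(img, [_hvec(0, 9, y) for y in range(10)])
    assert resolution_reduction(img, comp10) == 0.0
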