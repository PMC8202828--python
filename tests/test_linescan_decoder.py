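import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from varpscan import CompositeImage, DecoderConfig, binarize_scanline, decode_composite
from varpscan._symbology import CODE128_PATTERNS, CODE128_STOP, code128_checksum
from varpscan.linescan_decoder import decode_code39, decode_code128
from varpscan.synthetic_data import encode_modules, render_scanline


def _symbol_runs(symbol_values):
    runs = [(j % 2 == 0, w) for v in symbol_values for j, w in enumerate(CODE128_PATTERNS[v])]
    runs += [(j % 2 == 0, w) for j, w in enumerate(CODE128_STOP)]
    return runs


def test_binarize_trivial_cases():
    assert binarize_scanline(np.full(40, 255, dtype=np.uint8)) == []
    line = np.array([255] * 5 + [0] * 3 + [255] * 5, dtype=np.uint8)
    assert binarize_scanline(line) == [(False, 5), (True, 3), (False, 5)]
    # near-flat is undecodable, not an error
    assert binarize_scanline(np.array([120, 125, 130], dtype=np.uint8)) == []


def test_code128_minimal_symbol_sequence():
    # start-B, "A" (33), checksum 34, stop
    d = decode_code128(_symbol_runs([104, 33, 34]))
    assert d is not None and d.value == "A"
    assert d.symbology == "code128" and d.checksum_ok


def test_code128_reverse_direction():
    runs = binarize_scanline(render_scanline(encode_modules("UCHT001234", "code128"), 3))
    fwd = decode_code128(runs)
    rev = decode_code128(runs[::-1])
    assert fwd.value == rev.value == "UCHT001234"
    assert fwd.direction == "forward" and rev.direction == "reverse"


def test_code128_wrong_checksum_rejected():
    assert decode_code128(_symbol_runs([104, 33, 35])) is None


def test_code39_roundtrip_and_jitter():
    runs = encode_modules("UCHT001234", "code39")
    line = render_scanline(runs, 2)  # narrow 2 px / wide 6 px
    assert decode_code39(binarize_scanline(line)).value == "UCHT001234"
    rng = np.random.default_rng(17)
    jittered = [(b, max(1, w * 2 + int(rng.integers(-1, 2)))) for b, w in runs]
    parts = [np.full(20, 255, dtype=np.uint8)]
    for b, w in jittered:
        parts.append(np.full(w, 0 if b else 255, dtype=np.uint8))
    parts.append(np.full(20, 255, dtype=np.uint8))
    d = decode_code39(binarize_scanline(np.concatenate(parts)))
    assert d is not None and d.value == "UCHT001234"


def test_code39_requires_stop_delimiter():
    runs = encode_modules("ABC123", "code39")
    truncated = runs[:-10]  # drop the trailing "*" (9 elements + gap)
    line = render_scanline(truncated, 3)
    assert decode_code39(binarize_scanline(line)) is None


def test_code39_optional_mod43_checksum():
    from varpscan._symbology import code39_checksum

    payload = "UCHT001234"
    good = payload + code39_checksum(payload)
    line = render_scanline(encode_modules(good, "code39"), 3)
    d = decode_code39(binarize_scanline(line), checksum=True)
    assert d is not None and d.value == payload and d.checksum_ok
    bad = payload + ("0" if good[-1] != "0" else "1")
    line = render_scanline(encode_modules(bad, "code39"), 3)
    assert decode_code39(binarize_scanline(line), checksum=True) is None


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.text(alphabet="ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789", min_size=1, max_size=20),
    st.integers(min_value=2, max_value=5),
    st.sampled_from(["code128", "code39"]),
)
def test_roundtrip_property(value, module_width, symbology):
    """decode(render(encode(s))) == s for arbitrary payloads and module widths."""
    line = render_scanline(encode_modules(value, symbology), module_width)
    runs = binarize_scanline(line)
    d = decode_code128(runs) if symbology == "code128" else decode_code39(runs)
    assert d is not None and d.value == value


def _composite_from_scanline(line, n_cols=3):
    px = np.tile(np.asarray(line, dtype=np.uint8)[:, None], (1, n_cols))
    return CompositeImage(pixels=px, column_sources=())


def test_decode_composite_dedup_and_column():
    line = render_scanline(encode_modules("MARY00012345", "code128"), 3)
    comp = _composite_from_scanline(line, n_cols=4)
    found = decode_composite(comp)
    assert {d.value for d in found} == {"MARY00012345"}
    assert len(found) == 1  # k identical columns -> one entry


def test_decode_composite_white_is_empty():
    comp = CompositeImage(
        pixels=np.full((400, 8), 255, dtype=np.uint8), column_sources=()
    )
    assert decode_composite(comp) == set()


def test_low_contrast_rescued_by_enhancement():
    line = render_scanline(encode_modules("UCHT001234", "code128"), 3)
    # compress to bars=120 on background=135: flat to the midpoint binarizer
    low = np.where(line < 128, 120, 135).astype(np.uint8)
    comp = _composite_from_scanline(low)
    assert binarize_scanline(low) == []  # first pass sees nothing
    found = decode_composite(comp)
    assert {d.value for d in found} == {"UCHT001234"}


def test_single_axis_contract_transpose_changes_results():
    line = render_scanline(encode_modules("UCHT001234", "code128"), 3)
    comp = _composite_from_scanline(line)
    assert decode_composite(comp)
    transposed = CompositeImage(pixels=comp.pixels.T.copy(), column_sources=())
    assert decode_composite(transposed) == set()


def test_min_value_length_suppresses_short_decodes():
    comp = _composite_from_scanline(
        render_scanline(encode_modules("AB", "code128"), 3)
    )
    assert decode_composite(comp, DecoderConfig()) == set()
    cfg = DecoderConfig(min_value_length=1)
    assert {d.value for d in decode_composite(comp, cfg)} == {"AB"}


def test_decoder_config_validation():
    with pytest.raises(ValueError):
        DecoderConfig(symbologies=("qr",))
    with pytest.raises(ValueError):
        DecoderConfig(fallback_schedule=((0.5, 0),))
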