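"""Single-axis line scanning: Code 128 and Code 39 decoding of composite columns.

Every column of the composite is treated as an independent scanline: it is
binarized at the midpoint of its own intensity range (columns come from
differently lit regions of the source), run-length encoded, and fed to both
symbology decoders in both scan directions.  Rows are never scanned — after
compositing, every candidate barcode lies along the vertical axis, which is
the whole point of the method.  If nothing decodes, the composite is
re-scanned under a short schedule of contrast/brightness enhancements.

Code 128 symbols are classified by normalizing each 6-element group to its
own 11-module total, so the decoder is insensitive to the uniform stretch an
oblique scanline applies.  Code 39 groups (9 elements, 3 wide) are classified
wide/narrow against the group's own width range.  Both are therefore robust
to unknown absolute module width, which varies column to column.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from ._symbology import (
    CODE128_CODE_A,
    CODE128_CODE_B,
    CODE128_CODE_C,
    CODE128_FNC1,
    CODE128_FNC2,
    CODE128_FNC3,
    CODE128_PATTERN_TO_VALUE,
    CODE128_SHIFT,
    CODE128_START_A,
    CODE128_START_B,
    CODE128_START_C,
    CODE128_STOP,
    CODE39_PATTERN_TO_CHAR,
    code39_checksum,
    code128_checksum,
)
from .composite import CompositeImage

__all__ = [
    "DecoderConfig",
    "DecodedBarcode",
    "Run",
    "binarize_scanline",
    "decode_code128",
    "decode_code39",
    "decode_runs",
    "decode_composite",
]

# (is_bar, width_px)
Run = tuple[bool, int]

FLAT_RANGE = 16  # a scanline spanning less than this is undecodable, not an error

DEFAULT_FALLBACK_SCHEDULE: tuple[tuple[float, float], ...] = (
    (1.0, 0.0),
    (1.3, 10.0),
    (1.6, 20.0),
    (2.0, 40.0),
    (3.0, 60.0),
)


@dataclasses.dataclass(frozen=True)
class DecoderConfig:
    symbologies: tuple[str, ...] = ("code128", "code39")
    code39_checksum: bool = False
    fallback_schedule: tuple[tuple[float, float], ...] = DEFAULT_FALLBACK_SCHEDULE
    min_value_length: int = 4  # suppresses spurious 1-2 character decodes

    def __post_init__(self) -> None:
        for s in self.symbologies:
            if s not in ("code128", "code39"):
                raise ValueError(f"unknown symbology {s!r}")
        for gain, _ in self.fallback_schedule:
            if gain < 1.0:
                raise ValueError("enhancement gain must be >= 1")


@dataclasses.dataclass(frozen=True)
class DecodedBarcode:
    value: str
    symbology: str
    checksum_ok: bool
    column: int = -1
    direction: str = "forward"


def binarize_scanline(values: Sequence[int] | np.ndarray) -> list[Run]:
    """Threshold a scanline at the midpoint of its range and run-length encode.

    Returns alternating (is_bar, width) runs with leading/trailing light runs
    kept — they are the quiet zones the decoders check.  A flat scanline
    (range < 16 intensity units) yields an empty list.
    """
    v = np.asarray(values)
    if v.size == 0:
        return []
    lo, hi = int(v.min()), int(v.max())
    if hi - lo < FLAT_RANGE:
        return []
    dark = v < (lo + hi) / 2.0
    edges = np.flatnonzero(np.diff(dark)) + 1
    starts = np.concatenate(([0], edges))
    ends = np.concatenate((edges, [len(dark)]))
    return [(bool(dark[s]), int(e - s)) for s, e in zip(starts, ends)]


def _classify_group(widths: Sequence[int], n_modules: int) -> tuple[int, ...] | None:
    """Normalize a run group to its own module total; None if inconsistent."""
    total = sum(widths)
    if total < len(widths):
        return None
    est = tuple(int(round(w * n_modules / total)) for w in widths)
    if any(e < 1 for e in est) or sum(est) != n_modules:
        return None
    return est


# Edge-to-similar-edge sums (w_i + w_{i+1}) are invariant to the uniform
# bar-widening / space-narrowing a biased threshold or ink spread causes, and
# the 5-tuple of sums happens to identify each Code 128 symbol uniquely.
CODE128_EDGESUMS_TO_VALUE: dict[tuple[int, ...], int] = {
    tuple(p[i] + p[i + 1] for i in range(5)): v
    for p, v in CODE128_PATTERN_TO_VALUE.items()
}
_STOP_EDGESUMS = tuple(
    CODE128_STOP[i] + CODE128_STOP[i + 1] for i in range(6)
)


def _classify_symbol128(widths: Sequence[int]) -> int | None:
    """Symbol value for 6 runs, by direct rounding then edge-sum lookup."""
    pat = _classify_group(widths, 11)
    if pat is not None:
        v = CODE128_PATTERN_TO_VALUE.get(pat)
        if v is not None:
            return v
    total = sum(widths)
    if total < 6:
        return None
    sums = tuple(
        int(round((widths[i] + widths[i + 1]) * 11.0 / total)) for i in range(5)
    )
    return CODE128_EDGESUMS_TO_VALUE.get(sums)


def _is_stop128(widths: Sequence[int]) -> bool:
    if _classify_group(widths, 13) == CODE128_STOP:
        return True
    total = sum(widths)
    if total < 7:
        return False
    sums = tuple(
        int(round((widths[i] + widths[i + 1]) * 13.0 / total)) for i in range(6)
    )
    return sums == _STOP_EDGESUMS


def _quiet_before(runs: list[Run], i: int, module: float) -> bool:
    if i == 0:
        return True  # scanline starts here; treat the edge as quiet
    is_bar, width = runs[i - 1]
    return (not is_bar) and width >= 3.0 * module


def _quiet_after(runs: list[Run], j: int, module: float) -> bool:
    if j >= len(runs):
        return True
    is_bar, width = runs[j]
    return (not is_bar) and (j == len(runs) - 1 or width >= 3.0 * module)


def _translate_code128(start: int, data: list[int]) -> str | None:
    charset = {CODE128_START_A: "A", CODE128_START_B: "B", CODE128_START_C: "C"}[start]
    out: list[str] = []
    shift: str | None = None
    for v in data:
        cur = shift or charset
        shift = None
        if cur == "C":
            if v == CODE128_CODE_B:
                charset = "B"
            elif v == CODE128_CODE_A:
                charset = "A"
            elif v == CODE128_FNC1:
                pass
            elif v <= 99:
                out.append(f"{v:02d}")
            else:
                return None
            continue
        # sets A and B
        if v == CODE128_CODE_C:
            charset = "C"
        elif v == CODE128_CODE_B and cur == "A":
            charset = "B"
        elif v == CODE128_CODE_A and cur == "B":
            charset = "A"
        elif v == CODE128_SHIFT:
            shift = "B" if cur == "A" else "A"
        elif v in (CODE128_FNC1, CODE128_FNC2, CODE128_FNC3):
            pass
        elif cur == "B":
            if not 0 <= v <= 95:
                return None
            out.append(chr(32 + v))
        else:  # set A
            if not 0 <= v <= 95:
                return None
            out.append(chr(32 + v) if v < 64 else chr(v - 64))
    return "".join(out)


def _decode_code128_oneway(runs: list[Run]) -> str | None:
    widths = [w for _, w in runs]
    n = len(runs)
    for i in range(n - 12):
        if not runs[i][0]:
            continue
        start = _classify_symbol128(widths[i : i + 6])
        if start not in (CODE128_START_A, CODE128_START_B, CODE128_START_C):
            continue
        module = sum(widths[i : i + 6]) / 11.0
        if not _quiet_before(runs, i, module):
            continue
        symbols: list[int] = [start]
        j = i + 6
        ok = False
        while j + 7 <= n and len(symbols) < 60:
            if _is_stop128(widths[j : j + 7]) and _quiet_after(runs, j + 7, module):
                ok = True
                break
            v = _classify_symbol128(widths[j : j + 6])
            if v is None or v > 105:
                break
            symbols.append(v)
            j += 6
        if not ok or len(symbols) < 2:
            continue
        *body, check = symbols
        if code128_checksum(body) != check:
            continue
        value = _translate_code128(body[0], body[1:])
        if value:
            return value
    return None


def decode_code128(runs: list[Run]) -> DecodedBarcode | None:
    """Decode one Code 128 symbol sequence from a run-length scanline.

    Slides over candidate start symbols (sets A/B/C), classifies 6-element
    groups against the 107-pattern table, and requires a valid stop pattern
    and mod-103 checksum; code-set switching, shift, and the digit-pair set C
    are supported.  Both scan directions are attempted.  Returns None on any
    failure — a scanline simply may not contain a barcode.
    """
    if len(runs) < 13:
        return None
    value = _decode_code128_oneway(runs)
    if value is not None:
        return DecodedBarcode(value, "code128", checksum_ok=True)
    value = _decode_code128_oneway(runs[::-1])
    if value is not None:
        return DecodedBarcode(value, "code128", checksum_ok=True, direction="reverse")
    return None


def _classify_code39_group(widths: Sequence[int]) -> tuple[str, float] | None:
    """Wide/narrow pattern for 9 runs (5 bars, 4 spaces), or None.

    Bars and spaces are classified against their own width ranges: a biased
    threshold widens every bar and narrows every space by the same amount,
    which per-type classification cancels.  Every Code 39 character has
    either 2 wide bars + 1 wide space or (the $/+%-style specials) 0 + 3.
    Also returns the narrow-space cutoff used for inter-character gaps.
    """
    bars = widths[0::2]
    spaces = widths[1::2]
    s_lo, s_hi = min(spaces), max(spaces)
    if s_hi < 1.6 * s_lo:  # spaces always mix narrow and wide
        return None
    s_cut = (s_lo + s_hi) / 2.0
    b_lo, b_hi = min(bars), max(bars)
    b_cut = (b_lo + b_hi) / 2.0 if b_hi >= 1.6 * b_lo else float(b_hi) + 1.0
    pattern = "".join(
        "W" if w > (b_cut if k % 2 == 0 else s_cut) else "N"
        for k, w in enumerate(widths)
    )
    n_wide_bars = pattern[0::2].count("W")
    n_wide_spaces = pattern[1::2].count("W")
    if (n_wide_bars, n_wide_spaces) not in ((2, 1), (0, 3)):
        return None
    return pattern, s_cut


def _decode_code39_oneway(runs: list[Run], check: bool) -> tuple[str, bool] | None:
    n = len(runs)
    for i in range(n - 8):
        if not runs[i][0]:
            continue
        group = [w for _, w in runs[i : i + 9]]
        cls = _classify_code39_group(group)
        if cls is None:
            continue
        pattern, cut = cls
        if CODE39_PATTERN_TO_CHAR.get(pattern) != "*":
            continue
        narrow = min(group)
        if not _quiet_before(runs, i, narrow):
            continue
        chars: list[str] = []
        j = i + 9  # index of the inter-character gap
        ok = False
        while j + 10 <= n and len(chars) < 60:
            gap_bar, gap_w = runs[j]
            if gap_bar or gap_w > cut:  # gap must be a narrow space
                break
            cls = _classify_code39_group([w for _, w in runs[j + 1 : j + 10]])
            if cls is None:
                break
            pattern, cut = cls
            ch = CODE39_PATTERN_TO_CHAR.get(pattern)
            if ch is None:
                break
            if ch == "*":
                if _quiet_after(runs, j + 10, min(w for _, w in runs[j + 1 : j + 10])):
                    ok = True
                break
            chars.append(ch)
            j += 10
        if not ok or not chars:
            continue
        value = "".join(chars)
        if check:
            if len(value) < 2 or code39_checksum(value[:-1]) != value[-1]:
                continue
            return value[:-1], True
        return value, False
    return None


def decode_code39(runs: list[Run], checksum: bool = False) -> DecodedBarcode | None:
    """Decode one Code 39 value from a run-length scanline.

    Each character is 9 elements (5 bars, 4 spaces) of which exactly 3 are
    wide, classified against the group's own width range; the value must be
    framed by "*" delimiters with narrow inter-character gaps.  Both scan
    directions are attempted.  With ``checksum`` enabled the trailing mod-43
    check character is verified and stripped.
    """
    if len(runs) < 19:
        return None
    res = _decode_code39_oneway(runs, checksum)
    if res is not None:
        return DecodedBarcode(res[0], "code39", checksum_ok=res[1])
    res = _decode_code39_oneway(runs[::-1], checksum)
    if res is not None:
        return DecodedBarcode(res[0], "code39", checksum_ok=res[1], direction="reverse")
    return None


def decode_runs(runs: list[Run], config: DecoderConfig) -> list[DecodedBarcode]:
    """Run every configured symbology decoder over one scanline's runs."""
    found = []
    if "code128" in config.symbologies:
        r = decode_code128(runs)
        if r is not None:
            found.append(r)
    if "code39" in config.symbologies:
        r = decode_code39(runs, checksum=config.code39_checksum)
        if r is not None:
            found.append(r)
    return [r for r in found if len(r.value) >= config.min_value_length]


def _scan_columns(pixels: np.ndarray, config: DecoderConfig) -> list[DecodedBarcode]:
    found: list[DecodedBarcode] = []
    for c in range(pixels.shape[1]):
        runs = binarize_scanline(pixels[:, c])
        if not runs:
            continue
        for r in decode_runs(runs, config):
            found.append(dataclasses.replace(r, column=c))
    return found


def enhance(pixels: np.ndarray, gain: float, offset: float) -> np.ndarray:
    """pixel' = clip(gain * pixel + offset, 0, 255) — saturating."""
    return np.clip(pixels.astype(np.float32) * gain + offset, 0, 255).astype(np.uint8)


def decode_composite(
    comp: CompositeImage, config: DecoderConfig | None = None
) -> set[DecodedBarcode]:
    """Scan every composite column; escalate contrast/brightness on failure.

    Each step of the fallback schedule is applied to the *original* composite
    (never cumulatively) and the columns rescanned; the loop stops at the
    first step yielding at least one decode.  Results are deduplicated by
    (value, symbology); an empty set means no barcode was found.
    """
    config = config or DecoderConfig()
    for gain, offset in config.fallback_schedule:
        pixels = comp.pixels if (gain, offset) == (1.0, 0.0) else enhance(
            comp.pixels, gain, offset
        )
        found = _scan_columns(pixels, config)
        if found:
            unique: dict[tuple[str, str], DecodedBarcode] = {}
            for r in found:
                unique.setdefault((r.value, r.symbology), r)
            return set(unique.values())
    return set()
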