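"""Symbol tables for the Code 128 and Code 39 symbologies.

Both the synthetic renderer (encoding) and the line-scan decoder import these
tables, so a round trip exercises the geometry/sampling/classification path
rather than two independent transcriptions of the standard.

Code 128: each symbol value 0-102 plus the three start codes (103=A, 104=B,
105=C) is 11 modules wide, laid out as 6 elements (3 bars, 3 spaces) whose
widths are 1-4 modules.  The stop pattern (value 106) is 13 modules in 7
elements.  Code 39: each character is 9 elements (5 bars, 4 spaces), exactly
3 of which are wide; characters are separated by a narrow space.
"""

from __future__ import annotations

# fmt: off
CODE128_PATTERNS: tuple[tuple[int, ...], ...] = tuple(
    tuple(int(c) for c in s)
    for s in (
        "212222", "222122", "222221", "121223", "121322", "131222", "122213",
        "122312", "132212", "221213", "221312", "231212", "112232", "122132",
        "122231", "113222", "123122", "123221", "223211", "221132", "221231",
        "213212", "223112", "312131", "311222", "321122", "321221", "312212",
        "322112", "322211", "212123", "212321", "232121", "111323", "131123",
        "131321", "112313", "132113", "132311", "211313", "231113", "231311",
        "112133", "112331", "132131", "113123", "113321", "133121", "313121",
        "211331", "231131", "213113", "213311", "213131", "311123", "311321",
        "331121", "312113", "312311", "332111", "314111", "221411", "431111",
        "111224", "111422", "121124", "121421", "141122", "141221", "112214",
        "112412", "122114", "122411", "142112", "142211", "241211", "221114",
        "413111", "241112", "134111", "111242", "121142", "121241", "114212",
        "124112", "124211", "411212", "421112", "421211", "212141", "214121",
        "412121", "111143", "111341", "131141", "114113", "114311", "411113",
        "411311", "113141", "114131", "311141", "411131", "211412", "211214",
        "211232",
    )
)
# fmt: on

CODE128_STOP: tuple[int, ...] = (2, 3, 3, 1, 1, 1, 2)  # 13 modules, 7 elements

CODE128_START_A = 103
CODE128_START_B = 104
CODE128_START_C = 105
CODE128_STOP_VALUE = 106

# Special (non-literal) symbol values within code sets A/B.
CODE128_FNC3 = 96
CODE128_FNC2 = 97
CODE128_SHIFT = 98
CODE128_CODE_C = 99
CODE128_CODE_B = 100   # in sets A and C
CODE128_CODE_A = 101   # in sets B and C
CODE128_FNC1 = 102

CODE128_PATTERN_TO_VALUE: dict[tuple[int, ...], int] = {
    p: v for v, p in enumerate(CODE128_PATTERNS)
}

# Code 39: N = narrow, W = wide; elements alternate bar/space starting with a
# bar, so indices 0,2,4,6,8 are bars and 1,3,5,7 are spaces.
CODE39_PATTERNS: dict[str, str] = {
    "0": "NNNWWNWNN", "1": "WNNWNNNNW", "2": "NNWWNNNNW", "3": "WNWWNNNNN",
    "4": "NNNWWNNNW", "5": "WNNWWNNNN", "6": "NNWWWNNNN", "7": "NNNWNNWNW",
    "8": "WNNWNNWNN", "9": "NNWWNNWNN",
    "A": "WNNNNWNNW", "B": "NNWNNWNNW", "C": "WNWNNWNNN", "D": "NNNNWWNNW",
    "E": "WNNNWWNNN", "F": "NNWNWWNNN", "G": "NNNNNWWNW", "H": "WNNNNWWNN",
    "I": "NNWNNWWNN", "J": "NNNNWWWNN", "K": "WNNNNNNWW", "L": "NNWNNNNWW",
    "M": "WNWNNNNWN", "N": "NNNNWNNWW", "O": "WNNNWNNWN", "P": "NNWNWNNWN",
    "Q": "NNNNNNWWW", "R": "WNNNNNWWN", "S": "NNWNNNWWN", "T": "NNNNWNWWN",
    "U": "WWNNNNNNW", "V": "NWWNNNNNW", "W": "WWWNNNNNN", "X": "NWNNWNNNW",
    "Y": "WWNNWNNNN", "Z": "NWWNWNNNN",
    "-": "NWNNNNWNW", ".": "WWNNNNWNN", " ": "NWWNNNWNN", "*": "NWNNWNWNN",
    "$": "NWNWNWNNN", "/": "NWNWNNNWN", "+": "NWNNNWNWN", "%": "NNNWNWNWN",
}

CODE39_PATTERN_TO_CHAR: dict[str, str] = {p: c for c, p in CODE39_PATTERNS.items()}

# mod-43 check character values (the "*" delimiter has no value).
CODE39_VALUES: dict[str, int] = {
    c: i for i, c in enumerate("0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ-. $/+%")
}
CODE39_ALPHABET = frozenset(CODE39_VALUES)


def code128_checksum(symbol_values: list[int]) -> int:
    """Mod-103 check value for [start, data...] symbol values.

    The start code carries weight 1 and each data symbol i (1-based) carries
    weight i.
    """
    total = symbol_values[0]
    for i, v in enumerate(symbol_values[1:], start=1):
        total += i * v
    return total % 103


def code39_checksum(payload: str) -> str:
    """Mod-43 check character for a Code 39 payload (without delimiters)."""
    total = sum(CODE39_VALUES[c] for c in payload)
    inv = {v: c for c, v in CODE39_VALUES.items()}
    return inv[total % 43]
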