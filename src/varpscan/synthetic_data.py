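"""Synthetic specimen images with known barcode ground truth.

Emulates what a digitization station produces: a large, nearly white sheet
(herbarium mounting paper) carrying one small 1-D barcode at arbitrary
rotation, plus distractor shapes standing in for labels, rulers and plant
material, with mild sensor noise and optical blur.  Every image is fully
determined by its spec (including the seed), so ground truth is exact and
corpora are reproducible.

Deliberately not emulated: photorealistic plant texture, lens distortion,
JPEG artifacts, uneven illumination.  Passing tests on these images
demonstrates the geometry and decoding logic, not robustness to every
real-world degradation.
"""

from __future__ import annotations

import csv
import dataclasses
import math
from pathlib import Path

import numpy as np
import scipy.ndimage as ndi
from skimage.transform import rotate as _rotate

from ._symbology import (
    CODE39_ALPHABET,
    CODE39_PATTERNS,
    code39_checksum,
    code128_checksum,
    CODE128_PATTERNS,
    CODE128_START_B,
    CODE128_START_C,
    CODE128_CODE_B,
    CODE128_CODE_C,
    CODE128_STOP,
)
from .image_io import GrayImage
from .linescan_decoder import Run

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "CorpusProfile",
    "encode_modules",
    "encode_code128_symbols",
    "render_scanline",
    "render_specimen",
    "draw_specs",
    "make_corpus",
    "write_corpus",
]

QUIET_MODULES = 10  # quiet zone on each side, the symbology minimum
CODE39_WIDE = 3  # wide elements are 3 modules (standard 2:1..3:1 band)


def encode_code128_symbols(value: str) -> list[int]:
    """Code 128 symbol values [start, data...] (checksum excluded).

    Set selection is the practical minimal-length heuristic: runs of 4+
    digits (or an all-digit even-length value) are packed as digit pairs in
    set C; everything else uses set B.
    """
    for ch in value:
        o = ord(ch)
        if not 32 <= o <= 126:
            raise ValueError(f"character {ch!r} not encodable in Code 128 set B")
    if not value:
        raise ValueError("empty payload")

    def digit_run(s: str, i: int) -> int:
        j = i
        while j < len(s) and s[j].isdigit():
            j += 1
        return j - i

    symbols: list[int] = []
    i = 0
    d0 = digit_run(value, 0)
    if d0 == len(value) and d0 >= 2 and d0 % 2 == 0:
        charset = "C"
    elif d0 >= 4:
        charset = "C"
    else:
        charset = "B"
    symbols.append(CODE128_START_C if charset == "C" else CODE128_START_B)
    while i < len(value):
        d = digit_run(value, i)
        if charset == "B" and (d >= 4 or (d >= 2 and i + d == len(value) and d % 2 == 0)):
            symbols.append(CODE128_CODE_C)
            charset = "C"
        if charset == "C":
            if d >= 2:
                symbols.append(int(value[i : i + 2]))
                i += 2
                continue
            symbols.append(CODE128_CODE_B)
            charset = "B"
        symbols.append(ord(value[i]) - 32)
        i += 1
    return symbols


def encode_modules(value: str, symbology: str) -> list[Run]:
    """Module-level run lengths (is_bar, n_modules) for a payload.

    Code 128: start symbol, data, mod-103 checksum, stop — 3 bars + 3 spaces
    per symbol, 13-module stop.  Code 39: "*"-delimited characters (wide = 3
    modules) separated by single narrow spaces.  Quiet zones are left to the
    renderer.
    """
    if symbology == "code128":
        symbols = encode_code128_symbols(value)
        symbols.append(code128_checksum(symbols))
        runs: list[Run] = []
        for v in symbols:
            for k, w in enumerate(CODE128_PATTERNS[v]):
                runs.append((k % 2 == 0, w))
        for k, w in enumerate(CODE128_STOP):
            runs.append((k % 2 == 0, w))
        return runs
    if symbology == "code39":
        for ch in value:
            if ch not in CODE39_ALPHABET or ch == "*":
                raise ValueError(f"character {ch!r} not encodable in Code 39")
        runs = []
        for idx, ch in enumerate("*" + value + "*"):
            if idx:
                runs.append((False, 1))  # narrow inter-character gap
            for k, nw in enumerate(CODE39_PATTERNS[ch]):
                runs.append((k % 2 == 0, CODE39_WIDE if nw == "W" else 1))
        return runs
    raise ValueError(f"unknown symbology {symbology!r}")


def render_scanline(
    runs: list[Run], module_width: int, quiet_modules: int = QUIET_MODULES
) -> np.ndarray:
    """1-D rendering: black bars (0) on white (255) with quiet zones."""
    parts = [np.full(quiet_modules * module_width, 255, dtype=np.uint8)]
    for is_bar, n in runs:
        parts.append(np.full(n * module_width, 0 if is_bar else 255, dtype=np.uint8))
    parts.append(np.full(quiet_modules * module_width, 255, dtype=np.uint8))
    return np.concatenate(parts)


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    image_size: tuple[int, int] = (4000, 6000)  # (height, width)
    value: str = "UCHT001234"
    symbology: str = "code128"
    module_width: int = 3
    bar_height: int = 150
    rotation_deg: float = 0.0
    position: tuple[float, float] | None = None  # (x, y) barcode center; None = image center
    noise_sigma: float = 0.0
    blur_sigma: float = 0.0
    n_distractors: int = 0
    seed: int = 0


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    value: str
    symbology: str
    rotation_deg: float
    bbox: np.ndarray  # 4 corner (x, y) points of the rendered barcode patch


def _barcode_patch(spec: SyntheticSpec) -> np.ndarray:
    scan = render_scanline(
        encode_modules(spec.value, spec.symbology), spec.module_width
    )
    margin = QUIET_MODULES * spec.module_width
    patch = np.full((spec.bar_height + 2 * margin, len(scan)), 255, dtype=np.uint8)
    patch[margin : margin + spec.bar_height, :] = scan[np.newaxis, :]
    return patch


def render_specimen(spec: SyntheticSpec) -> tuple[GrayImage, GroundTruth]:
    """Render one specimen image and its exact ground truth.

    The barcode patch (bars + quiet zones) is rasterized at module_width /
    bar_height, rotated with bilinear resampling, and pasted at ``position``
    on a white-ish (mean 245) sheet; distractor rectangles and ellipses are
    placed without touching the barcode's bounding box; blur then Gaussian
    noise are applied last so bar edges degrade the way optics and sensor
    degrade them.  Deterministic for a fixed spec.

    Raises ValueError if the rotated barcode does not fit fully inside the
    image — a clipped barcode would silently poison ground truth.
    """
    h, w = spec.image_size
    rng = np.random.default_rng(spec.seed)
    patch = _barcode_patch(spec)
    ph, pw = patch.shape
    rotated = (
        patch
        if spec.rotation_deg % 360.0 == 0.0
        else _rotate(
            patch, spec.rotation_deg, resize=True, order=1, cval=1.0,
            mode="constant", preserve_range=False,
        )
    )
    if rotated.dtype != np.uint8:
        rotated = np.clip(np.round(rotated * 255.0), 0, 255).astype(np.uint8)
    rh, rw = rotated.shape
    cx, cy = spec.position if spec.position is not None else (w / 2, h / 2)
    x0, y0 = int(round(cx - rw / 2)), int(round(cy - rh / 2))
    if x0 < 0 or y0 < 0 or x0 + rw > w or y0 + rh > h:
        raise ValueError(
            f"rotated barcode ({rh}x{rw} at center ({cx}, {cy})) "
            f"does not fit inside {h}x{w} image"
        )

    image = np.full((h, w), 245, dtype=np.uint8)

    # ground-truth bbox: patch corners rotated about the patch center (image
    # y-axis points down, so a CCW rotation in standard axes is implemented
    # by skimage as CCW in displayed orientation; track corners accordingly)
    ang = math.radians(spec.rotation_deg)
    rot = np.array([[math.cos(ang), math.sin(ang)], [-math.sin(ang), math.cos(ang)]])
    corners = np.array([[0, 0], [pw, 0], [pw, ph], [0, ph]], dtype=float)
    centered = corners - [pw / 2, ph / 2]
    bbox = centered @ rot.T + [cx, cy]

    if spec.n_distractors:
        _place_distractors(image, rng, spec.n_distractors,
                           (x0 - 20, y0 - 20, x0 + rw + 20, y0 + rh + 20))

    region = image[y0 : y0 + rh, x0 : x0 + rw]
    np.minimum(region, rotated, out=region)

    out = image.astype(np.float32)
    if spec.blur_sigma > 0:
        out = ndi.gaussian_filter(out, spec.blur_sigma)
    if spec.noise_sigma > 0:
        out += rng.normal(0.0, spec.noise_sigma, out.shape).astype(np.float32)
    image = np.clip(np.round(out), 0, 255).astype(np.uint8)

    gt = GroundTruth(spec.value, spec.symbology, spec.rotation_deg, bbox)
    return GrayImage(image), gt


def _place_distractors(
    image: np.ndarray, rng: np.random.Generator, n: int,
    forbidden: tuple[int, int, int, int],
) -> None:
    """Gray rectangles/ellipses (labels, rulers, stems) avoiding the barcode."""
    h, w = image.shape
    fx0, fy0, fx1, fy1 = forbidden
    for _ in range(n):
        for _attempt in range(50):
            dw = int(rng.integers(40, max(41, w // 12)))
            dh = int(rng.integers(40, max(41, h // 12)))
            x = int(rng.integers(0, max(1, w - dw)))
            y = int(rng.integers(0, max(1, h - dh)))
            if x < fx1 and x + dw > fx0 and y < fy1 and y + dh > fy0:
                continue
            intensity = int(rng.integers(80, 211))
            if rng.random() < 0.5:
                image[y : y + dh, x : x + dw] = np.minimum(
                    image[y : y + dh, x : x + dw], intensity
                )
            else:
                yy, xx = np.mgrid[0:dh, 0:dw]
                mask = (
                    ((yy - dh / 2) / (dh / 2)) ** 2 + ((xx - dw / 2) / (dw / 2)) ** 2
                ) <= 1.0
                sub = image[y : y + dh, x : x + dw]
                sub[mask] = np.minimum(sub[mask], intensity)
            break


@dataclasses.dataclass(frozen=True)
class CorpusProfile:
    """Parameter ranges a corpus is drawn from.

    Defaults describe a vascular-plant digitization station: 24-Mpx frames,
    catalog numbers of 2-5 letters + 6-9 digits, barcode modules 2-5 px,
    arbitrary rotation, mild optical blur and sensor noise, a handful of
    distractor shapes.
    """

    image_size: tuple[int, int] = (4000, 6000)
    symbologies: tuple[str, ...] = ("code128", "code39")
    module_widths: tuple[int, ...] = (2, 3, 4, 5)
    n_letters: tuple[int, int] = (2, 5)  # inclusive range
    n_digits: tuple[int, int] = (6, 9)
    bar_height: tuple[int, int] = (120, 200)
    rotation: tuple[float, float] = (0.0, 360.0)
    noise_sigma: tuple[float, float] = (1.0, 5.0)
    blur_sigma: tuple[float, float] = (0.2, 0.8)
    n_distractors: tuple[int, int] = (3, 8)


_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def draw_specs(n: int, seed: int, profile: CorpusProfile | None = None) -> list[SyntheticSpec]:
    """Draw n deterministic, order-stable specimen specs from a profile.

    Each spec's own seed is derived from (seed, index), so rendering item k
    does not depend on how many items precede it.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    profile = profile or CorpusProfile()
    h, w = profile.image_size
    specs = []
    for i in range(n):
        rng = np.random.default_rng([seed, i])
        nl = int(rng.integers(profile.n_letters[0], profile.n_letters[1] + 1))
        nd = int(rng.integers(profile.n_digits[0], profile.n_digits[1] + 1))
        value = "".join(rng.choice(list(_LETTERS), nl)) + "".join(
            rng.choice(list("0123456789"), nd)
        )
        symbology = str(rng.choice(profile.symbologies))
        module_width = int(rng.choice(profile.module_widths))
        bar_height = int(rng.integers(profile.bar_height[0], profile.bar_height[1] + 1))
        rotation = float(rng.uniform(*profile.rotation))
        spec = SyntheticSpec(
            image_size=profile.image_size,
            value=value,
            symbology=symbology,
            module_width=module_width,
            bar_height=bar_height,
            rotation_deg=rotation,
            noise_sigma=float(rng.uniform(*profile.noise_sigma)),
            blur_sigma=float(rng.uniform(*profile.blur_sigma)),
            n_distractors=int(
                rng.integers(profile.n_distractors[0], profile.n_distractors[1] + 1)
            ),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        # place so the rotated patch fits: margin = half-diagonal + safety
        ph, pw = _barcode_patch(spec).shape
        margin = math.hypot(ph, pw) / 2 + 8
        if 2 * margin >= min(h, w):
            raise ValueError("barcode too large for the profile's image size")
        cx = float(rng.uniform(margin, w - margin))
        cy = float(rng.uniform(margin, h - margin))
        specs.append(dataclasses.replace(spec, position=(cx, cy)))
    return specs


def make_corpus(
    n: int, seed: int, profile: CorpusProfile | None = None
) -> list[tuple[GrayImage, GroundTruth]]:
    """Render a corpus eagerly (memory O(n x image); for large corpora
    iterate ``draw_specs`` and render one spec at a time instead)."""
    return [render_specimen(s) for s in draw_specs(n, seed, profile)]


def write_corpus(
    n: int, seed: int, out_dir: str | Path, profile: CorpusProfile | None = None
) -> Path:
    """Write corpus PNGs plus a manifest CSV; returns the manifest path."""
    from .image_io import save_grayscale

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with manifest.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["filename", "value", "symbology", "rotation_deg", "module_width", "seed"]
        )
        for i, spec in enumerate(draw_specs(n, seed, profile)):
            image, gt = render_specimen(spec)
            name = f"specimen_{i:04d}.png"
            save_grayscale(image, out_dir / name)
            writer.writerow(
                [name, gt.value, gt.symbology,
                 f"{gt.rotation_deg:.2f}", spec.module_width, spec.seed]
            )
    return manifest
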