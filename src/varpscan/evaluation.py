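"""Benchmark harness: success-by-regex, median-of-5 timing, baselines.

Success is judged by pattern matching with a collection-specific regular
expression rather than string equality: digitization corpora contain records
whose stored catalog number disagrees with the physically attached barcode,
so "decoded something with the right format" is the operationally meaningful
criterion, and extraneous decodes are ignored as long as one value matches.

Timing follows a median-of-k protocol with the method evaluation order
randomized per image.  Times are reported, never asserted: they are
hardware-dependent.

Two reference baselines bracket the design space: rotate-retry (line scan
the full frame, rotating it stepwise until something decodes — the classic
workaround for line scanning's rotational variance) and upscale-retry
(re-scan at increasing scale factors, which fixes undersampling but can
never fix rotation).  Both reuse the in-repo decoder on raw rows/columns so
the comparison isolates strategy, not backend.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
import statistics
import time
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from skimage.transform import rescale as _rescale
from skimage.transform import rotate as _rotate

from .image_io import GrayImage
from .linescan_decoder import (
    DecodedBarcode,
    DecoderConfig,
    binarize_scanline,
    decode_runs,
)
from .pipeline import DecodeResult, decode_image
from .synthetic_data import GroundTruth

__all__ = [
    "BenchmarkResult",
    "is_success",
    "run_benchmark",
    "line_scan_raw",
    "baseline_rotate_retry",
    "baseline_upscale_retry",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class BenchmarkResult:
    method: str
    n_images: int
    n_success: int
    success_rate: float
    median_time_success_s: float | None
    median_time_failure_s: float | None
    median_time_combined_s: float | None
    median_reduction: float | None = None  # composite methods only


def _values_of(decoded) -> set[str]:
    if isinstance(decoded, DecodeResult):
        return decoded.texts
    return {d.value if isinstance(d, DecodedBarcode) else str(d) for d in decoded}


def is_success(decoded, pattern: str | re.Pattern) -> bool:
    """True iff at least one decoded value fully matches the pattern.

    Extraneous decodes never hurt: one correctly formatted value suffices.
    """
    pattern = re.compile(pattern)
    return any(pattern.fullmatch(v) for v in _values_of(decoded))


def line_scan_raw(
    image: GrayImage, config: DecoderConfig | None = None, stride: int = 2
) -> set[DecodedBarcode]:
    """Single-pass traditional line scan: every stride-th row AND column."""
    config = config or DecoderConfig()
    found: dict[tuple[str, str], DecodedBarcode] = {}
    px = image.pixels
    for axis_pixels in (px, px.T):
        for i in range(0, axis_pixels.shape[0], stride):
            runs = binarize_scanline(axis_pixels[i])
            if not runs:
                continue
            for r in decode_runs(runs, config):
                found.setdefault((r.value, r.symbology), r)
    return set(found.values())


def baseline_rotate_retry(
    image: GrayImage,
    config: DecoderConfig | None = None,
    angles: Sequence[float] = tuple(range(0, 360, 15)),
    stride: int = 2,
) -> set[DecodedBarcode]:
    """Rotate the full-scale image stepwise, line scanning after each step."""
    for angle in angles:
        if angle % 360 == 0:
            rotated = image
        else:
            arr = _rotate(
                image.pixels, angle, resize=True, order=1, cval=1.0,
                mode="constant", preserve_range=False,
            )
            rotated = GrayImage(np.clip(np.round(arr * 255), 0, 255).astype(np.uint8))
        found = line_scan_raw(rotated, config, stride=stride)
        if found:
            return found
    return set()


def baseline_upscale_retry(
    image: GrayImage,
    config: DecoderConfig | None = None,
    scales: Sequence[float] = (1.0, 1.25, 1.5, 2.0),
    stride: int = 2,
) -> set[DecodedBarcode]:
    """Re-scan at increasing scale factors until line scanning succeeds."""
    for scale in scales:
        if scale == 1.0:
            scaled = image
        else:
            arr = _rescale(image.pixels, scale, order=1, preserve_range=True)
            scaled = GrayImage(np.clip(np.round(arr), 0, 255).astype(np.uint8))
        found = line_scan_raw(scaled, config, stride=stride)
        if found:
            return found
    return set()


Method = Callable[[GrayImage], object]


def run_benchmark(
    corpus: Iterable[tuple[GrayImage, GroundTruth]],
    methods: dict[str, Method] | None = None,
    pattern: str | re.Pattern = r"[A-Z]{2,5}[0-9]{6,9}",
    repeats: int = 5,
    seed: int = 0,
    log_path: str | Path | None = None,
) -> list[BenchmarkResult]:
    """Time and score every method on every corpus image.

    Per image, the method order is shuffled (from ``seed``) and each method
    runs ``repeats`` times; the per-image time is the median of those runs.
    A method that raises is logged and counted as a failure for that image,
    never aborting the benchmark.  Success depends only on the decode set,
    so it is invariant to ``repeats`` and to the shuffling seed.
    """
    methods = methods or {"varp": decode_image}
    rng = np.random.default_rng(seed)
    times: dict[str, dict[bool, list[float]]] = {m: {True: [], False: []} for m in methods}
    successes: dict[str, int] = {m: 0 for m in methods}
    reductions: dict[str, list[float]] = {m: [] for m in methods}
    n_images = 0
    log_lines = []
    for image, gt in corpus:
        n_images += 1
        order = list(methods)
        rng.shuffle(order)
        for name in order:
            fn = methods[name]
            elapsed = []
            result: object = set()
            for _ in range(repeats):
                t0 = time.perf_counter()
                try:
                    result = fn(image)
                except Exception:
                    logger.exception("method %s failed on %r", name, gt.value)
                    result = set()
                elapsed.append(time.perf_counter() - t0)
            ok = is_success(result, pattern)
            successes[name] += ok
            times[name][ok].append(statistics.median(elapsed))
            if isinstance(result, DecodeResult) and result.reduction is not None:
                reductions[name].append(result.reduction)
            log_lines.append(
                json.dumps(
                    {"method": name, "truth": gt.value, "success": ok,
                     "values": sorted(_values_of(result)),
                     "median_time_s": statistics.median(elapsed)}
                )
            )
    if log_path is not None:
        Path(log_path).write_text("\n".join(log_lines) + "\n")

    results = []
    for name in methods:
        ok_t, fail_t = times[name][True], times[name][False]
        results.append(
            BenchmarkResult(
                method=name,
                n_images=n_images,
                n_success=successes[name],
                success_rate=successes[name] / n_images if n_images else 0.0,
                median_time_success_s=statistics.median(ok_t) if ok_t else None,
                median_time_failure_s=statistics.median(fail_t) if fail_t else None,
                median_time_combined_s=(
                    statistics.median(ok_t + fail_t) if (ok_t or fail_t) else None
                ),
                median_reduction=(
                    statistics.median(reductions[name]) if reductions[name] else None
                ),
            )
        )
    return results


def results_to_csv(results: list[BenchmarkResult], path: str | Path) -> None:
    """Write benchmark results as a CSV table."""
    import pandas as pd

    pd.DataFrame([dataclasses.asdict(r) for r in results]).to_csv(path, index=False)
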