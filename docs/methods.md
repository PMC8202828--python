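# Methods

## Problem and approach

Digitization of herbarium sheets produces very-high-resolution images
(commonly more than 24 Mpx) in which a small 1-D barcode (Code 39 or
Code 128) carries the specimen's catalog number. Conventional line scanning —
matching bar/space patterns along raw image rows and columns — degrades badly
here: the barcode is a tiny fraction of the frame, so nearly every scanned
pixel is wasted, and the technique is rotationally variant, failing outright
whenever the barcode does not lie along a row or column.

`varpscan` implements vector-assisted region proposal (VARP). The pipeline
is:

1. **Contour proposals.** Binarize the grayscale image and find
   rectangle-like dark contours. A 1-D barcode is a stack of solid
   rectangles, so each *bar* is itself a detection target; labels and rulers
   are also rectangles and simply produce harmless extra proposals. Contour
   detection does not depend on orientation, which is where the method's
   rotational invariance comes from.
2. **Scan vectors.** For each rectangle, emit a segment through its centroid
   perpendicular to its long axis (through the midpoints of the opposite
   long edges), extended to a total of `floor(2 f d)` pixels, where `d` is
   the image's smaller dimension and `f` is the extension fraction (default
   1/6 per side). A vector seeded on any bar then crosses the whole bar
   pattern. With `f = 1/6` and `d = 4000` the nominal traversal is 1333
   cells.
3. **Composite.** Each vector is rasterized by 8-connected Bresenham
   traversal and its intensities become one column of a composite matrix
   (width = number of vectors, height = longest scanline, shorter columns
   padded with white). Oblique traversal stretches bar widths uniformly by
   sec(theta); since only width *ratios* carry the code, this is harmless,
   and no intensity interpolation is performed.
4. **Column-wise decoding.** Every column is binarized at the midpoint of
   its own intensity range, run-length encoded, and passed to the Code 128
   and Code 39 decoders in both scan directions. Rows are never scanned. If
   nothing decodes, the original composite is re-scanned under an escalating
   contrast/brightness schedule.

The composite for a 4000x6000 source with 200 proposals is 200x1333 px —
a 98.9% reduction in pixels evaluated by the expensive decoding step.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `extension_fraction` | 1/6 | per-side vector extension relative to the smaller image dimension; raise it for collections whose barcodes occupy a larger fraction of the frame (packet/label close-ups) |
| `min/max_rect_area_frac` | 5e-6 / 1e-2 | contour area band relative to image area; admits single bars through label blocks, rejects specks and the full sheet |
| `approx_epsilon_frac` | 0.04 | polygon-approximation tolerance as a fraction of contour perimeter (see below) |
| `min_fill_ratio` | 0.8 | contour area over its minimum-area bounding rectangle; the main rectangularity test |
| `binarization` | otsu | global Otsu; `adaptive` (mean, block 51, offset 10) for unevenly lit sheets |
| `fallback_schedule` | (1.0,0) (1.3,10) (1.6,20) (2.0,40) (3.0,60) | (gain, offset) enhancement steps, each applied to the original composite, never cumulatively, stopping at the first step that decodes |
| `min_value_length` | 4 | suppresses spurious 1-2 character decodes from noise runs |
| `code39_checksum` | off | most herbarium Code 39 labels omit the optional mod-43 check character |

The geometric precondition worth knowing: the barcode's bar span must fit
within one vector, i.e. be at most `floor(2 f d)` pixels. With defaults that
means a barcode can occupy up to about a third of the image's smaller
dimension — comfortably true for sheet-format collections, and the reason
`extension_fraction` is exposed for everything else.

## Numerical and design choices

- **Vector length arithmetic.** The nominal traversal is
  `floor(2 * extension_fraction * smaller_dim)` *cells*; endpoints are
  placed `(n-1)/2` either side of the centroid so an axis-aligned Bresenham
  walk visits exactly `n` cells (Euclidean endpoint separation `n-1`).
  Oblique vectors visit fewer cells (`max(|dx|,|dy|)+1`) while covering the
  same geometric span. Endpoints are clipped to bounds parametrically
  (Liang-Barsky); the nominal length depends only on the image dimension,
  never on rectangle size, so behaviour is stable across resolutions.
- **Which edge pair defines the vector.** A rectangle has two parallel edge
  pairs; the vector uses the midpoints of the *long*-edge pair, i.e. runs
  across the bars. A vector along the bar's long axis would never traverse
  the pattern.
- **Polygon approximation tolerance.** A perimeter-relative
  Douglas-Peucker epsilon collapses thin bars (the short side is smaller
  than the epsilon), so the tolerance is clamped to 0.6 of the short-side
  estimate `2 * area / perimeter`. Rasterized rotated rectangles can retain
  a staircase corner after approximation, so 4-6 convex vertices are
  accepted; non-rectangles that slip through (ellipse fill ratio is pi/4)
  are rejected by the 0.8 fill-ratio test.
- **Symbol classification.** Code 128 symbols are first classified by
  rounding each run to modules against the 6-run group's own 11-module
  total; on a table miss, classification falls back to edge-to-similar-edge
  sums (w_i + w_{i+1}), which are invariant to the uniform bar-widening /
  space-narrowing a biased threshold produces and which happen to identify
  every Code 128 symbol uniquely. Code 39 groups classify bars and spaces
  against their own width ranges for the same reason, and require the
  (2 wide bars, 1 wide space) or (0, 3) structure of the symbology. These
  choices are what make 2-px modules decodable after bilinear rotation and
  blur.
- **Checksums.** Code 128 requires the mod-103 check symbol; every
  single-symbol substitution is rejected (verified by brute-force
  perturbation). Code 39's mod-43 check is optional and off by default.
- **Duplicate proposals are kept.** A barcode crossed by k vectors yields k
  columns and one deduplicated result; merging near-duplicate proposals
  would only add failure modes.
- **Degenerate inputs.** Flat scanlines (intensity range < 16) are
  undecodable, not errors; zero-length rectangle edges are skipped with a
  warning; an empty proposal list yields a distinct "no composite" signal
  rather than an exception.

## Synthetic data

The generator emulates what the method's operating conditions require:
large frames (default 4000x6000), one barcode whose center, rotation
(uniform on [0, 360)), module width (2-5 px) and payload (2-5 letters +
6-9 digits, catalog-number shaped) vary per image; gray rectangle/ellipse
distractors that never overlap the barcode; Gaussian blur (sigma 0.2-0.8 px)
then sensor noise (sigma 1-5) applied after rotation so bar edges degrade
realistically. Every image is a pure function of its spec, and per-item
seeds are derived from (corpus seed, index), so corpora are deterministic
and order-stable.

It does **not** emulate plant material texture, uneven illumination, lens
distortion, JPEG artifacts, or damaged/occluded barcodes. Results on this
corpus demonstrate the geometry and decoding logic under controlled
degradation; they are not a claim about any particular real collection.

## Evaluation protocol

Success is "at least one decoded value fully matches the collection's
catalog-number regular expression"; extraneous decodes are ignored. Timing
uses a median-of-5 protocol with method order randomized per image, and is
reported but never asserted (hardware-dependent). Baselines: rotate-retry
(full-frame row+column scan, retried at 15-degree steps) and upscale-retry
(factors 1.0/1.25/1.5/2.0); both reuse the in-repo decoder so the comparison
isolates strategy from backend. On a 45-degree specimen the single-pass scan
fails, rotate-retry recovers at a cost, upscale-retry cannot recover, and
the composite pipeline succeeds directly.

Problem sizes used by the test suite: decoder round trips run on rendered
scanlines (500 payloads per symbology, lengths 4-20, modules 2-5);
rotational invariance uses 24 angles at 2000x3000; the end-to-end benchmark
uses a seed-fixed 100-image corpus at the full 4000x6000 default, on which
at least 95/100 decode and the median resolution reduction exceeds 0.95.

## Known limitations

- Barcodes longer than the nominal vector (relative barcode span above
  ~1/3 of the smaller dimension at defaults) require raising
  `extension_fraction`.
- Position information is deliberately discarded when the composite is
  built; mapping decodes back to source coordinates would require retaining
  per-column vector coordinates (feasible, not implemented).
- Only Code 39 and Code 128 are supported; EAN/UPC, Interleaved 2-of-5 and
  2-D symbologies are out of scope.
- The rectangle filter assumes dark bars on a light background.
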