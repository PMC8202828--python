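"""End-to-end decode: propose vectors, composite, line-scan.

This is the vector-assisted region proposal (VARP) pipeline in one call:
rectangle contours -> scan vectors -> composite image -> column-wise
decoding with enhancement fallbacks.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

from .composite import build_composite, resolution_reduction
from .contour_proposals import ProposalConfig, propose_vectors
from .image_io import GrayImage, load_grayscale
from .linescan_decoder import DecodedBarcode, DecoderConfig, decode_composite

__all__ = ["DecodeResult", "decode_image"]


@dataclasses.dataclass(frozen=True)
class DecodeResult:
    values: frozenset[DecodedBarcode]
    n_vectors: int
    reduction: float | None  # None when no vectors were proposed

    @property
    def texts(self) -> set[str]:
        return {v.value for v in self.values}


def decode_image(
    image: GrayImage | str | Path,
    proposal_config: ProposalConfig | None = None,
    decoder_config: DecoderConfig | None = None,
) -> DecodeResult:
    """Decode every readable barcode in a specimen image.

    Accepts an in-memory grayscale image or a path to a JPEG/PNG/TIFF file.
    Returns the deduplicated decode set together with the number of proposal
    vectors and the resolution reduction achieved by compositing (the
    fraction of source pixels never line-scanned).
    """
    if not isinstance(image, GrayImage):
        image = load_grayscale(image)
    vectors = propose_vectors(image, proposal_config)
    comp = build_composite(image, vectors)
    if comp is None:
        return DecodeResult(frozenset(), 0, None)
    values = decode_composite(comp, decoder_config)
    return DecodeResult(frozenset(values), len(vectors), resolution_reduction(image, comp))
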