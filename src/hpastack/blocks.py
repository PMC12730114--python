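"""Feature-block registry, extraction and block-matrix assembly.

A *feature block* is the 1000-value output of one registered extractor
applied to one source image.  At the image level the source is one of the
six channel compositions (12 extractors x 6 compositions = 72 blocks); at
the cell level the source is the nucleus crop or the perinuclear-ring crop
of the green channel (12 x 2 = 24 blocks).  Block matrices store samples in
rows with columns grouped per block in a canonical, serialized order —
chromosomes are meaningless without it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, NamedTuple, Sequence

import numpy as np

from .preprocess import (
    COMPOSITION_MODES,
    CompositionMode,
    ExtractorInputSpec,
    compose,
    input_spec_for,
    resize_for,
)
from .synth import MOCK_OUTPUT_DIM, MockExtractorSpec, mock_extract

BLOCK_DIM = 1000

# Canonical extractor registry order (fixed; written into every artifact).
EXTRACTOR_NAMES: tuple[str, ...] = (
    "alexnet",
    "vgg16",
    "vgg19",
    "mobilenet_v2",
    "squeezenet",
    "resnet18",
    "googlenet",
    "resnet50",
    "inception_v3",
    "resnet101",
    "densenet201",
    "inception_resnet_v2",
)

CELL_SOURCES: tuple[str, ...] = ("nucleus", "ring")


class BlockId(NamedTuple):
    extractor_name: str
    source: str  # a CompositionMode value (image level) or "nucleus"/"ring"

    def __str__(self) -> str:
        return f"{self.extractor_name}:{self.source}"

    @classmethod
    def parse(cls, text: str) -> "BlockId":
        name, source = text.split(":", 1)
        return cls(name, source)


def image_level_block_ids() -> list[BlockId]:
    """All 72 image-level blocks: extractor-major, composition-minor order."""
    return [
        BlockId(name, mode.value)
        for name in EXTRACTOR_NAMES
        for mode in COMPOSITION_MODES
    ]


def cell_level_block_ids() -> list[BlockId]:
    """All 24 cell-level blocks: extractor-major, (nucleus, ring) order."""
    return [
        BlockId(name, src) for name in EXTRACTOR_NAMES for src in CELL_SOURCES
    ]


@dataclass
class ExtractorBackend:
    """One extractor behind the uniform 1000-d contract.

    ``kind`` is ``"mock"`` for the deterministic stand-in used throughout the
    test surface, or ``"pretrained_backbone"`` for an optional real CNN
    plugin supplying its own ``extract_fn``.
    """

    name: str
    input_spec: ExtractorInputSpec
    kind: str = "mock"
    extract_fn: Callable[[np.ndarray], np.ndarray] | None = None
    mock_spec: MockExtractorSpec | None = None

    def extract(self, image3: np.ndarray) -> np.ndarray:
        if self.kind == "mock":
            spec = self.mock_spec or MockExtractorSpec(name=self.name)
            return mock_extract(spec, image3)
        if self.extract_fn is None:
            raise RuntimeError(
                f"backend {self.name!r} is {self.kind} but has no extract_fn; "
                "pretrained backbones are optional plugins"
            )
        return np.asarray(self.extract_fn(image3), dtype=np.float64)


def mock_backends(
    seed: int = 0, signal_extractors: Sequence[str] = ("densenet201",)
) -> dict[str, ExtractorBackend]:
    """The full 12-extractor registry backed by mock extractors.

    ``signal_extractors`` names the extractors whose mock carries image
    signal; the rest emit constant pseudo-noise (non-informative).
    """
    backends = {}
    for name in EXTRACTOR_NAMES:
        signal = frozenset(range(28)) if name in signal_extractors else frozenset()
        backends[name] = ExtractorBackend(
            name=name,
            input_spec=input_spec_for(name),
            kind="mock",
            mock_spec=MockExtractorSpec(name=name, seed=seed, signal_classes=signal),
        )
    return backends


def extract_block(backend: ExtractorBackend, image3: np.ndarray) -> np.ndarray:
    """Run one backend on one prepared image; enforce the 1000-d contract."""
    vec = np.asarray(backend.extract(image3), dtype=np.float64).ravel()
    if vec.shape[0] != BLOCK_DIM:
        raise ValueError(
            f"backend {backend.name!r} returned {vec.shape[0]} values, "
            f"expected {BLOCK_DIM}"
        )
    return vec


@dataclass
class BlockMatrix:
    """Samples x concatenated-blocks matrix with its serialized block order."""

    sample_ids: tuple[str, ...]
    block_order: tuple[BlockId, ...]
    values: np.ndarray  # (n_samples, BLOCK_DIM * n_blocks) float32

    def __post_init__(self) -> None:
        expected = (len(self.sample_ids), BLOCK_DIM * len(self.block_order))
        if tuple(self.values.shape) != expected:
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.block_order)} blocks"
            )

    @property
    def n_blocks(self) -> int:
        return len(self.block_order)

    def rows_for(self, ids: Sequence[str]) -> "BlockMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in ids]
        return BlockMatrix(
            sample_ids=tuple(ids),
            block_order=self.block_order,
            values=self.values[idx],
        )

    def save(self, path) -> None:
        header = {
            "sample_ids": list(self.sample_ids),
            "block_order": [str(b) for b in self.block_order],
            "block_dim": BLOCK_DIM,
        }
        np.savez_compressed(
            path, values=self.values, header=np.frombuffer(
                json.dumps(header).encode(), dtype=np.uint8
            )
        )

    @classmethod
    def load(cls, path) -> "BlockMatrix":
        with np.load(path) as data:
            header = json.loads(bytes(data["header"].tobytes()).decode())
            values = data["values"]
        return cls(
            sample_ids=tuple(header["sample_ids"]),
            block_order=tuple(BlockId.parse(b) for b in header["block_order"]),
            values=values,
        )


def default_image_provider(backends: dict[str, ExtractorBackend]):
    """Image-level provider: compose the channel mode, resize per backend."""

    def provider(sample, block_id: BlockId) -> np.ndarray:
        backend = backends[block_id.extractor_name]
        img = compose(sample, CompositionMode(block_id.source))
        return resize_for(img, backend.input_spec)

    return provider


def build_matrix(
    samples: Sequence,
    block_ids: Sequence[BlockId],
    backends: dict[str, ExtractorBackend],
    image_provider: Callable | None = None,
) -> BlockMatrix:
    """Extract the requested blocks for every sample into one matrix.

    ``image_provider(sample, block_id)`` supplies the prepared 3-plane input
    for each (sample, block); the default handles image-level composition
    sources.  Cell-level callers pass a provider that crops nucleus/ring ROIs.
    """
    provider = image_provider or default_image_provider(backends)
    for bid in block_ids:
        if bid.extractor_name not in backends:
            raise KeyError(f"no backend registered for block {bid}")
    rows = []
    for sample in samples:
        parts = []
        for bid in block_ids:
            try:
                img = provider(sample, bid)
                parts.append(extract_block(backends[bid.extractor_name], img))
            except Exception as exc:
                sid = getattr(sample, "sample_id", sample)
                raise RuntimeError(
                    f"feature extraction failed for sample {sid!r}, block {bid}"
                ) from exc
        rows.append(np.concatenate(parts))
    return BlockMatrix(
        sample_ids=tuple(getattr(s, "sample_id", str(s)) for s in samples),
        block_order=tuple(block_ids),
        values=np.asarray(rows, dtype=np.float32),
    )


def slice_by_chromosome(matrix: BlockMatrix, chromosome) -> BlockMatrix:
    """Keep only the blocks flagged 1 in the chromosome (order preserved)."""
    chrom = np.asarray(chromosome, dtype=np.uint8)
    if chrom.shape[0] != matrix.n_blocks:
        raise ValueError(
            f"chromosome length {chrom.shape[0]} != {matrix.n_blocks} blocks"
        )
    if not chrom.any():
        raise ValueError("no blocks selected: all-zero chromosome")
    keep = np.flatnonzero(chrom)
    cols = np.concatenate(
        [np.arange(b * BLOCK_DIM, (b + 1) * BLOCK_DIM) for b in keep]
    )
    return BlockMatrix(
        sample_ids=matrix.sample_ids,
        block_order=tuple(matrix.block_order[b] for b in keep),
        values=matrix.values[:, cols],
    )
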