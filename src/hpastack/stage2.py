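"""Second-level (stacked) features from the stage-1 OAO classifiers.

For one sample the *image-level* second-level vector is the calibrated
pairwise-score vector of the image-level OAO model set (length N(N-1)/2; 276
at N=24).  The *cell-level* vector applies the cell-level OAO models to every
valid segmented nucleus (nucleus crop + perinuclear-ring crop of the green
channel) and averages the score vectors element-wise across cells.  The two
vectors concatenate — image first — into the fused representation (552 at
N=24).  No further standardization is applied: the stacked features are
already calibrated probabilities in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .blocks import BlockId, build_matrix, cell_level_block_ids, image_level_block_ids
from .preprocess import resize_for
from .segment import (
    NucleusROI,
    SegmentationBackend,
    crop_roi,
    filter_rois,
    ring_from_nucleus,
    segment_nuclei,
)
from .stage1 import OAOModelSet, oao_input, oao_scores

NEUTRAL_SCORE = 0.5  # calibrated pairwise probability carrying no evidence


@dataclass
class SecondLevelVector:
    level: str  # image | cell | combined
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)


@dataclass
class CellAggregation:
    n_cells_used: int
    per_cell_vectors: list[np.ndarray]
    aggregate: np.ndarray
    fallback_used: bool = False


def selected_block_ids(all_ids: list[BlockId], chromosome) -> list[BlockId]:
    chrom = np.asarray(chromosome, dtype=np.uint8)
    if chrom.shape[0] != len(all_ids):
        raise ValueError(f"chromosome length {chrom.shape[0]} != {len(all_ids)}")
    if not chrom.any():
        raise ValueError("all-zero chromosome selects no blocks")
    return [b for b, bit in zip(all_ids, chrom) if bit]


def image_level_features(
    sample, image_chromosome, backends, oao_image_models: OAOModelSet
) -> SecondLevelVector:
    """Stacked pairwise scores of the image-level OAO models for one sample."""
    block_ids = selected_block_ids(image_level_block_ids(), image_chromosome)
    row = build_matrix([sample], block_ids, backends).values
    scores = oao_scores(oao_image_models, oao_input(oao_image_models, row))[0]
    return SecondLevelVector(level="image", values=scores)


@dataclass
class _CellInstance:
    """One (sample, nucleus) pair exposing nucleus/ring crops as sources."""

    sample_id: str
    images: dict  # source -> 2-D uint8 crop


def cell_instances(
    sample,
    seg_backend: SegmentationBackend | None = None,
    min_area: int = 100,
    rois: list[NucleusROI] | None = None,
) -> list[_CellInstance]:
    """Segment + filter nuclei and build per-cell nucleus/ring green crops."""
    if rois is None:
        rois = segment_nuclei(sample.channels["blue"], seg_backend)
    valid = filter_rois(rois, min_area=min_area, exclude_border=True)
    green = sample.channels["green"]
    instances = []
    for roi in valid:
        ring = ring_from_nucleus(roi.mask, parent_roi_id=roi.roi_id)
        if not ring.mask.any():
            continue
        instances.append(
            _CellInstance(
                sample_id=f"{sample.sample_id}#roi{roi.roi_id}",
                images={
                    "nucleus": crop_roi(green, roi.mask),
                    "ring": crop_roi(green, ring.mask),
                },
            )
        )
    return instances


def cell_image_provider(backends):
    """Provider mapping a cell instance + block id to the resized 3-plane crop."""

    def provider(instance: _CellInstance, block_id: BlockId) -> np.ndarray:
        crop = instance.images[block_id.source]
        img3 = np.repeat(np.asarray(crop, dtype=np.uint8)[..., None], 3, axis=-1)
        return resize_for(img3, backends[block_id.extractor_name].input_spec)

    return provider


def cell_level_features(
    sample,
    cell_chromosome,
    backends,
    oao_cell_models: OAOModelSet,
    seg_backend: SegmentationBackend | None = None,
    min_area: int = 100,
) -> tuple[SecondLevelVector, CellAggregation]:
    """Mean stacked score vector across all valid segmented cells.

    An image whose nuclei are all filtered out yields the neutral 0.5 vector
    with ``fallback_used`` flagged.
    """
    n_pairs = len(oao_cell_models.pairs)
    instances = cell_instances(sample, seg_backend, min_area=min_area)
    if not instances:
        agg = CellAggregation(
            n_cells_used=0,
            per_cell_vectors=[],
            aggregate=np.full(n_pairs, NEUTRAL_SCORE),
            fallback_used=True,
        )
        return SecondLevelVector(level="cell", values=agg.aggregate), agg
    block_ids = selected_block_ids(cell_level_block_ids(), cell_chromosome)
    rows = build_matrix(
        instances, block_ids, backends, image_provider=cell_image_provider(backends)
    ).values
    scores = oao_scores(oao_cell_models, oao_input(oao_cell_models, rows))
    agg = CellAggregation(
        n_cells_used=len(instances),
        per_cell_vectors=[scores[i] for i in range(scores.shape[0])],
        aggregate=scores.mean(axis=0),
    )
    return SecondLevelVector(level="cell", values=agg.aggregate), agg


def fuse(image_vec: SecondLevelVector, cell_vec: SecondLevelVector) -> SecondLevelVector:
    """Concatenate image-level then cell-level stacked features."""
    a = np.asarray(image_vec.values)
    b = np.asarray(cell_vec.values)
    if a.shape != b.shape:
        raise ValueError(f"level lengths differ: {a.shape} vs {b.shape}")
    return SecondLevelVector(level="combined", values=np.concatenate([a, b]))
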