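"""Two-phase pipeline orchestration.

Phase 1 works on the single-label subset: a class-balanced capped split,
feature-block matrices at image level (selected channel compositions x
extractors) and at cell level (nucleus + perinuclear-ring crops of one
representative median-area cell per image), and OAO linear-SVM model sets
with cross-validated C.  Phase 2 stacks the frozen phase-1 OAO outputs into
second-level features for *every* sample (all valid cells, not just the
representative one), splits the multi-label data by iterative stratification
with the phase-1 training ids pinned to the training side, and runs
BR/LP multi-label classification at image, cell and combined level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .blocks import (
    BlockMatrix,
    build_matrix,
    cell_level_block_ids,
    image_level_block_ids,
    mock_backends,
)
from .io import DatasetIndex, SplitSpec, phase1_split
from .multilabel import (
    BaseLearner,
    MetricsReport,
    evaluate,
    fit_predict_multilabel,
    iterative_stratified_split,
)
from .segment import SegmentationBackend, filter_rois, representative_cell, segment_nuclei
from .stage1 import CVPlan, OAOModelSet, train_oao
from .stage2 import (
    cell_image_provider,
    cell_instances,
    cell_level_features,
    fuse,
    image_level_features,
    selected_block_ids,
)


@dataclass
class Phase1Result:
    split: SplitSpec
    image_chromosome: np.ndarray
    cell_chromosome: np.ndarray
    image_models: OAOModelSet
    cell_models: OAOModelSet
    cell_sample_ids: tuple[str, ...] = ()


@dataclass
class Phase2Result:
    split: SplitSpec
    reports: dict[str, dict[str, MetricsReport]]  # level -> strategy/base -> report
    features: dict[str, np.ndarray] = field(default_factory=dict)


def _labels_of(index: DatasetIndex, ids):
    return [index[i].labels for i in ids]


def _single_labels_of(index: DatasetIndex, ids) -> np.ndarray:
    return np.array([next(iter(index[i].labels)) for i in ids])


def build_image_matrix(index, ids, chromosome, backends) -> BlockMatrix:
    block_ids = selected_block_ids(image_level_block_ids(), chromosome)
    samples = [index[i] for i in ids]
    return build_matrix(samples, block_ids, backends)


def build_cell_matrix(
    index,
    ids,
    chromosome,
    backends,
    seg_backend: SegmentationBackend | None = None,
    min_area: int = 100,
) -> BlockMatrix:
    """Representative-cell matrix: one median-area nucleus per image.

    Samples whose nuclei are all filtered out are dropped (their ids are not
    in the returned matrix).
    """
    block_ids = selected_block_ids(cell_level_block_ids(), chromosome)
    instances = []
    kept_ids = []
    for i in ids:
        sample = index[i]
        rois = filter_rois(
            segment_nuclei(sample.channels["blue"], seg_backend), min_area=min_area
        )
        if not rois:
            continue
        rep = representative_cell(rois)
        inst = cell_instances(sample, seg_backend, min_area=min_area, rois=[rep])
        if inst:
            kept_ids.append(i)
            instances.append(inst[0])
    matrix = build_matrix(
        instances, block_ids, backends, image_provider=cell_image_provider(backends)
    )
    return BlockMatrix(
        sample_ids=tuple(kept_ids),
        block_order=matrix.block_order,
        values=matrix.values,
    )


def planted_cell_matrix(
    index: DatasetIndex,
    ids,
    informative_blocks,
    seed: int = 0,
    seg_backend: SegmentationBackend | None = None,
    min_area: int = 100,
    signal_stats: tuple[int, ...] | None = (0,),
) -> BlockMatrix:
    """Cell-level block matrix where only chosen blocks carry class signal.

    Used for planted-recovery studies of the GA: each of the 24 cell-level
    blocks is backed by its own mock extractor, and only the blocks listed in
    ``informative_blocks`` encode image statistics — the rest are constant
    pseudo-noise.  Informative blocks are restricted to a narrow statistic
    slice (mean intensity by default) so that single blocks are genuinely
    insufficient and the GA must combine complementary nucleus/ring sources.
    One representative (median-area) cell per image.
    """
    from .synth import MockExtractorSpec, mock_extract

    informative = set(informative_blocks)
    block_ids = cell_level_block_ids()
    specs = {
        bid: MockExtractorSpec(
            name=f"{bid.extractor_name}@{bid.source}",
            seed=seed,
            signal_classes=frozenset(range(28)) if bid in informative else frozenset(),
            signal_stats=signal_stats if bid in informative else None,
        )
        for bid in block_ids
    }
    rows, kept_ids = [], []
    for i in ids:
        sample = index[i]
        rois = filter_rois(
            segment_nuclei(sample.channels["blue"], seg_backend), min_area=min_area
        )
        if not rois:
            continue
        rep = representative_cell(rois)
        inst = cell_instances(sample, seg_backend, min_area=min_area, rois=[rep])
        if not inst:
            continue
        crops3 = {
            src: np.repeat(np.asarray(img, dtype=np.uint8)[..., None], 3, axis=-1)
            for src, img in inst[0].images.items()
        }
        rows.append(
            np.concatenate([mock_extract(specs[b], crops3[b.source]) for b in block_ids])
        )
        kept_ids.append(i)
    return BlockMatrix(
        sample_ids=tuple(kept_ids),
        block_order=tuple(block_ids),
        values=np.asarray(rows, dtype=np.float32),
    )


def run_phase1(
    index: DatasetIndex,
    image_chromosome,
    cell_chromosome,
    backends=None,
    seed: int = 0,
    cv_plan: CVPlan | None = None,
    seg_backend: SegmentationBackend | None = None,
    min_area: int = 100,
) -> Phase1Result:
    backends = backends or mock_backends(seed=seed)
    singles = index.single_label_records
    single_index = DatasetIndex(records=singles, root=index.root)
    split = phase1_split(single_index, seed=seed)
    plan = cv_plan or CVPlan(seed=seed)

    img_train = build_image_matrix(single_index, split.train_ids, image_chromosome, backends)
    y_img = _single_labels_of(single_index, split.train_ids)
    image_models = train_oao(img_train.values, y_img, plan=plan)

    cell_train = build_cell_matrix(
        single_index, split.train_ids, cell_chromosome, backends,
        seg_backend=seg_backend, min_area=min_area,
    )
    y_cell = _single_labels_of(single_index, cell_train.sample_ids)
    cell_models = train_oao(cell_train.values, y_cell, plan=plan)

    return Phase1Result(
        split=split,
        image_chromosome=np.asarray(image_chromosome, dtype=np.uint8),
        cell_chromosome=np.asarray(cell_chromosome, dtype=np.uint8),
        image_models=image_models,
        cell_models=cell_models,
        cell_sample_ids=cell_train.sample_ids,
    )


def stack_features(
    index: DatasetIndex,
    phase1: Phase1Result,
    backends=None,
    seg_backend: SegmentationBackend | None = None,
    min_area: int = 100,
    seed: int = 0,
):
    """Second-level feature table for every sample at all three levels."""
    backends = backends or mock_backends(seed=seed)
    image_rows, cell_rows, combined_rows = [], [], []
    for record in index.records:
        iv = image_level_features(
            record, phase1.image_chromosome, backends, phase1.image_models
        )
        cv, _ = cell_level_features(
            record, phase1.cell_chromosome, backends, phase1.cell_models,
            seg_backend=seg_backend, min_area=min_area,
        )
        image_rows.append(iv.values)
        cell_rows.append(cv.values)
        combined_rows.append(fuse(iv, cv).values)
    return {
        "image": np.asarray(image_rows),
        "cell": np.asarray(cell_rows),
        "combined": np.asarray(combined_rows),
    }


def run_phase2(
    index: DatasetIndex,
    phase1: Phase1Result,
    backends=None,
    strategies=("LP",),
    bases=(BaseLearner(kind="linear_svm"),),
    n_classes: int = 28,
    seg_backend: SegmentationBackend | None = None,
    min_area: int = 100,
    seed: int = 0,
) -> Phase2Result:
    backends = backends or mock_backends(seed=seed)
    features = stack_features(
        index, phase1, backends, seg_backend=seg_backend, min_area=min_area, seed=seed
    )
    ids = index.sample_ids
    label_sets = [r.labels for r in index.records]
    pinned = [i for i in phase1.split.train_ids if i in set(ids)]
    split = iterative_stratified_split(
        ids, label_sets, ratio=0.8, pinned_train_ids=pinned, seed=seed
    )
    pos = {s: k for k, s in enumerate(ids)}
    tr = [pos[i] for i in split.train_ids]
    te = [pos[i] for i in split.test_ids]
    sets_train = [label_sets[k] for k in tr]
    sets_test = [label_sets[k] for k in te]

    reports: dict[str, dict[str, MetricsReport]] = {}
    for level, X in features.items():
        reports[level] = {}
        for strategy in strategies:
            for base in bases:
                _, preds = fit_predict_multilabel(
                    strategy, X[tr], sets_train, X[te], base, n_classes
                )
                key = f"{strategy}-{base.kind}" + (
                    f"-k{base.k}" if base.kind == "knn" else ""
                )
                reports[level][key] = evaluate(preds, sets_test, n_classes)
    return Phase2Result(split=split, reports=reports, features=features)


def run_two_phase(
    index: DatasetIndex,
    image_chromosome,
    cell_chromosome,
    backends=None,
    seed: int = 0,
    n_classes: int = 28,
    strategies=("LP",),
    bases=(BaseLearner(kind="linear_svm"),),
    min_area: int = 100,
) -> tuple[Phase1Result, Phase2Result]:
    """End-to-end run: phase-1 models then phase-2 stacked multi-label."""
    backends = backends or mock_backends(seed=seed)
    phase1 = run_phase1(
        index, image_chromosome, cell_chromosome, backends,
        seed=seed, min_area=min_area,
    )
    phase2 = run_phase2(
        index, phase1, backends, strategies=strategies, bases=bases,
        n_classes=n_classes, min_area=min_area, seed=seed,
    )
    return phase1, phase2
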