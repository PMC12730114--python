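"""Self-contained simulation studies over the synthetic fixtures.

These bundle the package's own validation experiments at desk scale:

* ``planted_recovery_study`` — can the GA find planted informative feature
  blocks among constant-noise blocks at the cell level?
* ``end_to_end_study`` — does fusing image-level and cell-level stacked
  features beat each single level on a 3-family multi-label fixture?
* ``nucleus_recovery_study`` — does the classical segmentation backend
  recover the generator's planted nuclei?

Problem sizes (96 px images, around a hundred samples) are chosen so each
study runs in minutes on one CPU while leaving the signal structure intact.
"""

from __future__ import annotations

import numpy as np

from .blocks import BlockId, cell_level_block_ids, image_level_block_ids, mock_backends
from .ga import GAConfig, run_ga
from .io import phase1_split
from .multilabel import BaseLearner
from .pipeline import planted_cell_matrix, run_two_phase
from .segment import segment_nuclei
from .stage1 import make_ga_fitness
from .synth import SynthConfig, generate_dataset

# Three planted informative blocks: two complementary sources of one
# extractor plus a second nucleus-source block (redundant with the first).
PLANTED_BLOCKS = (
    BlockId("densenet201", "nucleus"),
    BlockId("densenet201", "ring"),
    BlockId("resnet18", "nucleus"),
)

SIGNAL_EXTRACTORS = ("densenet201", "resnet50")


def planted_recovery_cfg(seed: int) -> SynthConfig:
    return SynthConfig(
        n_samples=120,
        image_size=96,
        n_classes=3,
        multilabel_rate=0.0,
        noise_sigma=2.0,
        nuclei_per_image=(3, 5),
        nucleus_radius_px=(8, 12),
        seed=seed,
    )


def planted_recovery_study(
    n_runs: int = 10,
    dataset_seed: int = 11,
    ga_seed0: int = 0,
    generations: int = 25,
) -> dict:
    """Run the GA ``n_runs`` times against a 24-block matrix where only the
    three ``PLANTED_BLOCKS`` carry signal; count runs whose best chromosome
    includes at least two of them."""
    index, _ = generate_dataset(planted_recovery_cfg(dataset_seed))
    matrix = planted_cell_matrix(index, index.sample_ids, PLANTED_BLOCKS,
                                 seed=dataset_seed)
    sub = index.subset(matrix.sample_ids)
    split = phase1_split(sub, seed=dataset_seed)
    y_tr = np.array([next(iter(sub[i].labels)) for i in split.train_ids])
    y_te = np.array([next(iter(sub[i].labels)) for i in split.test_ids])
    fitness = make_ga_fitness(
        matrix.rows_for(split.train_ids), matrix.rows_for(split.test_ids),
        y_tr, y_te,
    )
    planted_idx = [k for k, b in enumerate(cell_level_block_ids())
                   if b in set(PLANTED_BLOCKS)]
    runs = []
    for r in range(n_runs):
        config = GAConfig(generations=generations, seed=ga_seed0 + r)
        best, history, archive = run_ga(24, fitness, config)
        hits = int(sum(best.chromosome[k] for k in planted_idx))
        runs.append({
            "ga_seed": config.seed,
            "best_fitness": best.fitness,
            "informative_hits": hits,
            "offspring_evaluations": history[-1].evaluations,
        })
    successes = sum(r["informative_hits"] >= 2 for r in runs)
    return {
        "runs": runs,
        "successes": successes,
        "n_runs": n_runs,
        "recovery_rate": successes / n_runs,
    }


def study_chromosomes():
    """Fixed study chromosomes: the signal extractors' green/mean image
    blocks and all their cell blocks."""
    img = np.array(
        [1 if (b.extractor_name in SIGNAL_EXTRACTORS
               and b.source in ("gray_green", "mean_gray")) else 0
         for b in image_level_block_ids()], dtype=np.uint8)
    cell = np.array(
        [1 if b.extractor_name in SIGNAL_EXTRACTORS else 0
         for b in cell_level_block_ids()], dtype=np.uint8)
    return img, cell


def end_to_end_cfg(seed: int, noise_sigma: float = 2.0) -> SynthConfig:
    return SynthConfig(
        n_samples=90,
        image_size=96,
        n_classes=3,
        class_probs=(0.5, 0.3, 0.2),
        multilabel_rate=0.2,
        noise_sigma=noise_sigma,
        nuclei_per_image=(3, 5),
        nucleus_radius_px=(8, 12),
        seed=seed,
    )


def end_to_end_study(seed: int, noise_sigma: float = 2.0) -> dict:
    """Full two-phase pipeline on one seeded fixture; LP linear-SVM macro-F1
    at image, cell and combined level."""
    index, _ = generate_dataset(end_to_end_cfg(seed, noise_sigma))
    backends = mock_backends(seed=0, signal_extractors=SIGNAL_EXTRACTORS)
    img_chrom, cell_chrom = study_chromosomes()
    _, phase2 = run_two_phase(
        index, img_chrom, cell_chrom, backends, seed=seed, n_classes=3,
        strategies=("LP",), bases=(BaseLearner(kind="linear_svm", seed=seed),),
    )
    out = {}
    for level, by in phase2.reports.items():
        report = by["LP-linear_svm"]
        out[level] = {
            "macro_f1": report.macro_f1,
            "weighted_f1": report.weighted_f1,
            "subset_accuracy": report.subset_accuracy,
        }
    out["n_samples"] = len(index)
    return out


def nucleus_recovery_study(seed: int = 21, n_samples: int = 15,
                           noise_sigma: float = 5.0) -> dict:
    """Fraction of planted non-border nuclei recovered at IoU >= 0.5."""
    cfg = SynthConfig(
        n_samples=n_samples, image_size=96, n_classes=3, multilabel_rate=0.0,
        noise_sigma=noise_sigma, nuclei_per_image=(3, 5),
        nucleus_radius_px=(8, 12), seed=seed,
    )
    index, truth = generate_dataset(cfg)
    found, total = 0, 0
    for rec in index.records:
        rois = segment_nuclei(rec.channels["blue"])
        for planted in truth.nucleus_masks[rec.sample_id]:
            if (planted[0, :].any() or planted[-1, :].any()
                    or planted[:, 0].any() or planted[:, -1].any()):
                continue
            total += 1
            best = 0.0
            for roi in rois:
                inter = (roi.mask & planted).sum()
                union = (roi.mask | planted).sum()
                best = max(best, inter / union)
            found += best >= 0.5
    return {"found": found, "total": total,
            "recovery_rate": found / total if total else 0.0}
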