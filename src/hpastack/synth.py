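"""Synthetic HPA-like fixtures: image generator and deterministic mock extractors.

The generator emulates the on-disk layout of the real data — four 8-bit
grayscale channels per sample plus a ``train.csv`` — at configurable size.
Classes map onto three pattern families that mirror the broad localization
groups in the real data:

* ``nuclear``   (class index % 3 == 0): green signal painted inside nuclei,
* ``ring``      (class index % 3 == 1): green painted in a 3-6 px annulus
  just outside the nuclear boundary (nuclear-membrane-like),
* ``cytoplasm`` (class index % 3 == 2): diffuse green painted away from
  nuclei.

Multi-label samples superpose the patterns of every label they carry.  The
blue channel always contains bright, mutually disjoint elliptical nuclei
(ground-truth masks are returned for segmentation tests); red and yellow
carry label-independent smooth texture.

Mock feature extractors honor the real extractor contract (deterministic
1000-vector per image) without any pretrained weights: a *signal-bearing*
extractor writes region-restricted intensity statistics into its first 32
entries (enough for a linear classifier to separate the pattern families),
while the remaining entries — and the whole vector of a non-signal extractor
— are pseudo-noise fixed by (name, seed), carrying no image information.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from .io import DatasetIndex, SampleRecord, write_dataset

FAMILIES = ("nuclear", "ring", "cytoplasm")

MOCK_OUTPUT_DIM = 1000
N_SIGNAL_FEATURES = 32


def pattern_family(class_index: int) -> str:
    return FAMILIES[class_index % 3]


@dataclass
class SynthConfig:
    """Study conditions for one synthetic dataset.

    The seed fully determines the output, including file bytes on disk.
    """

    n_samples: int = 60
    image_size: int = 512
    n_classes: int = 3
    class_probs: tuple[float, ...] | None = None
    multilabel_rate: float = 0.0
    nuclei_per_image: tuple[int, int] = (3, 5)
    nucleus_radius_px: tuple[int, int] = (9, 13)
    noise_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.n_classes <= 28):
            raise ValueError("n_classes must be in [1, 28]")
        if self.nucleus_radius_px[0] < 3:
            raise ValueError("nucleus radius must be >= 3 px")
        if self.class_probs is None:
            self.class_probs = tuple([1.0 / self.n_classes] * self.n_classes)
        probs = np.asarray(self.class_probs, dtype=float)
        if len(probs) != self.n_classes or not np.isclose(probs.sum(), 1.0):
            raise ValueError("class_probs must have n_classes entries summing to 1")


@dataclass
class GroundTruth:
    """Planted per-sample nucleus masks, aligned with the dataset records."""

    nucleus_masks: dict[str, list[np.ndarray]] = field(default_factory=dict)


def _place_nuclei(rng, size, n_target, radius_range, margin=3, max_retries=60):
    """Random disjoint ellipses; returns (union mask, list of per-nucleus masks)."""
    yy, xx = np.mgrid[0:size, 0:size]
    masks: list[np.ndarray] = []
    occupied = np.zeros((size, size), dtype=bool)
    placed_params = []
    for _ in range(n_target):
        for _attempt in range(max_retries):
            r = rng.integers(radius_range[0], radius_range[1] + 1)
            a = r * rng.uniform(0.85, 1.15)
            b = r * rng.uniform(0.85, 1.15)
            theta = rng.uniform(0, np.pi)
            pad = int(np.ceil(max(a, b))) + margin + 1
            if 2 * pad >= size:
                continue
            cy = rng.integers(pad, size - pad)
            cx = rng.integers(pad, size - pad)
            # disjointness via center distance against every placed ellipse
            ok = all(
                np.hypot(cy - py, cx - px) > (max(a, b) + pm + margin)
                for py, px, pm in placed_params
            )
            if not ok:
                continue
            ct, st = np.cos(theta), np.sin(theta)
            u = (xx - cx) * ct + (yy - cy) * st
            v = -(xx - cx) * st + (yy - cy) * ct
            mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
            masks.append(mask)
            occupied |= mask
            placed_params.append((cy, cx, max(a, b)))
            break
        # fewer nuclei than requested after exhausting retries is acceptable
    return occupied, masks


def _smooth_noise(rng, size, scale=12.0, lo=0.0, hi=1.0):
    field_ = ndi.gaussian_filter(rng.standard_normal((size, size)), scale)
    fmin, fmax = field_.min(), field_.max()
    if fmax - fmin < 1e-12:
        return np.full((size, size), lo)
    return lo + (hi - lo) * (field_ - fmin) / (fmax - fmin)


def _draw_label_set(rng, cfg: SynthConfig) -> frozenset[int]:
    primary = int(rng.choice(cfg.n_classes, p=np.asarray(cfg.class_probs)))
    labels = {primary}
    if cfg.n_classes > 1 and rng.uniform() < cfg.multilabel_rate:
        others = [k for k in range(cfg.n_classes) if k != primary]
        labels.add(int(rng.choice(others)))
    return frozenset(labels)


def generate_dataset(
    cfg: SynthConfig, out_dir=None
) -> tuple[DatasetIndex, GroundTruth]:
    """Generate a synthetic dataset; optionally write it in the HPA layout."""
    rng = np.random.default_rng(cfg.seed)
    size = cfg.image_size
    records: list[SampleRecord] = []
    truth = GroundTruth()

    for i in range(cfg.n_samples):
        sid = f"synth{i:04d}"
        labels = _draw_label_set(rng, cfg)
        n_nuc = int(rng.integers(cfg.nuclei_per_image[0], cfg.nuclei_per_image[1] + 1))
        nuclei, masks = _place_nuclei(rng, size, n_nuc, cfg.nucleus_radius_px)
        dist_out = ndi.distance_transform_edt(~nuclei)

        blue = np.where(nuclei, 200.0, 8.0)
        green = np.zeros((size, size), dtype=np.float64)
        for label in labels:
            fam = pattern_family(label)
            if fam == "nuclear":
                green = np.maximum(green, np.where(nuclei, 175.0, 0.0))
            elif fam == "ring":
                annulus = (~nuclei) & (dist_out >= 1.0) & (dist_out <= 5.0)
                green = np.maximum(green, np.where(annulus, 175.0, 0.0))
            else:  # cytoplasm
                far = dist_out > 8.0
                texture = _smooth_noise(rng, size, scale=size / 10, lo=60.0, hi=130.0)
                green = np.maximum(green, np.where(far, texture, 0.0))
        red = _smooth_noise(rng, size, scale=size / 8, lo=20.0, hi=90.0)
        yellow = 0.6 * red + 0.4 * _smooth_noise(rng, size, scale=size / 8, lo=20.0, hi=90.0)

        channels = {}
        for name, plane in (
            ("blue", blue),
            ("green", green),
            ("red", red),
            ("yellow", yellow),
        ):
            if cfg.noise_sigma > 0:
                plane = plane + rng.normal(0.0, cfg.noise_sigma, plane.shape)
            channels[name] = np.clip(np.round(plane), 0, 255).astype(np.uint8)

        records.append(
            SampleRecord(sample_id=sid, channels=channels, labels=labels)
        )
        truth.nucleus_masks[sid] = masks

    index = DatasetIndex(records=records)
    if out_dir is not None:
        write_dataset(index, Path(out_dir))
        index.root = Path(out_dir)
    return index, truth


# ---------------------------------------------------------------------------
# mock feature extractor
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MockExtractorSpec:
    """A named deterministic stand-in feature extractor.

    ``signal_classes`` marks the extractor as signal-bearing: its first 32
    output entries then encode region-wise intensity statistics of the input
    (discriminative for the synthetic pattern families); when empty the whole
    output is a constant pseudo-noise vector fixed by (name, seed).
    ``signal_stats`` optionally restricts which of the 32 statistics the
    extractor writes, modelling extractors with narrow descriptive power
    (complementary blocks for planted-recovery studies).
    """

    name: str
    seed: int = 0
    output_dim: int = MOCK_OUTPUT_DIM
    signal_classes: frozenset[int] = frozenset()
    signal_stats: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.output_dim != MOCK_OUTPUT_DIM:
            raise ValueError(f"mock extractor output_dim is fixed at {MOCK_OUTPUT_DIM}")


def _stable_seed(*parts) -> int:
    digest = hashlib.blake2b(
        "|".join(str(p) for p in parts).encode(), digest_size=4
    ).digest()
    return int.from_bytes(digest, "little")


def _baseline(spec: MockExtractorSpec) -> np.ndarray:
    rng = np.random.default_rng(_stable_seed("mock", spec.name, spec.seed))
    return (0.1 * rng.standard_normal(spec.output_dim)).astype(np.float64)


def signal_features(image3: np.ndarray) -> np.ndarray:
    """32 intensity/shape statistics of a 3-plane image, zero for a zero image.

    The statistics describe how much signal there is and how it is arranged
    (coverage at several thresholds, bright-region thickness, boundary-to-area
    ratio, connected-component counts), which separates compact nuclear
    blobs, thin annuli and diffuse cytoplasmic texture linearly.
    """
    u = np.asarray(image3, dtype=np.float64).mean(axis=-1) / 255.0
    feats = np.zeros(N_SIGNAL_FEATURES)
    if not np.any(u):
        return feats
    k = 0
    feats[k] = u.mean(); k += 1
    feats[k] = u.std(); k += 1
    for q in (50, 75, 90, 99):
        feats[k] = np.percentile(u, q); k += 1
    feats[k] = u.max(); k += 1
    for thr in (0.1, 0.25, 0.4, 0.55, 0.7):
        feats[k] = (u > thr).mean(); k += 1
    mask = u > 0.2
    area = mask.sum()
    if area > 0:
        feats[k] = u[mask].mean(); k += 1
        inner = ndi.binary_erosion(mask)
        boundary = mask & ~inner
        feats[k] = boundary.sum() / area; k += 1           # thin shapes score high
        dist = ndi.distance_transform_edt(mask)
        feats[k] = dist[mask].mean() / 10.0; k += 1        # mean thickness
        feats[k] = dist.max() / 20.0; k += 1
        n_comp = ndi.label(mask)[1]
        feats[k] = n_comp / 20.0; k += 1
        filled = ndi.binary_fill_holes(mask)
        feats[k] = (filled.sum() - area) / max(filled.sum(), 1); k += 1  # hole frac
    return feats


def mock_extract(spec: MockExtractorSpec, image3: np.ndarray) -> np.ndarray:
    """Deterministic 1000-vector for a 3-plane image.

    ``baseline(name, seed) + signal`` where the signal term occupies the
    first 32 entries and vanishes for a zero image (and for non-signal
    extractors entirely).
    """
    image3 = np.asarray(image3)
    if image3.ndim != 3 or image3.shape[-1] != 3:
        raise ValueError(f"mock extractor expects HxWx3 input, got {image3.shape}")
    vec = _baseline(spec)
    if spec.signal_classes:
        stats = signal_features(image3)
        if spec.signal_stats is not None:
            keep = np.zeros(N_SIGNAL_FEATURES, dtype=bool)
            keep[list(spec.signal_stats)] = True
            stats = np.where(keep, stats, 0.0)
        vec[:N_SIGNAL_FEATURES] = vec[:N_SIGNAL_FEATURES] + stats
    return vec
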