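"""Shared fixtures: small synthetic datasets and lightweight sample records."""

import numpy as np
import pytest

from hpastack.io import CHANNEL_NAMES, DatasetIndex, SampleRecord
from hpastack.synth import SynthConfig, generate_dataset


def make_record(sample_id="s0", labels=(0,), size=8, fill=0):
    """Minimal valid record (tiny images) for label/split logic tests."""
    channels = {
        c: np.full((size, size), fill, dtype=np.uint8) for c in CHANNEL_NAMES
    }
    return SampleRecord(sample_id=sample_id, channels=channels, labels=frozenset(labels))


def make_index(label_sets, size=4):
    records = [
        make_record(sample_id=f"r{i:04d}", labels=labels, size=size)
        for i, labels in enumerate(label_sets)
    ]
    return DatasetIndex(records=records)


@pytest.fixture(scope="session")
def small_synth():
    """40-sample 96-px 3-class dataset with 20% multi-label, mild imbalance."""
    cfg = SynthConfig(
        n_samples=40,
        image_size=96,
        n_classes=3,
        class_probs=(0.5, 0.3, 0.2),
        multilabel_rate=0.2,
        noise_sigma=2.0,
        nuclei_per_image=(3, 5),
        nucleus_radius_px=(8, 12),
        seed=7,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def clean_synth():
    """Low-noise single-label dataset for segmentation-recovery checks."""
    cfg = SynthConfig(
        n_samples=15,
        image_size=96,
        n_classes=3,
        multilabel_rate=0.0,
        noise_sigma=5.0,
        nuclei_per_image=(3, 5),
        nucleus_radius_px=(8, 12),
        seed=21,
    )
    return generate_dataset(cfg)
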