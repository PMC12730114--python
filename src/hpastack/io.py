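"""Dataset model and on-disk I/O for HPA-layout fluorescence microscopy data.

A *sample* is four co-registered 8-bit grayscale images of the same field of
view, one per fluorescence channel: ``blue`` (nuclei, DAPI-like), ``green``
(the protein of interest), ``red`` (microtubules) and ``yellow`` (endoplasmic
reticulum).  On disk a dataset is a directory of ``<Id>_<color>.png`` (or
``.tif``) files plus a ``train.csv`` with columns ``Id`` and ``Target``, the
latter holding space-separated integer class labels in ``[0, 27]``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

CHANNEL_NAMES: tuple[str, ...] = ("blue", "green", "red", "yellow")
N_CLASSES = 28


class DatasetError(ValueError):
    """Raised when a dataset directory or labels CSV violates the layout."""


@dataclass
class SampleRecord:
    """One four-channel sample and its label set.

    ``channels`` maps each of the four channel names to an 8-bit 2-D array;
    all four arrays must share one shape.  ``labels`` is a set of integers in
    ``[0, 27]``; training records must carry at least one label.
    """

    sample_id: str
    channels: dict[str, np.ndarray]
    labels: frozenset[int]
    resolution_scaled: bool = True

    def __post_init__(self) -> None:
        missing = [c for c in CHANNEL_NAMES if c not in self.channels]
        if missing:
            raise DatasetError(
                f"sample {self.sample_id!r}: missing channel(s) {missing}"
            )
        shapes = {self.channels[c].shape for c in CHANNEL_NAMES}
        if len(shapes) != 1:
            raise DatasetError(
                f"sample {self.sample_id!r}: channel shapes differ: {shapes}"
            )
        bad = [l for l in self.labels if not (0 <= int(l) < N_CLASSES)]
        if bad:
            raise DatasetError(
                f"sample {self.sample_id!r}: label out of range [0, {N_CLASSES - 1}]: {bad}"
            )
        self.labels = frozenset(int(l) for l in self.labels)

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels["blue"].shape

    @property
    def is_single_label(self) -> bool:
        return len(self.labels) == 1


@dataclass
class DatasetIndex:
    """Ordered collection of samples with per-class bookkeeping."""

    records: list[SampleRecord]
    root: Path | None = None

    @property
    def class_counts(self) -> Counter:
        counts: Counter = Counter()
        for r in self.records:
            counts.update(r.labels)
        return counts

    @property
    def single_label_records(self) -> list[SampleRecord]:
        return [r for r in self.records if r.is_single_label]

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, sample_id: str) -> SampleRecord:
        for r in self.records:
            if r.sample_id == sample_id:
                return r
        raise KeyError(sample_id)

    def subset(self, ids) -> "DatasetIndex":
        wanted = set(ids)
        return DatasetIndex(
            records=[r for r in self.records if r.sample_id in wanted],
            root=self.root,
        )


@dataclass(frozen=True)
class SplitSpec:
    """A train/test partition of sample ids.

    ``strategy`` records how the split was produced (``phase1_balanced`` for
    the per-class capped random split, ``iterative_stratification`` for the
    multi-label greedy split).
    """

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    ratio: float
    strategy: str
    unusable_classes: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")


def parse_target(token: str) -> frozenset[int]:
    """Parse a space-separated ``Target`` field into a label set."""
    parts = str(token).split()
    if not parts:
        raise DatasetError(f"empty Target field: {token!r}")
    labels = set()
    for p in parts:
        try:
            v = int(p)
        except ValueError as exc:
            raise DatasetError(f"malformed Target token {p!r}") from exc
        if not (0 <= v < N_CLASSES):
            raise DatasetError(f"label out of range [0, {N_CLASSES - 1}]: {v}")
        labels.add(v)
    return frozenset(labels)


def _read_channel(root: Path, sample_id: str, color: str) -> np.ndarray:
    for ext in (".png", ".tif", ".tiff"):
        path = root / f"{sample_id}_{color}{ext}"
        if path.exists():
            img = np.asarray(Image.open(path).convert("L"), dtype=np.uint8)
            return img
    raise DatasetError(
        f"missing channel file for sample {sample_id!r}: "
        f"expected {sample_id}_{color}.png (or .tif) under {root}"
    )


def load_dataset(root_path, labels_csv=None) -> DatasetIndex:
    """Load a dataset directory plus labels CSV into a :class:`DatasetIndex`.

    A missing channel file or an out-of-range label aborts the load with an
    error naming the offending sample: silently dropping records would bias
    downstream class counts.
    """
    root = Path(root_path)
    csv_path = Path(labels_csv) if labels_csv is not None else root / "train.csv"
    if not csv_path.exists():
        raise DatasetError(f"labels CSV not found: {csv_path}")
    table = pd.read_csv(csv_path, dtype={"Id": str, "Target": str})
    for col in ("Id", "Target"):
        if col not in table.columns:
            raise DatasetError(f"labels CSV missing column {col!r}")
    records = []
    for _, row in table.iterrows():
        sid = row["Id"]
        labels = parse_target(row["Target"])
        channels = {c: _read_channel(root, sid, c) for c in CHANNEL_NAMES}
        side = channels["blue"].shape[0]
        records.append(
            SampleRecord(
                sample_id=sid,
                channels=channels,
                labels=labels,
                resolution_scaled=(side <= 512),
            )
        )
    return DatasetIndex(records=records, root=root)


def write_dataset(index: DatasetIndex, root_path) -> Path:
    """Write an index back to disk in the canonical layout (PNG + train.csv).

    Labels are serialized in ascending order; pixel data round-trips
    bit-exactly through lossless PNG.
    """
    root = Path(root_path)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in index.records:
        for color in CHANNEL_NAMES:
            Image.fromarray(r.channels[color].astype(np.uint8), mode="L").save(
                root / f"{r.sample_id}_{color}.png"
            )
        rows.append(
            {"Id": r.sample_id, "Target": " ".join(str(l) for l in sorted(r.labels))}
        )
    pd.DataFrame(rows, columns=["Id", "Target"]).to_csv(root / "train.csv", index=False)
    return root


def phase1_split(
    index: DatasetIndex,
    cap: int = 250,
    small_threshold: int = 275,
    small_train_frac: float = 0.8,
    seed: int = 0,
) -> SplitSpec:
    """Class-balanced random split of the single-label subset.

    Large classes (count >= ``small_threshold``) contribute exactly ``cap``
    random samples to training, leaving the excess in the test set; small
    classes contribute ``floor(small_train_frac * count)``.  A class whose
    training allotment comes out to zero is flagged unusable (its samples all
    land in the test set).
    """
    rng = np.random.default_rng(seed)
    singles = index.single_label_records
    by_class: dict[int, list[str]] = {}
    for r in singles:
        (label,) = tuple(r.labels)
        by_class.setdefault(label, []).append(r.sample_id)

    train: list[str] = []
    test: list[str] = []
    unusable: list[int] = []
    for label in sorted(by_class):
        ids = sorted(by_class[label])
        rng.shuffle(ids)
        n = len(ids)
        if n >= small_threshold:
            n_train = cap
        else:
            n_train = int(np.floor(small_train_frac * n))
        if n_train == 0:
            unusable.append(label)
        train.extend(ids[:n_train])
        test.extend(ids[n_train:])
    total = len(train) + len(test)
    return SplitSpec(
        train_ids=tuple(train),
        test_ids=tuple(test),
        ratio=len(train) / total if total else 0.0,
        strategy="phase1_balanced",
        unusable_classes=tuple(unusable),
    )


def write_split(split: SplitSpec, path) -> None:
    rows = [{"Id": i, "split": "train"} for i in split.train_ids]
    rows += [{"Id": i, "split": "test"} for i in split.test_ids]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_split(path, strategy: str = "unknown") -> SplitSpec:
    table = pd.read_csv(path, dtype={"Id": str})
    train = tuple(table.loc[table["split"] == "train", "Id"])
    test = tuple(table.loc[table["split"] == "test", "Id"])
    total = len(train) + len(test)
    return SplitSpec(
        train_ids=train,
        test_ids=test,
        ratio=len(train) / total if total else 0.0,
        strategy=strategy,
    )
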