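"""Dataset manifests: global IDs, deduplication, and stratified 7:3 splitting.

A :class:`DatasetManifest` lists every image with a globally unique ID, the
original per-source ID it came from, its file path, class label and split
assignment.  Splitting is per class (stratified): round-half-up of 70% of a
class goes to the training portion and the remainder to the test set; 15%
of the training portion (rounded half-up) is then carved out as an internal
validation set used for checkpoint selection.  With the class sizes
1621/1645/1757/2000 this yields training portions 1135/1152/1230/1400 and
test portions 486/493/527/600 (totals 4917 and 2106).

Duplicate images across sources are detected by matching source IDs; the
earliest occurrence survives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ManifestRecord",
    "DatasetManifest",
    "round_half_up",
    "assign_global_ids",
    "split_dataset",
    "split_counts",
]

SPLITS = ("train", "internal_val", "test")
MANIFEST_COLUMNS = ("global_id", "source_id", "path", "class_label", "split")


def round_half_up(x: float) -> int:
    """Round to the nearest integer with halves going up (0.5 -> 1)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class ManifestRecord:
    global_id: str
    source_id: str
    path: str
    class_label: str
    split: str = "unassigned"


class DatasetManifest:
    """An ordered collection of image records with unique global IDs."""

    def __init__(self, records: list[ManifestRecord]):
        ids = [r.global_id for r in records]
        if len(set(ids)) != len(ids):
            raise ValueError("global IDs must be unique across the manifest")
        self.records = list(records)

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def class_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.class_label, None)
        return list(seen)

    def subset(self, split: str) -> "DatasetManifest":
        return DatasetManifest([r for r in self.records if r.split == split])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[getattr(r, c) for c in MANIFEST_COLUMNS] for r in self.records],
            columns=list(MANIFEST_COLUMNS),
        )

    def write(self, path: str | Path) -> None:
        """Write as a tab-delimited text file with a header row."""
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "DatasetManifest":
        frame = pd.read_csv(path, sep="\t", dtype=str)
        missing = set(MANIFEST_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"manifest is missing columns: {sorted(missing)}")
        return cls(
            [ManifestRecord(**{c: row[c] for c in MANIFEST_COLUMNS})
             for _, row in frame.iterrows()]
        )


def assign_global_ids(manifests: list[DatasetManifest]) -> DatasetManifest:
    """Merge source manifests into one with fresh unique global IDs.

    Records whose ``source_id`` matches an earlier record (within or across
    sources) are treated as duplicate images and dropped, keeping the first
    occurrence.
    """
    seen: set[str] = set()
    merged: list[ManifestRecord] = []
    for manifest in manifests:
        for record in manifest:
            if record.source_id in seen:
                continue
            seen.add(record.source_id)
            merged.append(record)
    return DatasetManifest(
        [replace(r, global_id=f"g{i:06d}") for i, r in enumerate(merged)]
    )


def split_counts(n_class: int, ratio: float = 0.7, val_fraction: float = 0.15
                 ) -> tuple[int, int, int]:
    """(train, internal_val, test) counts for one class of size ``n_class``."""
    if n_class < 1:
        raise ValueError("every class needs at least one record")
    train_portion = round_half_up(ratio * n_class)
    n_test = n_class - train_portion
    n_val = round_half_up(val_fraction * train_portion)
    return train_portion - n_val, n_val, n_test


def split_dataset(
    manifest: DatasetManifest,
    ratio: float = 0.7,
    seed: int = 0,
    val_fraction: float = 0.15,
) -> DatasetManifest:
    """Assign stratified train / internal_val / test splits, seeded.

    Per class, a round-half-up ``ratio`` share forms the training portion and
    the rest the test set; ``val_fraction`` of the training portion (rounded
    half-up) becomes the internal validation set.  The same seed always
    produces the same assignment, and no global ID appears in two splits.
    """
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[ManifestRecord]] = {}
    for record in manifest:
        by_class.setdefault(record.class_label, []).append(record)
    assigned: dict[str, str] = {}
    for label in sorted(by_class):
        records = sorted(by_class[label], key=lambda r: r.global_id)
        order = rng.permutation(len(records))
        n_train, n_val, _ = split_counts(len(records), ratio, val_fraction)
        for rank, idx in enumerate(order):
            if rank < n_val:
                split = "internal_val"
            elif rank < n_val + n_train:
                split = "train"
            else:
                split = "test"
            assigned[records[idx].global_id] = split
    return DatasetManifest([replace(r, split=assigned[r.global_id]) for r in manifest])
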