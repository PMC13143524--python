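"""Dataset manifests, stratified cross-validation splits, and class weights.

The study design is a six-class, class-imbalanced image classification
problem evaluated by stratified k-fold cross-validation at the image level.
This module owns the bookkeeping: mapping label strings to integer ids
(excluding unmapped rows), partitioning samples into folds that preserve
per-class proportions to within one sample, and the normalized
inverse-frequency class weights w_c = N / (N_c * C) used by the weighted
cross-entropy loss.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Canonical class order; fixes integer ids, confusion-matrix layout and
#: the class axis of every probability vector the package emits.
CLASS_NAMES: tuple[str, ...] = (
    "Blepharitis",
    "Regular",
    "Conjunctivitis",
    "Corneal Sequestrum",
    "Corneal Ulcer",
    "Non-Ulcerative Keratitis",
)


@dataclass
class DatasetManifest:
    """Labelled sample index.

    ``records`` holds (filepath, label-string) pairs whose labels all map
    through ``class_map``; rows that did not map are kept in ``excluded``.
    """

    records: list[tuple[str, str]]
    class_map: dict[str, int]
    excluded: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for _, label in self.records:
            if label not in self.class_map:
                raise ValueError(f"record label {label!r} missing from class_map")

    @property
    def C(self) -> int:
        return len(self.class_map)

    @property
    def N(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> np.ndarray:
        """Integer label per record, in record order."""
        return np.array([self.class_map[lab] for _, lab in self.records], dtype=np.int64)

    @property
    def filepaths(self) -> list[str]:
        return [fp for fp, _ in self.records]

    @property
    def counts(self) -> np.ndarray:
        """Per-class sample counts N_c in class-id order."""
        return np.bincount(self.labels, minlength=self.C)

    @property
    def class_names(self) -> list[str]:
        inv = {v: k for k, v in self.class_map.items()}
        return [inv[i] for i in range(self.C)]

    def subset(self, indices: Sequence[int]) -> "DatasetManifest":
        return DatasetManifest(
            records=[self.records[i] for i in indices], class_map=dict(self.class_map)
        )

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["filepath", "label"])
            w.writerows(self.records)


def load_manifest(
    path: str | Path, class_names: Sequence[str] | None = None
) -> DatasetManifest:
    """Build a manifest from a CSV file or a directory.

    Accepts, in order of precedence: a ``filepath,label`` CSV; a directory
    containing ``manifest.csv``; a directory-per-class layout (each
    subdirectory name is the label of the images inside it).  Rows whose
    label is not in the class map are excluded and logged on the returned
    manifest.  Relative CSV filepaths are resolved against the CSV's
    directory.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    names = tuple(class_names) if class_names is not None else CLASS_NAMES
    class_map = {name: i for i, name in enumerate(names)}

    rows: list[tuple[str, str]] = []
    if path.is_file():
        rows = _read_manifest_csv(path)
    elif (path / "manifest.csv").exists():
        rows = _read_manifest_csv(path / "manifest.csv")
    else:
        for sub in sorted(p for p in path.iterdir() if p.is_dir()):
            for img in sorted(sub.iterdir()):
                if img.suffix.lower() in {".png", ".jpg", ".jpeg"}:
                    rows.append((str(img), sub.name))

    records, excluded = [], []
    for fp, label in rows:
        (records if label in class_map else excluded).append((fp, label))
    if not records:
        raise ValueError(f"no readable labelled records found under {path}")
    seen: set[str] = set()
    for fp, _ in records:
        if fp in seen:
            raise ValueError(f"duplicate filepath in manifest: {fp}")
        seen.add(fp)
    return DatasetManifest(records=records, class_map=class_map, excluded=excluded)


def _read_manifest_csv(csv_path: Path) -> list[tuple[str, str]]:
    base = csv_path.parent
    rows = []
    with open(csv_path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or {"filepath", "label"} - set(reader.fieldnames):
            raise ValueError(f"{csv_path} must have a 'filepath,label' header")
        for row in reader:
            fp = row["filepath"]
            if not Path(fp).is_absolute():
                fp = str(base / fp)
            rows.append((fp, row["label"]))
    return rows


# ---------------------------------------------------------------------------
# stratified k-fold
# ---------------------------------------------------------------------------

@dataclass
class FoldSplit:
    """k disjoint validation sets exactly covering all sample indices."""

    k: int
    folds: list[tuple[np.ndarray, np.ndarray]]  # (train_idx, val_idx) per fold
    seed: int

    def validation_sets(self) -> list[np.ndarray]:
        return [val for _, val in self.folds]


def stratified_kfold(manifest: DatasetManifest, k: int = 5, seed: int = 0) -> FoldSplit:
    """Per-class shuffle under ``seed``, then round-robin fold assignment.

    Guarantees: each index appears in exactly one fold's validation set;
    per-class validation counts differ from N_c / k by at most one.
    """
    labels = manifest.labels
    counts = manifest.counts
    if k < 2:
        raise ValueError("k must be at least 2")
    for c, n_c in enumerate(counts):
        if n_c < k:
            raise ValueError(
                f"class {manifest.class_names[c]!r} has {n_c} samples, fewer than k={k}"
            )
    rng = np.random.default_rng(seed)
    fold_of = np.empty(manifest.N, dtype=np.int64)
    for c in range(manifest.C):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            fold_of[i] = pos % k
    all_idx = np.arange(manifest.N)
    folds = [
        (all_idx[fold_of != f].copy(), all_idx[fold_of == f].copy()) for f in range(k)
    ]
    return FoldSplit(k=k, folds=folds, seed=seed)


def export_folds_csv(
    manifest: DatasetManifest, split: FoldSplit, path: str | Path
) -> None:
    """Write ``filepath,label,fold`` with each sample's validation fold."""
    fold_of = np.empty(manifest.N, dtype=np.int64)
    for f, (_, val) in enumerate(split.folds):
        fold_of[val] = f
    df = pd.DataFrame(
        {
            "filepath": manifest.filepaths,
            "label": [lab for _, lab in manifest.records],
            "fold": fold_of,
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# class weights
# ---------------------------------------------------------------------------

def compute_class_weights(manifest_or_counts) -> np.ndarray:
    """Normalized inverse-frequency class weights w_c = N / (N_c * C).

    Balanced classes give w_c = 1 for every class, and the identity
    sum_c w_c * N_c = N holds for any manifest.
    """
    if isinstance(manifest_or_counts, DatasetManifest):
        counts = manifest_or_counts.counts.astype(np.float64)
    else:
        counts = np.asarray(manifest_or_counts, dtype=np.float64)
    if np.any(counts <= 0):
        raise ValueError("every class must have at least one sample")
    n = counts.sum()
    c = counts.size
    return n / (counts * c)
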