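"""Labelled image collections and stratified train/val/test assignment.

A :class:`LabeledDataset` is the in-memory container moved between every
pipeline stage: a list of single-channel ``float`` images in ``[0, 1]``,
integer class labels, class names, and a per-item split assignment in
``{"train", "val", "test"}``.
"""
from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

SPLIT_NAMES = ("train", "val", "test")
DEFAULT_SPLIT_FRACTIONS = (0.70, 0.15, 0.15)

#: Minimum images per class needed to place every class in every split.
MIN_PER_CLASS_STRATIFIED = 3


@dataclass
class LabeledDataset:
    images: list[np.ndarray]
    labels: list[int]
    class_names: list[str]
    split: list[str]
    aug_log: list[dict] | None = field(default=None, repr=False)

    def __post_init__(self):
        if not (len(self.images) == len(self.labels) == len(self.split)):
            raise DataError(
                "images, labels and split must have equal length "
                f"({len(self.images)}, {len(self.labels)}, {len(self.split)})"
            )

    def __len__(self) -> int:
        return len(self.images)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def indices(self, split: str) -> list[int]:
        return [i for i, s in enumerate(self.split) if s == split]

    def subset(self, split: str) -> tuple[np.ndarray, np.ndarray]:
        """Stacked image array ``(n, h, w)`` and label vector for one split."""
        idx = self.indices(split)
        if not idx:
            return np.empty((0,)), np.empty((0,), dtype=int)
        return (
            np.stack([self.images[i] for i in idx]).astype(np.float32),
            np.asarray([self.labels[i] for i in idx], dtype=int),
        )

    def split_sizes(self) -> dict[str, int]:
        return {s: len(self.indices(s)) for s in SPLIT_NAMES}


def stratified_split_sizes(
    n_per_class: int,
    n_classes: int,
    fractions: Sequence[float] = DEFAULT_SPLIT_FRACTIONS,
) -> np.ndarray:
    """Per-class item counts for each split, shape ``(n_classes, 3)``.

    Global split sizes are ``floor(N * f)`` with the rounding remainder
    assigned to train.  Every class then receives one item in every split
    (the coverage guarantee, feasible whenever ``n_per_class >= 3``; if a
    split's global quota is smaller than the class count it is raised to it
    and train absorbs the difference).  Remaining items are dealt
    round-robin over classes, each going to the split with the largest
    remaining quota (ties broken by the larger fractional remainder of
    ``n_per_class * f``, then by split order train/val/test).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError(f"split fractions must sum to 1, got {fractions}")
    if n_per_class < MIN_PER_CLASS_STRATIFIED:
        raise ConfigurationError(
            "stratified 3-way splitting needs at least "
            f"{MIN_PER_CLASS_STRATIFIED} items per class, got {n_per_class}"
        )
    n_total = n_per_class * n_classes
    quota = [int(np.floor(n_total * f)) for f in fractions]
    quota[0] += n_total - sum(quota)
    for j in (1, 2):
        if quota[j] < n_classes:
            quota[j] = n_classes
    quota[0] = n_total - quota[1] - quota[2]
    if quota[0] < n_classes:
        raise ConfigurationError(
            f"cannot cover every class in every split with n_per_class={n_per_class}"
        )

    alloc = np.ones((n_classes, 3), dtype=int)
    remaining = [q - n_classes for q in quota]
    frac = [n_per_class * f - np.floor(n_per_class * f) for f in fractions]
    for u in range(n_total - 3 * n_classes):
        c = u % n_classes
        j = max(range(3), key=lambda j: (remaining[j], frac[j], -j))
        alloc[c, j] += 1
        remaining[j] -= 1
    assert alloc.sum() == n_total and all(r == 0 for r in remaining)
    return alloc


def assign_splits(
    labels: Sequence[int],
    n_classes: int,
    fractions: Sequence[float] = DEFAULT_SPLIT_FRACTIONS,
) -> list[str]:
    """Deterministic stratified split assignment for a balanced label list."""
    labels = list(labels)
    counts = [labels.count(c) for c in range(n_classes)]
    if len(set(counts)) != 1:
        raise ConfigurationError("assign_splits expects a balanced dataset")
    alloc = stratified_split_sizes(counts[0], n_classes, fractions)
    remaining = {c: list(alloc[c]) for c in range(n_classes)}
    out = []
    for lab in labels:
        quota = remaining[lab]
        j = next(i for i in range(3) if quota[i] > 0)
        quota[j] -= 1
        out.append(SPLIT_NAMES[j])
    return out


def save_dataset(ds: LabeledDataset, root: str | Path) -> Path:
    """Write a directory-per-class PNG tree plus ``manifest.csv``."""
    from PIL import Image as PILImage

    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (img, lab, split) in enumerate(zip(ds.images, ds.labels, ds.split)):
        cls = ds.class_names[lab]
        (root / cls).mkdir(exist_ok=True)
        rel = f"{cls}/{i:05d}.png"
        arr = np.clip(np.asarray(img, dtype=float), 0.0, 1.0)
        PILImage.fromarray((arr * 255.0 + 0.5).astype(np.uint8)).save(root / rel)
        rows.append((rel, lab, split))
    with open(root / "manifest.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["filename", "label", "split"])
        w.writerows(rows)
    return root


def load_dataset(root: str | Path) -> LabeledDataset:
    """Read a directory-per-class tree; ``manifest.csv`` takes precedence.

    Items are ordered lexicographically; unreadable image files are skipped
    with a logged warning.
    """
    from PIL import Image as PILImage

    root = Path(root)
    if not root.is_dir():
        raise DataError(f"dataset root {root} is not a directory")
    manifest = root / "manifest.csv"
    images, labels, splits = [], [], []
    if manifest.exists():
        with open(manifest, newline="") as fh:
            entries = sorted(csv.DictReader(fh), key=lambda r: r["filename"])
        class_names = sorted({Path(e["filename"]).parts[0] for e in entries})
        skipped = 0
        for e in entries:
            try:
                arr = np.asarray(PILImage.open(root / e["filename"]).convert("L"))
            except Exception as exc:  # noqa: BLE001 - robustness contract
                logger.warning("skipping unreadable image %s (%s)", e["filename"], exc)
                skipped += 1
                continue
            images.append(arr.astype(np.float64) / 255.0)
            labels.append(int(e["label"]))
            splits.append(e.get("split", "train"))
        if skipped:
            logger.warning("skipped %d unreadable images", skipped)
        return LabeledDataset(images, labels, class_names, splits)

    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not class_dirs:
        raise DataError(f"no class directories under {root}")
    class_names = [p.name for p in class_dirs]
    for lab, cdir in enumerate(class_dirs):
        files = sorted(
            f for f in cdir.iterdir()
            if f.suffix.lower() in {".png", ".jpg", ".jpeg", ".tif", ".tiff"}
        )
        if not files:
            logger.warning("class directory %s is empty", cdir)
        for f in files:
            try:
                arr = np.asarray(PILImage.open(f).convert("L"))
            except Exception as exc:  # noqa: BLE001
                logger.warning("skipping unreadable image %s (%s)", f, exc)
                continue
            images.append(arr.astype(np.float64) / 255.0)
            labels.append(lab)
            splits.append("train")
    return LabeledDataset(images, labels, class_names, splits)
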