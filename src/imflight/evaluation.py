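"""Confusion matrices and classification metrics.

Orientation is fixed as rows = true class, columns = predicted class.
Multi-class precision/recall/F1 are aggregated by the macro (unweighted)
mean over classes, stated explicitly in every report to avoid ambiguity.
Zero-denominator classes report 0 with a logged warning.  AUC is the
rank-based Mann-Whitney formulation with midranks for ties; multi-class
scores are macro-averaged one-vs-rest.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import DataError

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "metrics_from_confusion",
    "roc_auc",
    "dice_coefficient",
]


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (k, k) ints; rows = true, cols = predicted
    class_names: list[str]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise DataError(
                f"counts shape {self.counts.shape} does not match {k} classes"
            )
        if k < 2:
            raise DataError("need at least 2 classes")
        if (self.counts < 0).any():
            raise DataError("confusion counts must be non-negative")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_names,
                            columns=self.class_names)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="true\\pred")


@dataclass
class MetricsReport:
    accuracy: float
    per_class: dict[str, dict[str, float]]  # name -> precision/recall/f1
    macro_precision: float
    macro_recall: float
    macro_f1: float
    auc: float | None = None
    dice: float | None = None
    averaging: str = field(default="macro")

    def to_dict(self) -> dict:
        out = {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "averaging": self.averaging,
            "per_class": self.per_class,
        }
        if self.auc is not None:
            out["auc"] = self.auc
        if self.dice is not None:
            out["dice"] = self.dice
        return out


def confusion(true_labels, pred_labels, class_names) -> ConfusionMatrix:
    """Tally counts[i, j] = #(true == i and predicted == j)."""
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(pred_labels, dtype=int)
    if t.shape != p.shape:
        raise DataError("true and predicted label lists differ in length")
    k = len(class_names)
    if len(t) and (t.min() < 0 or t.max() >= k or p.min() < 0 or p.max() >= k):
        raise DataError(f"labels outside the {k}-class range")
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts=counts, class_names=list(class_names))


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy plus per-class and macro precision/recall/F1."""
    counts = cm.counts.astype(float)
    total = counts.sum()
    if total == 0:
        raise DataError("all-zero confusion matrix")
    tp = np.diag(counts)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp

    def _safe(num, den, what, cls):
        if den == 0:
            logger.warning("%s undefined for class %s (0/0); reporting 0", what, cls)
            return 0.0
        return float(num / den)

    per_class = {}
    for i, name in enumerate(cm.class_names):
        prec = _safe(tp[i], tp[i] + fp[i], "precision", name)
        rec = _safe(tp[i], tp[i] + fn[i], "recall", name)
        f1 = _safe(2 * prec * rec, prec + rec, "f1", name) if (prec + rec) else 0.0
        per_class[name] = {"precision": prec, "recall": rec, "f1": f1}

    ms = [per_class[n] for n in cm.class_names]
    return MetricsReport(
        accuracy=float(tp.sum() / total),
        per_class=per_class,
        macro_precision=float(np.mean([m["precision"] for m in ms])),
        macro_recall=float(np.mean([m["recall"] for m in ms])),
        macro_f1=float(np.mean([m["f1"] for m in ms])),
    )


def _binary_auc(y: np.ndarray, s: np.ndarray) -> float:
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DataError("AUC undefined: only one class present")
    ranks = rankdata(s)  # midranks for ties
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_auc(true_labels, scores) -> float:
    """Mann-Whitney AUC; multi-class input is macro one-vs-rest.

    ``scores`` is a 1D positive-class score vector for binary labels, or an
    ``(n, k)`` score matrix for k-class labels.
    """
    y = np.asarray(true_labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if s.ndim == 1:
        classes = np.unique(y)
        if not np.array_equal(classes, [0, 1]):
            if len(classes) < 2:
                raise DataError("AUC undefined: only one class present")
            raise DataError("1D scores need binary 0/1 labels")
        return _binary_auc(y, s)
    if s.ndim != 2 or len(s) != len(y):
        raise DataError(f"bad score matrix shape {s.shape} for {len(y)} labels")
    aucs = []
    for c in range(s.shape[1]):
        y_c = (y == c).astype(int)
        if y_c.sum() in (0, len(y_c)):
            raise DataError(f"AUC undefined: class {c} absent from labels")
        aucs.append(_binary_auc(y_c, s[:, c]))
    return float(np.mean(aucs))


def dice_coefficient(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); two empty masks -> 1 with a warning."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise DataError(f"mask shapes differ: {a.shape} vs {b.shape}")
    size = int(a.sum()) + int(b.sum())
    if size == 0:
        logger.warning("both masks empty; Dice defined as 1")
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / size)
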