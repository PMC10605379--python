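"""Confusion matrices and the classification indicators derived from them.

Binary indicators (sensitivity, specificity, precision, accuracy, F1,
Jaccard) follow the standard 2x2 contingency definitions.  The
multiclass per-class F1 is computed directly from the K x K confusion
matrix as

    F1_j = 2 TP_j / (2 TP_j + sum FP_j + sum FN_j)

where TP_j is the diagonal count for class j, sum FP_j the off-diagonal
sum of column j, and sum FN_j the off-diagonal sum of row j.

Orientation is fixed globally: rows are true classes, columns are
predicted classes.

Zero-division convention: any indicator whose denominator is zero is
defined as 0.  A confusion matrix with no counts at all is rejected as
a structural error rather than silently scored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .catalog import ClassCatalog, as_catalog
from .errors import StructuralError

__all__ = [
    "ConfusionMatrix",
    "MetricSet",
    "build_confusion",
    "binary_metrics",
    "multiclass_f1",
    "per_class_f1",
    "mean_accuracy",
    "macro_f1",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K table of true-class (rows) vs predicted-class (columns) counts."""

    counts: np.ndarray
    catalog: ClassCatalog

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise StructuralError(f"confusion matrix must be square, got shape {counts.shape}")
        if counts.shape[0] != len(self.catalog):
            raise StructuralError(
                f"confusion matrix is {counts.shape[0]}x{counts.shape[0]} but the "
                f"catalog has {len(self.catalog)} classes"
            )
        if np.any(counts < 0):
            raise StructuralError("confusion counts must be nonnegative")
        if not np.allclose(counts, np.round(counts)):
            raise StructuralError("confusion counts must be integers")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        labels = list(self.catalog.labels)
        return pd.DataFrame(self.counts, index=labels, columns=labels)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, catalog: ClassCatalog | None = None) -> "ConfusionMatrix":
        cat = as_catalog(tuple(frame.index) if catalog is None else catalog)
        aligned = frame.loc[list(cat.labels), list(cat.labels)]
        return cls(aligned.to_numpy(), cat)


@dataclass(frozen=True)
class MetricSet:
    """Binary performance indicators computed from one 2x2 contingency table."""

    tpr: float  # sensitivity, TP/(TP+FN)
    tnr: float  # specificity, TN/(TN+FP)
    ppv: float  # precision, TP/(TP+FP)
    acc: float  # accuracy, (TP+TN)/total
    f1: float  # 2TP/(2TP+FP+FN)
    ji: float  # Jaccard index, TP/(TP+FP+FN)

    def as_dict(self) -> dict[str, float]:
        return {
            "TPR": self.tpr,
            "TNR": self.tnr,
            "PPV": self.ppv,
            "ACC": self.acc,
            "F1": self.f1,
            "JI": self.ji,
        }


def _safe_ratio(num: float, den: float) -> float:
    return float(num) / float(den) if den > 0 else 0.0


def build_confusion(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    catalog: ClassCatalog | Sequence[str] | None = None,
) -> ConfusionMatrix:
    """Count true-vs-predicted label pairs into a confusion matrix.

    Both sequences must have equal length and contain only catalog labels.
    """
    cat = as_catalog(catalog)
    if len(true_labels) != len(predicted_labels):
        raise StructuralError(
            f"label sequences differ in length: {len(true_labels)} true vs "
            f"{len(predicted_labels)} predicted"
        )
    for name, seq in (("true", true_labels), ("predicted", predicted_labels)):
        unknown = sorted(set(seq) - set(cat.labels))
        if unknown:
            raise StructuralError(f"unknown {name} labels {unknown!r}; catalog is {cat.labels!r}")
    counts = _sk_confusion(list(true_labels), list(predicted_labels), labels=list(cat.labels))
    return ConfusionMatrix(counts, cat)


def binary_metrics(tp: int, tn: int, fp: int, fn: int) -> MetricSet:
    """Evaluate the six binary indicators from raw TP/TN/FP/FN counts."""
    for name, v in (("tp", tp), ("tn", tn), ("fp", fp), ("fn", fn)):
        if v < 0:
            raise StructuralError(f"count {name} must be nonnegative, got {v}")
    total = tp + tn + fp + fn
    if total == 0:
        raise StructuralError("cannot compute metrics from an all-zero contingency table")
    return MetricSet(
        tpr=_safe_ratio(tp, tp + fn),
        tnr=_safe_ratio(tn, tn + fp),
        ppv=_safe_ratio(tp, tp + fp),
        acc=_safe_ratio(tp + tn, total),
        f1=_safe_ratio(2 * tp, 2 * tp + fp + fn),
        ji=_safe_ratio(tp, tp + fp + fn),
    )


def multiclass_f1(cm: ConfusionMatrix, j: str) -> float:
    """Per-class F1 for class ``j`` from a multiclass confusion matrix."""
    if cm.total == 0:
        raise StructuralError("cannot compute F1 from an empty confusion matrix")
    idx = cm.catalog.index(j)
    tp = cm.counts[idx, idx]
    fp = cm.counts[:, idx].sum() - tp
    fn = cm.counts[idx, :].sum() - tp
    return _safe_ratio(2 * tp, 2 * tp + fp + fn)


def per_class_f1(cm: ConfusionMatrix) -> dict[str, float]:
    """Per-class F1 for every catalog class."""
    return {label: multiclass_f1(cm, label) for label in cm.catalog}


def mean_accuracy(cm: ConfusionMatrix) -> float:
    """Overall accuracy: trace over total count."""
    if cm.total == 0:
        raise StructuralError("cannot compute accuracy from an empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.total


def macro_f1(cm: ConfusionMatrix) -> float:
    """Unweighted mean of the per-class F1 scores (exposed alternative)."""
    scores = per_class_f1(cm)
    return float(np.mean(list(scores.values())))
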