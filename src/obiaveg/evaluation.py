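"""Thematic-accuracy assessment for classified maps.

Confusion matrix plus overall accuracy, per-class producer's (map) and
user's accuracy, and the kappa coefficient.  Orientation is fixed
throughout: rows are the predicted class, columns the reference (true)
class, so producer's accuracy divides the diagonal by the column total
and user's accuracy by the row total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "AccuracyReport",
    "confusion_matrix",
    "overall_accuracy",
    "map_accuracy",
    "user_accuracy",
    "kappa",
    "accuracy_report",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """c x c count matrix; ``counts[r, v]`` = predicted class ``r``, truly ``v``."""

    counts: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if counts.shape[0] != len(self.labels):
            raise ValueError("label count must match matrix size")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if counts.sum() < 1:
            raise ValueError("matrix must contain at least one sample")
        object.__setattr__(self, "counts", counts.astype(np.int64))
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_classes(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown class label {label!r}") from None

    def to_text(self) -> str:
        """Plain-text table, predicted classes down the rows."""
        width = max(8, max(len(str(lbl)) for lbl in self.labels) + 1)
        corner = "pred\\true"
        lines = [f"{corner:<{width}}" + "".join(f"{lbl:>{width}}" for lbl in self.labels)]
        for r, lbl in enumerate(self.labels):
            row = "".join(f"{int(c):>{width}}" for c in self.counts[r])
            lines.append(f"{lbl:<{width}}" + row)
        return "\n".join(lines)


@dataclass(frozen=True)
class AccuracyReport:
    overall: float
    map_accuracy: dict[str, float]
    user_accuracy: dict[str, float]
    kappa: float

    def to_dict(self) -> dict:
        clean = lambda d: {k: (None if v is None or math.isnan(v) else v) for k, v in d.items()}
        return {
            "overall_accuracy": self.overall,
            "map_accuracy": clean(self.map_accuracy),
            "user_accuracy": clean(self.user_accuracy),
            "kappa": None if math.isnan(self.kappa) else self.kappa,
        }


def confusion_matrix(
    true_labels, predicted_labels, label_order: list[str] | None = None
) -> ConfusionMatrix:
    """Tally predictions against reference labels.

    ``label_order`` fixes the row/column ordering; it defaults to the
    sorted union of labels seen.  Labels outside the order are an error.
    """
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences must have equal length")
    if label_order is None:
        label_order = sorted(set(true_labels) | set(predicted_labels))
    idx = {lbl: i for i, lbl in enumerate(label_order)}
    counts = np.zeros((len(label_order), len(label_order)), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        if t not in idx:
            raise KeyError(f"true label {t!r} not in label_order")
        if p not in idx:
            raise KeyError(f"predicted label {p!r} not in label_order")
        counts[idx[p], idx[t]] += 1
    return ConfusionMatrix(counts, tuple(label_order))


def overall_accuracy(cm: ConfusionMatrix, *, printed_variant: bool = False) -> float:
    """Overall accuracy: correctly classified fraction, Σ diag / T.

    ``printed_variant=True`` additionally subtracts Σ diag / c (c = class
    count).  That variant is internally inconsistent — it drives reported
    accuracies negative for any reasonably accurate map — and exists only
    for auditability; the standard ratio is the default.
    """
    diag = float(np.trace(cm.counts))
    oa = diag / cm.total
    if printed_variant:
        return oa - diag / cm.n_classes
    return oa


def map_accuracy(cm: ConfusionMatrix, class_label: str) -> float:
    """Producer's (map) accuracy of one class: diagonal over true-class
    column total.  NaN ("not applicable") when the class never truly occurs."""
    r = cm.index_of(class_label)
    col_total = float(cm.counts[:, r].sum())
    if col_total == 0:
        return float("nan")
    return float(cm.counts[r, r]) / col_total


def user_accuracy(cm: ConfusionMatrix, class_label: str) -> float:
    """User's accuracy of one class: diagonal over predicted-class row
    total.  NaN when the class is never predicted."""
    r = cm.index_of(class_label)
    row_total = float(cm.counts[r, :].sum())
    if row_total == 0:
        return float("nan")
    return float(cm.counts[r, r]) / row_total


def kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement.

    ``(T Σ X_γγ - Σ row_γ col_γ) / (T² - Σ row_γ col_γ)``; NaN when the
    denominator vanishes (all mass concentrated in one row-column pair).
    """
    counts = cm.counts.astype(float)
    t = float(cm.total)
    diag = float(np.trace(counts))
    row_tot = counts.sum(axis=1)
    col_tot = counts.sum(axis=0)
    chance = float((row_tot * col_tot).sum())
    denom = t * t - chance
    if denom == 0:
        return float("nan")
    return (t * diag - chance) / denom


def accuracy_report(cm: ConfusionMatrix) -> AccuracyReport:
    """Bundle overall, per-class and kappa statistics for one matrix."""
    return AccuracyReport(
        overall=overall_accuracy(cm),
        map_accuracy={lbl: map_accuracy(cm, lbl) for lbl in cm.labels},
        user_accuracy={lbl: user_accuracy(cm, lbl) for lbl in cm.labels},
        kappa=kappa(cm),
    )
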