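"""Confusion matrices and one-vs-rest diagnostic metrics.

For each target class the confusion matrix is collapsed one-vs-rest into
TP/TN/FP/FN counts, from which

* accuracy    = (TP + TN) / total
* sensitivity = TP / (TP + FN)
* specificity = TN / (TN + FP)
* F1          = 2 * specificity * sensitivity / (specificity + sensitivity)

all reported in percent.  Note the F1 here is deliberately the harmonic mean
of SPECIFICITY and sensitivity — the convention of this toolkit's diagnostic
report — which differs from the usual precision-recall F1; the conventional
form is available as :func:`precision_recall_f1` under its own name.  Macro
averages run over the four disease classes (AS, MR, MS, MVP), excluding
Normal; the all-class average is available separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from ._core import CLASSES, DISEASE_CLASSES, ValidationError

__all__ = ["ConfusionMatrix", "ClassMetrics", "confusion", "class_metrics",
           "precision_recall_f1", "macro_average", "overall_accuracy",
           "metrics_from_rates", "report_table", "round2"]


def round2(value: float) -> float:
    """Round half-up to 2 decimals (display convention for percentages)."""
    value = float(value)
    if not math.isfinite(value):
        return value
    # pre-quantize at 12 decimals so binary representation noise (~1e-14)
    # cannot flip a half-up decision like 91.105 -> 91.11
    exact = Decimal(repr(value)).quantize(Decimal("1e-12"), rounding=ROUND_HALF_UP)
    return float(exact.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """counts[i, j] = recordings of true class i predicted as class j."""

    counts: np.ndarray
    classes: tuple[str, ...] = CLASSES

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        n = len(self.classes)
        if counts.shape != (n, n):
            raise ValidationError(f"confusion matrix must be {n}x{n}")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            raise ValidationError("confusion counts must be non-negative integers")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, target: str) -> tuple[int, int, int, int]:
        """Collapse to (TP, TN, FP, FN) for ``target`` against all others."""
        if target not in self.classes:
            raise ValidationError(f"unknown target class {target!r}")
        i = self.classes.index(target)
        tp = int(self.counts[i, i])
        fn = int(self.counts[i].sum() - tp)
        fp = int(self.counts[:, i].sum() - tp)
        tn = self.total - tp - fn - fp
        return tp, tn, fp, fn

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes),
                            columns=list(self.classes))


@dataclass(frozen=True)
class ClassMetrics:
    """One-vs-rest metrics in percent; NaN marks an undefined metric."""

    accuracy: float
    sensitivity: float
    specificity: float
    f1: float

    def __post_init__(self) -> None:
        for name in ("accuracy", "sensitivity", "specificity", "f1"):
            v = getattr(self, name)
            if math.isfinite(v) and not 0 <= v <= 100 + 1e-9:
                raise ValidationError(f"{name} = {v} outside [0, 100]")

    def rounded(self) -> dict[str, float]:
        return {name: round2(getattr(self, name))
                for name in ("accuracy", "sensitivity", "specificity", "f1")}


def confusion(y_true, y_pred, classes: tuple[str, ...] = CLASSES) -> ConfusionMatrix:
    """Build the confusion matrix over the canonical class order."""
    y_true = np.asarray(y_true, dtype=str)
    y_pred = np.asarray(y_pred, dtype=str)
    if y_true.size == 0:
        raise ValidationError("cannot build a confusion matrix from empty input")
    if y_true.shape != y_pred.shape:
        raise ValidationError("y_true and y_pred must have equal length")
    known = set(classes)
    bad = (set(y_true.tolist()) | set(y_pred.tolist())) - known
    if bad:
        raise ValidationError(f"unknown labels {sorted(bad)}; expected {classes}")
    counts = _sk_confusion(y_true, y_pred, labels=list(classes))
    return ConfusionMatrix(counts=counts, classes=classes)


def _harmonic_f1(sens: float, spec: float) -> float:
    if not (math.isfinite(sens) and math.isfinite(spec)) or sens + spec == 0:
        return math.nan
    return 2.0 * spec * sens / (spec + sens)


def class_metrics(cm: ConfusionMatrix, target: str) -> ClassMetrics:
    """Accuracy / sensitivity / specificity / F1 for one target class.

    A zero denominator yields NaN (an explicit undefined-metric flag), never
    a silent zero.
    """
    tp, tn, fp, fn = cm.one_vs_rest(target)
    if tp + fn == 0:
        raise ValidationError(f"no true recordings of class {target!r}")
    total = tp + tn + fp + fn
    sens = 100.0 * tp / (tp + fn)
    spec = 100.0 * tn / (tn + fp) if tn + fp > 0 else math.nan
    return ClassMetrics(
        accuracy=100.0 * (tp + tn) / total,
        sensitivity=sens,
        specificity=spec,
        f1=_harmonic_f1(sens, spec),
    )


def metrics_from_rates(sensitivity: float, specificity: float) -> float:
    """F1 (harmonic mean of specificity and sensitivity) from percent rates."""
    return _harmonic_f1(sensitivity, specificity)


def precision_recall_f1(cm: ConfusionMatrix, target: str) -> float:
    """Conventional F1 (harmonic mean of precision and recall), in percent."""
    tp, _, fp, fn = cm.one_vs_rest(target)
    if tp + fn == 0:
        raise ValidationError(f"no true recordings of class {target!r}")
    if tp == 0 and fp == 0:
        return math.nan
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    if precision + recall == 0:
        return math.nan
    return 100.0 * 2 * precision * recall / (precision + recall)


def macro_average(per_class: dict[str, ClassMetrics],
                  classes: tuple[str, ...] = DISEASE_CLASSES) -> ClassMetrics:
    """Unweighted arithmetic mean of each metric over ``classes``.

    The default averages over the four disease classes only (Normal
    excluded); pass ``classes=CLASSES`` for the all-class average.
    """
    missing = [c for c in classes if c not in per_class]
    if missing:
        raise ValidationError(f"missing per-class metrics for {missing}")
    return ClassMetrics(**{
        name: float(np.mean([getattr(per_class[c], name) for c in classes]))
        for name in ("accuracy", "sensitivity", "specificity", "f1")
    })


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Multi-class accuracy in percent: trace / total."""
    if cm.total == 0:
        raise ValidationError("empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def report_table(cm: ConfusionMatrix, rounded_from_display: bool = True) -> pd.DataFrame:
    """Per-class metric table (rows: metrics, columns: classes, percent).

    Macro averages (disease classes only) are appended as a final column.
    When ``rounded_from_display`` is set, macro averages are computed from
    the 2-decimal displayed per-class values, matching how summary rows of a
    printed report are conventionally derived.
    """
    per_class = {c: class_metrics(cm, c) for c in cm.classes
                 if cm.counts[cm.classes.index(c)].sum() > 0}
    cols = {}
    for c in cm.classes:
        if c in per_class:
            cols[c] = per_class[c].rounded()
    if all(c in per_class for c in DISEASE_CLASSES):
        if rounded_from_display:
            src = {c: ClassMetrics(**per_class[c].rounded()) for c in DISEASE_CLASSES}
        else:
            src = per_class
        cols["disease avg"] = macro_average(src).rounded()
    return pd.DataFrame(cols)
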