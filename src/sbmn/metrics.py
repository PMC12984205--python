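"""Confusion-matrix evaluation: accuracy, sensitivity, specificity, PPV, F1.

The positive class is the fracture class throughout (screening prioritizes
catching every fracture, so sensitivity is recall on fractures).  Ratios
with a zero denominator are reported as NaN with a warning, never silently
as zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .exceptions import ValidationError


@dataclass
class ConfusionMatrix:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricTable:
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    f1: float

    def as_dict(self) -> dict:
        return asdict(self)

    def as_percent_strings(self) -> dict:
        """One-decimal percentage rendering for reports."""
        return {k: ("nan" if math.isnan(v) else f"{100.0 * v:.1f}")
                for k, v in self.as_dict().items()}


def confusion(labels_true, labels_pred, positive_class: int = 1) -> ConfusionMatrix:
    """2x2 counts; ``positive_class`` marks the fracture class."""
    yt = np.asarray(labels_true, dtype=int)
    yp = np.asarray(labels_pred, dtype=int)
    if yt.shape != yp.shape:
        raise ValidationError(
            f"label arrays differ in length: {yt.shape} vs {yp.shape}")
    pos_t, pos_p = yt == positive_class, yp == positive_class
    return ConfusionMatrix(TP=int(np.sum(pos_t & pos_p)),
                           FP=int(np.sum(~pos_t & pos_p)),
                           TN=int(np.sum(~pos_t & ~pos_p)),
                           FN=int(np.sum(pos_t & ~pos_p)))


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN",
                      RuntimeWarning, stacklevel=3)
        return float("nan")
    return num / den


def metric_table(cm: ConfusionMatrix) -> MetricTable:
    if cm.total == 0:
        raise ValidationError("cannot compute metrics on an empty confusion matrix")
    accuracy = (cm.TP + cm.TN) / cm.total
    sensitivity = _ratio(cm.TP, cm.TP + cm.FN, "sensitivity")
    specificity = _ratio(cm.TN, cm.TN + cm.FP, "specificity")
    ppv = _ratio(cm.TP, cm.TP + cm.FP, "ppv")
    if math.isnan(sensitivity) or math.isnan(ppv) or (ppv + sensitivity) == 0:
        warnings.warn("f1 undefined; reporting NaN", RuntimeWarning, stacklevel=2)
        f1 = float("nan")
    else:
        f1 = 2.0 * ppv * sensitivity / (ppv + sensitivity)
    return MetricTable(accuracy, sensitivity, specificity, ppv, f1)


def mean_metric_table(tables: list[MetricTable]) -> MetricTable:
    """Arithmetic mean across folds, NaN-propagating."""
    if not tables:
        raise ValidationError("no metric tables to average")
    keys = ("accuracy", "sensitivity", "specificity", "ppv", "f1")
    return MetricTable(**{k: float(np.mean([getattr(t, k) for t in tables]))
                          for k in keys})
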