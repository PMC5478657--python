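"""Binary-classification performance measures and the relative F1 error.

All measures follow the standard confusion-matrix definitions with the
zero-denominator convention that precision, sensitivity and F1 are 0 when
undefined.  The relative F1 error compares two models' F1 errors
(``error = 1 - F1``): it is 1 when the second model is perfect and 0 when
both err equally.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["Metrics", "compute_metrics", "f1_error", "relative_f1_error"]


@dataclass(frozen=True)
class Metrics:
    f1: float
    precision: float
    sensitivity: float
    specificity: float
    accuracy: float
    tp: int
    fp: int
    fn: int
    tn: int

    def to_dict(self) -> dict:
        return asdict(self)


def compute_metrics(y_pred, y_true, positive_class=1) -> Metrics:
    """Confusion-matrix metrics with ``positive_class`` as the positive label."""
    y_pred = np.asarray(y_pred)
    y_true = np.asarray(y_true)
    if len(y_pred) != len(y_true):
        raise ValueError("label vectors differ in length")
    if len(y_true) == 0:
        raise ValueError("empty label vectors")
    pp = y_pred == positive_class
    ap = y_true == positive_class
    tp = int(np.sum(pp & ap))
    fp = int(np.sum(pp & ~ap))
    fn = int(np.sum(~pp & ap))
    tn = int(np.sum(~pp & ~ap))
    precision = tp / (tp + fp) if tp + fp else 0.0
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    accuracy = (tp + tn) / len(y_true)
    f1 = (2 * precision * sensitivity / (precision + sensitivity)
          if precision + sensitivity else 0.0)
    return Metrics(f1, precision, sensitivity, specificity, accuracy,
                   tp, fp, fn, tn)


def f1_error(f1: float) -> float:
    """F1 error of a model: 1 - F1."""
    return 1.0 - f1


def relative_f1_error(m1_f1: float, m2_f1: float) -> float:
    """Relative F1 error of model 2 with respect to model 1.

    ``(error(m1) - error(m2)) / error(m1)``; requires ``m1_f1 < 1``.
    """
    e1 = f1_error(m1_f1)
    if e1 == 0.0:
        raise ValueError("relative F1 error undefined when the reference F1 is 1")
    return (e1 - f1_error(m2_f1)) / e1
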