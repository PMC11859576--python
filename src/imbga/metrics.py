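"""Binary-classification evaluation: threshold metrics, ROC curve, AUC.

By package convention the positive class for recall / precision / F-score is
the minority outcome (label 0) — the rare clinical event the pipeline is
meant to detect — and ``y_score`` is the score assigned to that positive
class.  AUC is threshold-free, computed by trapezoidal integration of the
ROC curve; it equals the Mann-Whitney pair-ordering probability with the
midpoint (0.5-credit) tie convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    auc as _trapezoid_auc,
    f1_score,
    precision_score,
    recall_score,
    roc_curve,
)


@dataclass
class EvalReport:
    accuracy: float
    precision: float
    recall: float
    f_score: float
    auc: float
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    positive_class_label: int = 0

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f_score": self.f_score,
            "auc": self.auc,
            "positive_class_label": self.positive_class_label,
            "roc_points": [list(p) for p in self.roc_points],
        }


def classification_report(
    y_true,
    y_score,
    threshold: float = 0.5,
    positive_label: int = 0,
) -> EvalReport:
    """Evaluate scores against binary labels.

    ``y_score[i]`` is the score for ``positive_label``; samples with score
    >= ``threshold`` are predicted positive.  Raises on single-class
    ``y_true`` (AUC undefined).
    """
    y_true = np.asarray(y_true, dtype=int)
    y_score = np.asarray(y_score, dtype=float)
    if y_true.shape != y_score.shape:
        raise ValueError("y_true and y_score must have equal length")
    if positive_label not in (0, 1):
        raise ValueError("positive_label must be 0 or 1")
    if len(np.unique(y_true)) < 2:
        raise ValueError("y_true contains a single class; AUC is undefined")

    is_pos = (y_true == positive_label).astype(int)
    y_pred = (y_score >= threshold).astype(int)

    fpr, tpr, thresh = roc_curve(is_pos, y_score)
    report = EvalReport(
        accuracy=float(accuracy_score(is_pos, y_pred)),
        precision=float(precision_score(is_pos, y_pred, zero_division=0)),
        recall=float(recall_score(is_pos, y_pred, zero_division=0)),
        f_score=float(f1_score(is_pos, y_pred, zero_division=0)),
        auc=float(_trapezoid_auc(fpr, tpr)),
        roc_points=list(zip(fpr.tolist(), tpr.tolist())),
        positive_class_label=positive_label,
    )
    return report


def roc_table(y_true, y_score, positive_label: int = 0) -> list[tuple[float, float, float]]:
    """(fpr, tpr, threshold) rows for plotting / CSV export."""
    y_true = np.asarray(y_true, dtype=int)
    fpr, tpr, thr = roc_curve((y_true == positive_label).astype(int), np.asarray(y_score))
    return list(zip(fpr.tolist(), tpr.tolist(), thr.tolist()))
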