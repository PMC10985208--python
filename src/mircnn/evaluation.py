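"""Confusion-matrix bookkeeping and classification metrics.

Conventions: label/prediction 1 = miRNA (positive class), 0 = other.
Accuracy = (TP+TN)/(TP+FP+FN+TN), Precision = TP/(TP+FP),
Recall = TP/(TP+FN), F1 = 2*TP/(2*TP+FP+FN).  Ratios with a vanishing
denominator are reported as NaN with a warning rather than silently 0.
Cross-validation results are averaged as the unweighted mean of per-fold
metrics; pooled counts are also carried for reference.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence, Tuple


@dataclass
class MetricsReport:
    TP: int
    FP: int
    TN: int
    FN: int
    accuracy: float
    precision: float
    recall: float
    f1: float

    def as_dict(self) -> dict:
        return {
            "TP": self.TP, "FP": self.FP, "TN": self.TN, "FN": self.FN,
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1,
        }


def confusion(
    labels: Sequence[int], predictions: Sequence[int]
) -> Tuple[int, int, int, int]:
    """(TP, FP, TN, FN) for binary labels/predictions; counts partition N."""
    if len(labels) != len(predictions):
        raise ValueError(
            f"length mismatch: {len(labels)} labels vs {len(predictions)} predictions"
        )
    TP = FP = TN = FN = 0
    for y, p in zip(labels, predictions):
        if y == 1 and p == 1:
            TP += 1
        elif y == 0 and p == 1:
            FP += 1
        elif y == 0 and p == 0:
            TN += 1
        else:
            FN += 1
    return TP, FP, TN, FN


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN")
        return math.nan
    return num / den


def metrics(TP: int, FP: int, TN: int, FN: int) -> MetricsReport:
    """The four metrics from raw confusion counts."""
    if min(TP, FP, TN, FN) < 0:
        raise ValueError("confusion counts must be non-negative")
    total = TP + FP + TN + FN
    if total == 0:
        raise ValueError("all confusion counts are zero")
    return MetricsReport(
        TP=TP, FP=FP, TN=TN, FN=FN,
        accuracy=(TP + TN) / total,
        precision=_ratio(TP, TP + FP, "precision"),
        recall=_ratio(TP, TP + FN, "recall"),
        f1=_ratio(2 * TP, 2 * TP + FP + FN, "F1"),
    )


def mean_report(reports: Sequence[MetricsReport]) -> MetricsReport:
    """Unweighted mean of per-fold metrics; counts are pooled sums."""
    if not reports:
        raise ValueError("no reports to average")
    k = len(reports)
    return MetricsReport(
        TP=sum(r.TP for r in reports),
        FP=sum(r.FP for r in reports),
        TN=sum(r.TN for r in reports),
        FN=sum(r.FN for r in reports),
        accuracy=sum(r.accuracy for r in reports) / k,
        precision=sum(r.precision for r in reports) / k,
        recall=sum(r.recall for r in reports) / k,
        f1=sum(r.f1 for r in reports) / k,
    )
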