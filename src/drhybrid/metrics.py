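"""Confusion matrices and the five evaluation metrics.

Accuracy is 5-class trace accuracy.  Sensitivity, specificity, precision and
F1 are binary metrics computed after collapsing the 5x5 matrix to a chosen
positive grade versus the rest.  The default positive grade is 0 ("no DR"):
that collapse is the one under which the reference results for the fusers
reconcile numerically (the clinical convention of positive = diseased
differs, so the parameter is exposed).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

N_GRADES = 5

__all__ = [
    "ConfusionMatrix",
    "BinaryCounts",
    "MetricsReport",
    "confusion_matrix",
    "multiclass_accuracy",
    "binary_metrics",
    "confusion_percentages",
    "evaluate_model",
    "format_report",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """5x5 counts; rows = actual grade, columns = predicted grade."""

    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (N_GRADES, N_GRADES):
            raise ValueError(f"expected {N_GRADES}x{N_GRADES} counts, got {counts.shape}")
        if np.any(counts < 0):
            raise ValueError("confusion counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass(frozen=True)
class BinaryCounts:
    """TP/TN/FP/FN after collapsing to positive_grade vs the rest."""

    tp: int
    tn: int
    fp: int
    fn: int
    positive_grade: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    positive_grade: int = 0
    undefined: tuple[str, ...] = field(default_factory=tuple)

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f1": self.f1,
        }


def confusion_matrix(true_grades, predicted_grades) -> ConfusionMatrix:
    t = np.asarray(true_grades, dtype=np.int64)
    p = np.asarray(predicted_grades, dtype=np.int64)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError("true and predicted grades must be equal-length 1-D sequences")
    if t.size and (t.min() < 0 or t.max() >= N_GRADES or p.min() < 0 or p.max() >= N_GRADES):
        raise ValueError(f"grades must lie in [0, {N_GRADES})")
    counts = np.zeros((N_GRADES, N_GRADES), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts)


def multiclass_accuracy(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.total


def binary_metrics(cm: ConfusionMatrix, positive_grade: int) -> tuple[BinaryCounts, dict[str, float]]:
    """Collapse to positive vs rest; divisions by zero yield NaN, flagged in the dict."""
    if not 0 <= positive_grade < N_GRADES:
        raise ValueError(f"positive_grade must lie in [0, {N_GRADES})")
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    c = cm.counts
    tp = int(c[positive_grade, positive_grade])
    fn = int(c[positive_grade, :].sum()) - tp
    fp = int(c[:, positive_grade].sum()) - tp
    tn = cm.total - tp - fn - fp
    bc = BinaryCounts(tp=tp, tn=tn, fp=fp, fn=fn, positive_grade=positive_grade)

    def ratio(num: int, den: int) -> float:
        return num / den if den else math.nan

    out = {
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "precision": ratio(tp, tp + fp),
    }
    ps = out["precision"] + out["sensitivity"]
    out["f1"] = (2 * out["precision"] * out["sensitivity"] / ps) if ps > 0 else math.nan
    return bc, out


def confusion_percentages(cm: ConfusionMatrix, decimals: int = 2) -> np.ndarray:
    """Row-normalized percentages; rows with zero total come back as NaN."""
    totals = cm.row_totals().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * cm.counts / totals[:, None]
    return np.round(pct, decimals)


def evaluate_model(true_grades, predicted_grades,
                   positive_grade: int = 0) -> tuple[MetricsReport, ConfusionMatrix]:
    cm = confusion_matrix(true_grades, predicted_grades)
    bc, binm = binary_metrics(cm, positive_grade)
    undefined = tuple(k for k, v in binm.items() if math.isnan(v))
    report = MetricsReport(
        accuracy=multiclass_accuracy(cm),
        sensitivity=binm["sensitivity"],
        specificity=binm["specificity"],
        precision=binm["precision"],
        f1=binm["f1"],
        positive_grade=positive_grade,
        undefined=undefined,
    )
    return report, cm


def format_report(report: MetricsReport, cm: ConfusionMatrix | None = None) -> str:
    """Pretty table: 4-decimal metrics, count/percent confusion cells."""
    lines = ["metric        value",
             "-" * 19]
    for name, value in report.as_dict().items():
        shown = "undefined" if math.isnan(value) else f"{value:.4f}"
        lines.append(f"{name:<12}  {shown}")
    lines.append(f"(positive grade for binary metrics: {report.positive_grade})")
    if cm is not None:
        pct = confusion_percentages(cm)
        lines.append("")
        lines.append("actual\\pred  " + "".join(f"{j:>14d}" for j in range(N_GRADES)))
        for i in range(N_GRADES):
            cells = "".join(
                f"{cm.counts[i, j]:>7d}/{pct[i, j]:6.2f}" for j in range(N_GRADES)
            )
            lines.append(f"{i:>11d}  {cells}")
    return "\n".join(lines)
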