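"""Evaluation: confusion matrix, accuracy/precision/recall/F1, ROC/AUC, kappa.

The positive class is the ADR post (label 1).  Undefined ratios (zero
denominators) are reported as NaN with a warning, never silently as 0.  The
ROC sweep classifies at every distinct score plus endpoints above the maximum
score and at 0, so the curve runs from (0, 0) to (1, 1); AUC is trapezoidal
over (FPR, TPR).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

PRINTED_GRID = tuple(round(0.1 * i, 1) for i in range(1, 11))  # 0.1 ... 1.0


def _as_binary(v, name: str) -> np.ndarray:
    arr = np.asarray(v)
    if arr.ndim != 1 or arr.size < 1:
        raise ValueError(f"{name} must be a non-empty 1-D vector")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 entries")
    return arr.astype(np.int64)


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion matrix must count at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn}


@dataclass(frozen=True)
class MetricReport:
    accuracy: float
    precision: float
    recall: float
    f1: float

    def rounded(self) -> dict:
        """Display rounding: integer percent accuracy, two-decimal ratios."""
        return {
            "accuracy_pct": round(self.accuracy * 100),
            "precision": round(self.precision, 2) if not math.isnan(self.precision) else None,
            "recall": round(self.recall, 2) if not math.isnan(self.recall) else None,
            "f1": round(self.f1, 2) if not math.isnan(self.f1) else None,
        }


def confusion(y_true, y_pred) -> ConfusionMatrix:
    yt = _as_binary(y_true, "y_true")
    yp = _as_binary(y_pred, "y_pred")
    if yt.shape != yp.shape:
        raise ValueError(f"length mismatch: {yt.size} true vs {yp.size} predicted")
    tp = int(((yt == 1) & (yp == 1)).sum())
    fp = int(((yt == 0) & (yp == 1)).sum())
    fn = int(((yt == 1) & (yp == 0)).sum())
    tn = int(((yt == 0) & (yp == 0)).sum())
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def metrics(cm: ConfusionMatrix) -> MetricReport:
    """Accuracy, precision, recall, F1 for the positive (ADR) class."""
    accuracy = (cm.tp + cm.tn) / cm.total

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reporting NaN", stacklevel=3)
            return float("nan")
        return num / den

    precision = ratio(cm.tp, cm.tp + cm.fp, "precision")
    recall = ratio(cm.tp, cm.tp + cm.fn, "recall")
    f1 = ratio(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn, "f1")
    return MetricReport(accuracy=accuracy, precision=precision, recall=recall, f1=f1)


@dataclass
class RocCurve:
    thresholds: np.ndarray  # descending sweep
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    accuracy_by_threshold: dict[float, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "thresholds": [None if np.isinf(t) else float(t) for t in self.thresholds],
            "fpr": self.fpr.tolist(),
            "tpr": self.tpr.tolist(),
            "auc": self.auc,
            "accuracy_by_threshold": {f"{k:g}": v for k, v in self.accuracy_by_threshold.items()},
        }


def roc(y_true, scores, grid: Optional[Sequence[float]] = None) -> RocCurve:
    """Threshold-sweep ROC curve with trapezoidal AUC.

    The sweep uses every distinct score as a cut point (prediction is
    ``score >= threshold``) bracketed by a value above max(scores) and by 0,
    so FPR/TPR rise monotonically from (0, 0) to (1, 1).
    ``accuracy_by_threshold`` is reported on the printed-style 0.1..1.0 grid
    (plus any user grid).
    """
    yt = _as_binary(y_true, "y_true")
    s = np.asarray(scores, dtype=float)
    if s.shape != yt.shape:
        raise ValueError(f"length mismatch: {yt.size} labels vs {s.size} scores")
    if (s < 0).any() or (s > 1).any():
        raise ValueError("scores must lie in [0, 1]")
    n_pos = int(yt.sum())
    n_neg = int(yt.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC/AUC undefined for single-class y_true")

    cuts = np.unique(s)[::-1]
    thresholds = np.concatenate(([np.inf], cuts, [0.0] if cuts[-1] > 0.0 else []))
    fpr_list, tpr_list = [], []
    for t in thresholds:
        pred = s >= t
        tp = int((pred & (yt == 1)).sum())
        fp = int((pred & (yt == 0)).sum())
        fpr_list.append(fp / n_neg)
        tpr_list.append(tp / n_pos)
    fpr = np.asarray(fpr_list)
    tpr = np.asarray(tpr_list)
    auc = float(np.trapezoid(tpr, fpr))

    acc = {}
    grid_all = sorted(set(PRINTED_GRID) | set(float(g) for g in (grid or [])))
    for t in grid_all:
        pred = (s >= t).astype(np.int64)
        acc[float(t)] = float((pred == yt).mean())
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc, accuracy_by_threshold=acc)


def plot_roc(curve: RocCurve, path, title: str = "ROC") -> None:
    """Optional ROC plot (PNG) for reports."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(curve.fpr, curve.tpr, marker=".", label=f"AUC = {curve.auc:.2f}")
    ax.plot([0, 1], [0, 1], linestyle="--", color="grey", linewidth=1)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title(title)
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def cohens_kappa(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two raters on binary labels.

    kappa = (p_o - p_e) / (1 - p_e); when p_e == 1 (degenerate marginals)
    kappa is 1 for perfect agreement, else 0 by convention.
    """
    a = _as_binary(labels_a, "labels_a")
    b = _as_binary(labels_b, "labels_b")
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    n = a.size
    p_o = float((a == b).mean())
    pa1, pb1 = float(a.mean()), float(b.mean())
    p_e = pa1 * pb1 + (1 - pa1) * (1 - pb1)
    if abs(1.0 - p_e) < 1e-15:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def fleiss_kappa(ratings) -> float:
    """Fleiss' kappa for an n_items x n_raters matrix of binary ratings."""
    arr = np.asarray(ratings)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("ratings must be an n_items x n_raters matrix with >= 2 raters")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("ratings must be binary (0/1)")
    n_items, n_raters = arr.shape
    counts = np.stack([(arr == 0).sum(axis=1), (arr == 1).sum(axis=1)], axis=1)  # n_items x 2
    p_j = counts.sum(axis=0) / (n_items * n_raters)
    p_i = ((counts**2).sum(axis=1) - n_raters) / (n_raters * (n_raters - 1))
    p_bar = float(p_i.mean())
    p_e = float((p_j**2).sum())
    if abs(1.0 - p_e) < 1e-15:
        return 1.0 if p_bar == 1.0 else 0.0
    return (p_bar - p_e) / (1.0 - p_e)


def evaluation_report(y_true, scores, threshold: float = 0.5) -> dict:
    """Machine-readable evaluation bundle: confusion, metrics, ROC, AUC."""
    yt = _as_binary(y_true, "y_true")
    s = np.asarray(scores, dtype=float)
    pred = (s >= threshold).astype(np.int64)
    cm = confusion(yt, pred)
    rep = metrics(cm)
    curve = roc(yt, s)
    return {
        "threshold": threshold,
        "confusion": cm.as_dict(),
        "metrics": {
            "accuracy": rep.accuracy,
            "precision": rep.precision,
            "recall": rep.recall,
            "f1": rep.f1,
        },
        "display": rep.rounded(),
        "roc": curve.as_dict(),
        "auc": curve.auc,
    }
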