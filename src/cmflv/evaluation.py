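"""Segmentation quality metrics and ROC analysis.

Voxelwise confusion counts give the five standard overlap metrics:

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    IoU       = TP / (TP + FP + FN)
    Dice      = 2 TP / (2 TP + FP + FN)

Metrics with a zero denominator are reported as NaN and excluded from
group averages (with a count note).  The ROC curve sweeps the cut level
of the relaxed label against a hard truth mask — effectively the CDF of
the segmentation probability — and the AUC is the trapezoid integral.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cmf_solver import threshold_label
from .core_grid_io import BinaryMask, GridError, LabelField

__all__ = [
    "ConfusionCounts",
    "confusion",
    "metrics",
    "roc_curve",
    "auc",
    "group_summary",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion(pred: BinaryMask, truth: BinaryMask) -> ConfusionCounts:
    """Voxelwise confusion counts of a predicted vs a reference mask."""
    if pred.shape != truth.shape:
        raise GridError("prediction/truth grid mismatch")
    p = pred.mask.astype(bool)
    t = truth.mask.astype(bool)
    return ConfusionCounts(
        TP=int(np.sum(p & t)),
        TN=int(np.sum(~p & ~t)),
        FP=int(np.sum(p & ~t)),
        FN=int(np.sum(~p & t)),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def metrics(cc: ConfusionCounts) -> dict:
    """Accuracy, precision, recall, IoU and Dice from confusion counts."""
    return {
        "accuracy": _ratio(cc.TP + cc.TN, cc.total),
        "precision": _ratio(cc.TP, cc.TP + cc.FP),
        "recall": _ratio(cc.TP, cc.TP + cc.FN),
        "iou": _ratio(cc.TP, cc.TP + cc.FP + cc.FN),
        "dice": _ratio(2 * cc.TP, 2 * cc.TP + cc.FP + cc.FN),
    }


def roc_curve(lam: LabelField, truth: BinaryMask, n_thresholds: int = 99):
    """(FPR, TPR) pairs over thresholds in (0, 1), sorted by FPR.

    Uses pooled voxels; raises if the truth contains only one class.
    """
    if n_thresholds < 2:
        raise ValueError("need n_thresholds >= 2")
    t = truth.mask.astype(bool)
    if t.all() or not t.any():
        raise ValueError("truth mask is single-class; ROC undefined")
    pts = []
    for thr in np.linspace(0.0, 1.0, n_thresholds + 2)[1:-1]:
        pred = threshold_label(lam, float(thr)).mask.astype(bool)
        tp = np.sum(pred & t)
        fp = np.sum(pred & ~t)
        pts.append((fp / np.sum(~t), tp / np.sum(t)))
    pts.extend([(0.0, 0.0), (1.0, 1.0)])
    pts.sort()
    return np.array(pts)


def auc(curve: np.ndarray) -> float:
    """Trapezoid area under an (FPR, TPR) curve sorted by FPR."""
    return float(np.trapezoid(curve[:, 1], curve[:, 0]))


def group_summary(metric_dicts: list) -> dict:
    """Per-metric mean +/- sample SD (ddof=1), NaN entries excluded.

    Returns {metric: (mean, sd, n_used)}; averages the way grouped
    results are reported per dataset.
    """
    out = {}
    keys = metric_dicts[0].keys() if metric_dicts else ()
    for k in keys:
        vals = np.array([d[k] for d in metric_dicts], dtype=np.float64)
        vals = vals[np.isfinite(vals)]
        n = vals.size
        mean = float(vals.mean()) if n else float("nan")
        sd = float(vals.std(ddof=1)) if n > 1 else float("nan")
        out[k] = (mean, sd, n)
    return out
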