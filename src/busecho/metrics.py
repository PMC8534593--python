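"""Confusion-matrix metrics and ROC/AUC evaluation.

Implements the standard binary summaries

    sensitivity = TP / (TP + FN)
    precision   = TP / (TP + FP)
    accuracy    = (TN + TP) / (FP + TN + FN + TP)

plus specificity = TN / (TN + FP), their one-vs-rest reduction from a
multi-class confusion matrix, and ROC curves by threshold sweep with
trapezoidal AUC.  For segmentation, the ROC samples are the pixels of one
image (ground-truth tumor pixels positive, the predicted probability map as
scores), giving a per-image AUC; ``auc_summary`` reports the fraction of
images above an AUC cutoff.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from busecho.classical import ConfusionMatrix
from busecho.dataio import TUMOR_LABEL, _TUMOR_ALIAS


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero; refusing to report a silent 0."""


@dataclasses.dataclass
class BinaryCounts:
    """TP/FP/TN/FN counts for one positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclasses.dataclass
class ROCCurve:
    """Threshold-sweep ROC: (fpr, tpr) from (0,0) to (1,1), AUC by trapezoid."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        raise UndefinedMetricError(f"{name} undefined: denominator is zero")
    return num / den


def sensitivity(c: BinaryCounts) -> float:
    """TP / (TP + FN), a.k.a. recall / true-positive rate."""
    return _ratio(c.tp, c.tp + c.fn, "sensitivity")


def precision(c: BinaryCounts) -> float:
    """TP / (TP + FP), a.k.a. positive predictive value."""
    return _ratio(c.tp, c.tp + c.fp, "precision")


def accuracy(c: BinaryCounts) -> float:
    """(TN + TP) / (FP + TN + FN + TP)."""
    return _ratio(c.tn + c.tp, c.total, "accuracy")


def specificity(c: BinaryCounts) -> float:
    """TN / (TN + FP); provided alongside the core three for completeness."""
    return _ratio(c.tn, c.tn + c.fp, "specificity")


def one_vs_rest_counts(cm: ConfusionMatrix, positive_class) -> BinaryCounts:
    """Reduce a multi-class confusion matrix to binary counts for one class."""
    matches = np.nonzero(cm.classes == positive_class)[0]
    if len(matches) != 1:
        raise ValueError(f"unknown class {positive_class!r}; classes are {list(cm.classes)}")
    i = int(matches[0])
    counts = cm.counts
    tp = int(counts[i, i])
    fn = int(counts[i, :].sum()) - tp
    fp = int(counts[:, i].sum()) - tp
    tn = int(counts.sum()) - tp - fn - fp
    return BinaryCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def roc_curve(scores: np.ndarray, truth: np.ndarray) -> ROCCurve:
    """ROC by sweeping thresholds over the unique score values.

    Equal scores are grouped (one sweep point per unique score), which
    handles ties correctly; AUC is the trapezoidal area and equals the
    Mann-Whitney concordance statistic.
    """
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(truth).ravel().astype(bool)
    if s.shape != y.shape:
        raise ValueError("scores and truth must have the same length")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present in truth")

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    # group ties: keep the last index of each run of equal scores
    is_end = np.empty(len(s_sorted), dtype=bool)
    is_end[-1] = True
    is_end[:-1] = s_sorted[1:] != s_sorted[:-1]
    cum_tp = np.cumsum(y_sorted)[is_end]
    cum_fp = np.cumsum(~y_sorted)[is_end]

    tpr = np.concatenate([[0.0], cum_tp / n_pos])
    fpr = np.concatenate([[0.0], cum_fp / n_neg])
    thresholds = np.concatenate([[np.inf], s_sorted[is_end]])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


def per_image_auc(prob_map: np.ndarray, gt_mask: np.ndarray) -> float:
    """Pixel-level ROC AUC of one image's tumor-probability map.

    Positives are ground-truth tumor pixels (255, or the legacy 225);
    every other pixel is a negative.  Raises if the ground truth is
    single-class — callers should exclude such images with a logged reason.
    """
    prob = np.asarray(prob_map, dtype=float)
    gt = np.asarray(gt_mask)
    if prob.shape != gt.shape:
        raise ValueError("probability map and mask must share a shape")
    positives = (gt == TUMOR_LABEL) | (gt == _TUMOR_ALIAS)
    if not positives.any() or positives.all():
        raise ValueError("ground truth must contain both tumor and non-tumor pixels")
    return roc_curve(prob.ravel(), positives.ravel()).auc


def auc_summary(aucs, cutoff: float = 0.6) -> float:
    """Fraction of images with per-image AUC strictly above ``cutoff``."""
    arr = np.asarray(list(aucs), dtype=float)
    if arr.size == 0:
        raise ValueError("no AUC values given")
    return float(np.mean(arr > cutoff))
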