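"""Evaluation metrics.

Segmentation quality is scored from a c x c pixel confusion matrix whose
entry n[i][j] counts pixels of true class i predicted as class j:

    pixel accuracy  =  sum_i n_ii / sum_ij n_ij
    mean IoU        =  (1/c) sum_i n_ii / (row_i + col_i - n_ii)
    avg precision   =  (1/c) sum_i n_ii / col_i
    avg recall      =  (1/c) sum_i n_ii / row_i

Counting quality compares per-image integer predictions with ground truth:
percent agreement (exact matches), signed and absolute count difference
(mean and SD), and mean squared error.

Absent-class policy for the class-averaged scores: a class with no ground
truth *and* no predicted pixels contributes a perfect 1 to the average; a
class present on only one side contributes its literal ratio, 0.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "ConfusionMatrix", "SegScores", "CountScores", "confusion",
    "pixel_accuracy", "mean_iou", "avg_precision", "avg_recall",
    "seg_scores", "count_scores",
]


@dataclass
class ConfusionMatrix:
    n: np.ndarray  # (c, c) int64
    c: int

    def __post_init__(self):
        self.n = np.asarray(self.n, dtype=np.int64)
        if self.n.shape != (self.c, self.c):
            raise ValueError(f"confusion matrix must be {self.c}x{self.c}")
        if (self.n < 0).any():
            raise ValueError("confusion matrix entries must be non-negative")

    @property
    def total(self) -> int:
        return int(self.n.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.c != other.c:
            raise ValueError("class-count mismatch")
        return ConfusionMatrix(self.n + other.n, self.c)


@dataclass
class SegScores:
    pixel_accuracy: float
    mean_iou: float
    avg_precision: float
    avg_recall: float

    def as_dict(self):
        return asdict(self)


@dataclass
class CountScores:
    percent_agreement: float   # [0, 100]
    count_diff_mean: float     # signed roots
    count_diff_sd: float
    abs_count_diff_mean: float
    abs_count_diff_sd: float
    mse: float                 # roots^2
    n: int

    def as_dict(self):
        return asdict(self)


def confusion(gt: np.ndarray, pred: np.ndarray, c: int) -> ConfusionMatrix:
    """Pixel confusion matrix between two label rasters with classes [0, c)."""
    gt = np.asarray(gt)
    pred = np.asarray(pred)
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {pred.shape}")
    g = gt.ravel().astype(np.int64)
    p = pred.ravel().astype(np.int64)
    if g.size and (g.min() < 0 or g.max() >= c or p.min() < 0 or p.max() >= c):
        raise ValueError(f"labels must lie in [0, {c})")
    n = np.bincount(g * c + p, minlength=c * c).reshape(c, c)
    return ConfusionMatrix(n, c)


def pixel_accuracy(cm: ConfusionMatrix) -> float:
    total = cm.total
    if total == 0:
        raise ValueError("pixel accuracy undefined on an empty confusion matrix")
    return float(np.trace(cm.n) / total)


def _class_average(diag, denom) -> float:
    # absent on both sides -> perfect; otherwise literal ratio
    ratios = np.where(denom > 0, diag / np.where(denom > 0, denom, 1), 1.0)
    return float(ratios.mean())


def mean_iou(cm: ConfusionMatrix) -> float:
    diag = np.diag(cm.n).astype(float)
    denom = cm.n.sum(axis=1) + cm.n.sum(axis=0) - np.diag(cm.n)
    return _class_average(diag, denom.astype(float))


def avg_precision(cm: ConfusionMatrix) -> float:
    diag = np.diag(cm.n).astype(float)
    col = cm.n.sum(axis=0).astype(float)
    row = cm.n.sum(axis=1).astype(float)
    # class absent on both sides is perfect; predicted-only (row 0, col > 0)
    # scores its literal 0
    denom = np.where((col == 0) & (row == 0), 0.0, col)
    ratios = np.where(denom > 0, diag / np.where(denom > 0, denom, 1), np.where(row == 0, 1.0, 0.0))
    return float(ratios.mean())


def avg_recall(cm: ConfusionMatrix) -> float:
    diag = np.diag(cm.n).astype(float)
    row = cm.n.sum(axis=1).astype(float)
    col = cm.n.sum(axis=0).astype(float)
    denom = np.where((col == 0) & (row == 0), 0.0, row)
    ratios = np.where(denom > 0, diag / np.where(denom > 0, denom, 1), np.where(col == 0, 1.0, 0.0))
    return float(ratios.mean())


def seg_scores(cm: ConfusionMatrix) -> SegScores:
    return SegScores(
        pixel_accuracy=pixel_accuracy(cm),
        mean_iou=mean_iou(cm),
        avg_precision=avg_precision(cm),
        avg_recall=avg_recall(cm),
    )


def count_scores(pred, gt, ddof: int = 0) -> CountScores:
    """Counting metrics over paired per-image predictions.

    SD uses the population divisor N by default (``ddof=0``); pass
    ``ddof=1`` for the sample SD.
    """
    pred = np.asarray(pred, dtype=float)
    gt = np.asarray(gt, dtype=float)
    if pred.shape != gt.shape or pred.ndim != 1:
        raise ValueError("pred and gt must be 1-D arrays of equal length")
    if pred.size == 0:
        raise ValueError("empty input")
    diff = pred - gt
    adiff = np.abs(diff)
    return CountScores(
        percent_agreement=float(100.0 * np.mean(pred == gt)),
        count_diff_mean=float(diff.mean()),
        count_diff_sd=float(diff.std(ddof=ddof)),
        abs_count_diff_mean=float(adiff.mean()),
        abs_count_diff_sd=float(adiff.std(ddof=ddof)),
        mse=float(np.mean(diff ** 2)),
        n=int(pred.size),
    )
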