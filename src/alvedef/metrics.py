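"""Evaluation suite: keypoint localisation, length agreement, and
disease-detection statistics.

Three families of measures are computed, per defect class and at two
granularities (individual slice and tooth-level consensus):

* keypoint localisation — recognition rate (fraction of ground-truth
  endpoints with a predicted endpoint of the same class and role within a
  tolerance) and the distribution of Euclidean distances over recognised
  points (mean AED, SD, quartiles), all in mm;
* length agreement — MAE, RMSE, mean relative error, Pearson correlation,
  and Bland–Altman bias with 95% limits of agreement;
* detection — accuracy, recall, precision, specificity, F1 from the
  confusion counts, plus a trapezoidal ROC/AUC over confidence scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "KeypointStats",
    "LengthStats",
    "AgreementStats",
    "match_keypoints",
    "keypoint_stats",
    "length_stats",
    "bland_altman",
    "classification_stats",
    "roc_auc",
    "cohen_kappa",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @classmethod
    def from_labels(cls, predicted, truth) -> "ConfusionCounts":
        predicted = np.asarray(predicted, dtype=bool)
        truth = np.asarray(truth, dtype=bool)
        if predicted.shape != truth.shape:
            raise ValueError("label vectors must have the same length")
        return cls(
            tp=int(np.sum(predicted & truth)),
            tn=int(np.sum(~predicted & ~truth)),
            fp=int(np.sum(predicted & ~truth)),
            fn=int(np.sum(~predicted & truth)),
        )


@dataclass(frozen=True)
class KeypointStats:
    recognition_rate: float
    aed_mm: float | None
    sd_mm: float | None
    q1_mm: float | None
    median_mm: float | None
    q3_mm: float | None
    n_recognized: int
    n_truth: int


@dataclass(frozen=True)
class LengthStats:
    mae: float
    rmse: float
    mre: float
    pcc: float | None
    n: int


@dataclass(frozen=True)
class AgreementStats:
    bias: float
    loa_low: float
    loa_high: float
    sd: float


def match_keypoints(
    predicted: list[tuple] , truth: list[tuple], tolerance_mm: float
) -> tuple[float, np.ndarray]:
    """Match predicted to ground-truth endpoints and score recognition.

    Both inputs are lists of records ``(key, x_mm, y_mm)`` where ``key``
    identifies the slice, defect class and endpoint role (so at most one
    prediction can correspond to each truth point).  A truth point is
    recognised iff a prediction with the same key lies within
    ``tolerance_mm``; distances are collected over recognised points only.
    """
    if tolerance_mm <= 0:
        raise ValueError("tolerance_mm must be positive")
    pred_by_key = {k: np.array([x, y]) for k, x, y in predicted}
    distances = []
    recognized = 0
    for k, x, y in truth:
        p = pred_by_key.get(k)
        if p is None:
            continue
        d = float(np.hypot(p[0] - x, p[1] - y))
        if d <= tolerance_mm:
            recognized += 1
            distances.append(d)
    n_truth = len(truth)
    rate = recognized / n_truth if n_truth else 0.0
    return rate, np.asarray(distances, dtype=float)


def keypoint_stats(
    distances: np.ndarray,
    recognition_rate: float = float("nan"),
    n_truth: int = 0,
    sample_sd: bool = True,
) -> KeypointStats:
    """Distribution statistics of the recognised-endpoint distances (mm).

    Quartiles use linear interpolation; SD is the sample (n-1) estimator by
    default.
    """
    distances = np.asarray(distances, dtype=float)
    if distances.size == 0:
        raise ValueError("keypoint_stats requires at least one distance")
    if distances.size == 1:
        logger.info("keypoint_stats on a single sample: SD reported as 0")
        sd = 0.0
    else:
        sd = float(np.std(distances, ddof=1 if sample_sd else 0))
    q1, med, q3 = np.percentile(distances, [25, 50, 75])
    return KeypointStats(
        recognition_rate=recognition_rate,
        aed_mm=float(np.mean(distances)),
        sd_mm=sd,
        q1_mm=float(q1),
        median_mm=float(med),
        q3_mm=float(q3),
        n_recognized=int(distances.size),
        n_truth=n_truth,
    )


def length_stats(predicted_mm, true_mm) -> LengthStats:
    """MAE, RMSE, mean relative error and Pearson correlation of paired
    predicted vs. reference lengths."""
    predicted = np.asarray(predicted_mm, dtype=float)
    true = np.asarray(true_mm, dtype=float)
    if predicted.shape != true.shape or predicted.ndim != 1:
        raise ValueError("length_stats requires paired 1-D arrays")
    if predicted.size == 0:
        raise ValueError("length_stats requires at least one pair")
    if np.any(true <= 0):
        raise ValueError("true lengths must be positive for the relative error")
    err = predicted - true
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    mre = float(np.mean(np.abs(err) / true))
    if predicted.size < 2 or np.std(predicted) == 0 or np.std(true) == 0:
        logger.info("PCC undefined for n<2 or constant inputs; reporting None")
        pcc = None
    else:
        pcc = float(np.corrcoef(predicted, true)[0, 1])
    return LengthStats(mae=mae, rmse=rmse, mre=mre, pcc=pcc, n=int(predicted.size))


def bland_altman(predicted_mm, true_mm, sample_sd: bool = True) -> AgreementStats:
    """Bland–Altman agreement: bias = mean(pred - true), 95% limits of
    agreement = bias +/- 1.96 SD of the differences."""
    predicted = np.asarray(predicted_mm, dtype=float)
    true = np.asarray(true_mm, dtype=float)
    if predicted.shape != true.shape or predicted.size < 2:
        raise ValueError("bland_altman requires at least 2 paired values")
    diff = predicted - true
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1 if sample_sd else 0))
    return AgreementStats(bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd, sd=sd)


def classification_stats(counts: ConfusionCounts) -> dict[str, float | None]:
    """Accuracy, recall, precision, specificity and F1 from confusion counts.

    Ratios with a zero denominator are reported as ``None`` (absent), never
    coerced to 0.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("all confusion counts are zero")

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    accuracy = (tp + tn) / total
    recall = ratio(tp, tp + fn)
    precision = ratio(tp, tp + fp)
    specificity = ratio(tn, tn + fp)
    if precision is None or recall is None or (precision + recall) == 0:
        f1 = None if (precision is None or recall is None) else 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {
        "accuracy": accuracy,
        "recall": recall,
        "precision": precision,
        "specificity": specificity,
        "f1": f1,
    }


def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC curve and trapezoidal AUC over all score thresholds.

    The trapezoidal integral equals the pairwise concordance probability
    with ties counted as 1/2.  Returns ``(points, auc)`` where ``points`` is
    an ``(n_thresholds, 2)`` array of (FPR, TPR) pairs.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must be paired")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both label classes")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # group tied scores so thresholds fall between distinct values
    distinct = np.r_[np.flatnonzero(np.diff(s)), s.size - 1]
    tps = np.cumsum(y)[distinct]
    fps = np.cumsum(~y)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return np.stack([fpr, tpr], axis=1), auc


def cohen_kappa(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two binary label vectors."""
    a = np.asarray(labels_a, dtype=bool)
    b = np.asarray(labels_b, dtype=bool)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("kappa requires two equal-length nonempty vectors")
    po = float(np.mean(a == b))
    pe = float(np.mean(a) * np.mean(b) + np.mean(~a) * np.mean(~b))
    if pe == 1.0:
        return 1.0
    return (po - pe) / (1 - pe)
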