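"""Classifier performance measures: confusion metrics, ROC, AUC and AUC50.

Threshold metrics follow the standard definitions: specificity =
TN/(TN+FP), sensitivity = TP/(TP+FN), accuracy = (TP+TN)/total and
false-positive rate = FP/(FP+TN); a pair is predicted positive when its
score is >= the threshold.  ROC curves are built by sweeping the
distinct observed scores; tied scores are collapsed into a single sweep
point, which makes the trapezoidal AUC equal to the rank statistic
(#concordant + half #tied) / (P*N).

AUC50 is the early-retrieval summary used for comparing rankers when
only the top of the list matters: the area under the ROC drawn against
the *absolute* false-positive count, integrated from 0 to 50 false
positives and normalized by 50*P so a perfect ranker scores 1.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .pairs import MISSING, is_missing

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "metrics",
    "roc_auc",
    "auc50",
    "precision_recall",
    "rank_correlation",
    "positives_ratio",
    "report",
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


@dataclass
class MetricsReport:
    """Threshold metrics plus threshold-free curves for one score set."""

    counts: ConfusionCounts | None = None
    accuracy: float = MISSING
    sensitivity: float = MISSING
    specificity: float = MISSING
    fpr: float = MISSING
    precision: float = MISSING
    auc: float = MISSING
    auc50: float = MISSING
    roc_curve: np.ndarray | None = None
    pr_curve: np.ndarray | None = None


def _clean(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape:
        raise ValueError("scores and labels must be aligned")
    mask = ~np.isnan(s)
    dropped = int((~mask).sum())
    if dropped:
        logger.warning("excluded %d pair(s) with MISSING scores", dropped)
    return s[mask], y[mask].astype(int)


def confusion(scores, labels, threshold: float) -> ConfusionCounts:
    """Tally the confusion matrix at a score threshold (predict iff >= t)."""
    s, y = _clean(scores, labels)
    pred = s >= threshold
    return ConfusionCounts(
        TP=int(np.sum(pred & (y == 1))),
        TN=int(np.sum(~pred & (y == 0))),
        FP=int(np.sum(pred & (y == 0))),
        FN=int(np.sum(~pred & (y == 1))),
    )


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else MISSING


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Threshold metrics from confusion counts; undefined ones are MISSING."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics on empty counts")
    return MetricsReport(
        counts=counts,
        accuracy=_safe_div(counts.TP + counts.TN, counts.total),
        sensitivity=_safe_div(counts.TP, counts.TP + counts.FN),
        specificity=_safe_div(counts.TN, counts.TN + counts.FP),
        fpr=_safe_div(counts.FP, counts.FP + counts.TN),
        precision=_safe_div(counts.TP, counts.TP + counts.FP),
    )


def _sweep(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative (FP, TP) counts at each distinct score, descending.

    Returns arrays starting at (0, 0); tied scores form one step.
    """
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = labels[order]
    tp = np.cumsum(y == 1)
    fp = np.cumsum(y == 0)
    distinct = np.nonzero(np.diff(s))[0]
    idx = np.r_[distinct, len(s) - 1]
    return np.r_[0, fp[idx]].astype(float), np.r_[0, tp[idx]].astype(float)


def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC curve (FPR, TPR columns) and trapezoidal AUC.

    Ties are averaged (diagonal segments), so the AUC equals the
    concordant-pair rank statistic.
    """
    s, y = _clean(scores, labels)
    P = int(np.sum(y == 1))
    N = int(np.sum(y == 0))
    if P == 0 or N == 0:
        raise ValueError("ROC requires both classes present")
    fp, tp = _sweep(s, y)
    curve = np.column_stack([fp / N, tp / P])
    auc = float(np.trapezoid(curve[:, 1], curve[:, 0]))
    return curve, auc


def auc50(scores, labels, max_fp: int = 50) -> float:
    """Partial ROC area up to ``max_fp`` false positives, normalized to [0, 1].

    With fewer than ``max_fp`` negatives, all negatives are used instead
    (flagged with a warning) and the normalization shrinks accordingly.
    """
    s, y = _clean(scores, labels)
    P = int(np.sum(y == 1))
    N = int(np.sum(y == 0))
    if P == 0 or N == 0:
        raise ValueError("AUC50 requires both classes present")
    cutoff = max_fp
    if N < max_fp:
        logger.warning("only %d negatives available; AUC50 cutoff reduced from %d", N, max_fp)
        cutoff = N
    fp, tp = _sweep(s, y)
    area = 0.0
    for i in range(1, len(fp)):
        f0, f1 = fp[i - 1], fp[i]
        t0, t1 = tp[i - 1], tp[i]
        if f0 >= cutoff:
            break
        if f1 > cutoff:  # linear interpolation of the tie segment at the cutoff
            t1 = t0 + (t1 - t0) * (cutoff - f0) / (f1 - f0)
            f1 = float(cutoff)
        area += (f1 - f0) * (t0 + t1) / 2.0
    if fp[-1] < cutoff:  # ranking exhausted before the cutoff: flat extension
        area += (cutoff - fp[-1]) * tp[-1]
    return area / (cutoff * P)


def precision_recall(scores, labels) -> np.ndarray:
    """Precision-recall curve (recall, precision columns), high scores first."""
    s, y = _clean(scores, labels)
    P = int(np.sum(y == 1))
    N = int(np.sum(y == 0))
    if P == 0 or N == 0:
        raise ValueError("precision-recall requires both classes present")
    fp, tp = _sweep(s, y)
    fp, tp = fp[1:], tp[1:]  # the (0,0) anchor has undefined precision
    recall = tp / P
    precision = tp / (tp + fp)
    return np.column_stack([recall, precision])


def rank_correlation(scores_a: Sequence[float], scores_b: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with midrank ties and a two-sided p-value.

    The p-value uses exact permutation enumeration for very small
    samples (n <= 8) and the t-approximation otherwise; constant input
    vectors are an error.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be aligned 1-d sequences")
    n = len(a)
    if n < 3:
        raise ValueError("rank correlation needs at least 3 observations")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    rho = float(np.corrcoef(ra, rb)[0, 1])
    if n <= 8:
        hits = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = np.corrcoef(ra, rb[list(perm)])[0, 1]
            hits += abs(r) >= abs(rho) - 1e-12
            total += 1
        p = hits / total
    else:
        t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
        p = min(p, 1.0)
    return rho, p


def positives_ratio(n_pos: int, n_neg: int) -> float:
    """Fraction of positives among all pairs of a test composition."""
    if n_pos + n_neg <= 0:
        raise ValueError("need at least one pair")
    return n_pos / (n_pos + n_neg)


def report(scores, labels, threshold: float = 0.5) -> MetricsReport:
    """Full battery: threshold metrics at ``threshold`` plus ROC/AUC/AUC50/PR."""
    rep = metrics(confusion(scores, labels, threshold))
    rep.roc_curve, rep.auc = roc_auc(scores, labels)
    rep.auc50 = auc50(scores, labels)
    rep.pr_curve = precision_recall(scores, labels)
    return rep
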