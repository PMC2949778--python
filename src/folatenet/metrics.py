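"""Classification performance metrics: confusion counts, sensitivity,
specificity, global accuracy (percentages) and the ROC AUC (Mann-Whitney
probability that a random case outscores a random control)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata


@dataclass
class MetricsRecord:
    """One classification experiment's performance.

    Percentages in [0, 100]; ``roc_auc`` a proportion in [0, 1]. A field is
    ``None`` when its denominator is empty (e.g. specificity with no true
    negatives in the evaluation set) — flagged as missing, not zero.
    """

    sensitivity: float | None
    specificity: float | None
    global_accuracy: float
    roc_auc: float | None
    confusion: tuple[int, int, int, int] | None  # (TP, FN, TN, FP)

    def as_row(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "global_accuracy": self.global_accuracy,
            "roc_auc": self.roc_auc,
        }


def confusion_counts(scores, labels, threshold: float = 0.5) -> tuple[int, int, int, int]:
    """(TP, FN, TN, FP) with the deterministic tie rule: score >= threshold
    classifies as positive."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary")
    pred = scores >= threshold
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & ~pos))
    fp = int(np.sum(pred & ~pos))
    return tp, fn, tn, fp


def metrics_from_confusion(tp: int, fn: int, tn: int, fp: int) -> MetricsRecord:
    total = tp + fn + tn + fp
    if total == 0:
        raise ValueError("empty confusion")
    sens = 100.0 * tp / (tp + fn) if (tp + fn) else None
    spec = 100.0 * tn / (tn + fp) if (tn + fp) else None
    acc = 100.0 * (tp + tn) / total
    return MetricsRecord(sens, spec, acc, None, (tp, fn, tn, fp))


def confusion_and_metrics(scores, labels, threshold: float = 0.5) -> MetricsRecord:
    """Threshold the scores and fill every metric, including the ROC AUC
    (computed from the raw scores, so it is threshold-free)."""
    tp, fn, tn, fp = confusion_counts(scores, labels, threshold)
    rec = metrics_from_confusion(tp, fn, tn, fp)
    labels = np.asarray(labels)
    if 0 < labels.sum() < labels.size:
        rec.roc_auc = roc_auc(scores, labels)
    return rec


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 * P(tie).

    Computed via midranks, which handles ties exactly.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC AUC needs both classes present")
    ranks = rankdata(scores)  # midranks
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))
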