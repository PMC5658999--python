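"""Classifier evaluation: confusion tables, sensitivity/specificity,
nonparametric (Mann-Whitney) AUC and the Youden-optimal cutoff.

The AUC is the probability that a randomly chosen positive outscores a
randomly chosen negative, ties counted half - the rank-statistic estimate
with no binormal smoothing.  Cutoffs are scanned over the observed score
values with ">= t" orientation (a higher score argues for the positive
class); ties in the Youden index break toward the smaller cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionTable",
    "ROCResult",
    "confusion",
    "sensitivity_specificity",
    "auc_mann_whitney",
    "roc_points",
    "youden_cutoff",
]


class SingleClassError(ValueError):
    """Both classes are required but only one is present."""


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ROCResult:
    auc: float
    optimal_cutoff: float
    sensitivity_at_cutoff: float
    specificity_at_cutoff: float
    reference_source: str = ""


def _labels(calls) -> np.ndarray:
    out = np.asarray([getattr(c, "label", c) for c in calls], dtype=int)
    if out.size and not np.isin(out, (0, 1)).all():
        raise ValueError("labels must be binary")
    return out


def confusion(predictions, reference) -> ConfusionTable:
    """Cross-tabulate binary predictions against binary reference labels."""
    pred, ref = _labels(predictions), _labels(reference)
    if pred.shape != ref.shape:
        raise ValueError("predictions and reference must have equal length")
    return ConfusionTable(
        tp=int(((pred == 1) & (ref == 1)).sum()),
        fp=int(((pred == 1) & (ref == 0)).sum()),
        tn=int(((pred == 0) & (ref == 0)).sum()),
        fn=int(((pred == 0) & (ref == 1)).sum()),
    )


def sensitivity_specificity(table: ConfusionTable) -> tuple[float, float]:
    """(tp/(tp+fn), tn/(tn+fp)); raises when either class is empty."""
    if table.tp + table.fn == 0 or table.tn + table.fp == 0:
        raise SingleClassError("sensitivity/specificity need both classes present")
    return (
        table.tp / (table.tp + table.fn),
        table.tn / (table.tn + table.fp),
    )


def auc_mann_whitney(scores, reference) -> float:
    """AUC = P(score_pos > score_neg) + 0.5 * P(tie) over all pairs.

    Computed via midranks (identical to the exhaustive pairwise count).
    """
    s = np.asarray(scores, dtype=float)
    y = _labels(reference)
    if s.shape != y.shape:
        raise ValueError("scores and reference must have equal length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise SingleClassError("AUC needs at least one positive and one negative")
    ranks = rankdata(s)
    rank_sum_pos = ranks[y == 1].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_points(scores, reference) -> np.ndarray:
    """(cutoff, sensitivity, specificity) rows for every observed cutoff."""
    s = np.asarray(scores, dtype=float)
    y = _labels(reference)
    n_pos, n_neg = (y == 1).sum(), (y == 0).sum()
    if n_pos == 0 or n_neg == 0:
        raise SingleClassError("ROC needs at least one positive and one negative")
    rows = []
    for t in np.unique(s):
        pred = s >= t
        rows.append(
            (t, (pred & (y == 1)).sum() / n_pos, (~pred & (y == 0)).sum() / n_neg)
        )
    return np.asarray(rows)


def youden_cutoff(scores, reference, reference_source: str = "") -> ROCResult:
    """Cutoff maximizing sensitivity + specificity - 1 over observed scores.

    Ties break toward the smaller cutoff.
    """
    pts = roc_points(scores, reference)
    j = pts[:, 1] + pts[:, 2] - 1.0
    best = int(np.argmax(j))  # argmax takes the first (= smallest cutoff) tie
    return ROCResult(
        auc=auc_mann_whitney(scores, reference),
        optimal_cutoff=float(pts[best, 0]),
        sensitivity_at_cutoff=float(pts[best, 1]),
        specificity_at_cutoff=float(pts[best, 2]),
        reference_source=reference_source,
    )
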