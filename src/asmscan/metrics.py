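"""Evaluation protocol: ROC/AUROC, Average Precision, Recall@FPR,
evidenced-set precision/recall/F1, and retention rates.

Recall at a fixed false-positive rate is read off the ROC curve by
linear interpolation on the FPR axis; when the target lands exactly on a
vertical segment of the curve (repeated FPR), the maximum TPR at that
FPR is used. Average precision is the step-function (non-interpolated)
retrieval definition. Precision of an empty hit set is defined as 0 so
threshold sweeps never divide by zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn import metrics as _skm


@dataclass(frozen=True)
class ScoredLabelSet:
    """Aligned scores and binary labels."""

    scores: list[float]
    labels: list[int]

    def __post_init__(self) -> None:
        if len(self.scores) != len(self.labels):
            raise ValueError("scores and labels must have equal length")
        if not set(self.labels) <= {0, 1}:
            raise ValueError("labels must be 0 or 1")

    def require_both_classes(self) -> None:
        if len(set(self.labels)) < 2:
            raise ValueError("need at least one positive and one negative")

    @classmethod
    def from_pos_neg(cls, pos_scores, neg_scores) -> "ScoredLabelSet":
        pos = list(map(float, pos_scores))
        neg = list(map(float, neg_scores))
        return cls(pos + neg, [1] * len(pos) + [0] * len(neg))


@dataclass(frozen=True)
class RocCurve:
    """ROC points (fpr, tpr), from (0,0) to (1,1), nondecreasing."""

    points: list[tuple[float, float]]

    def __post_init__(self) -> None:
        fprs = [p[0] for p in self.points]
        tprs = [p[1] for p in self.points]
        if self.points[0] != (0.0, 0.0) or self.points[-1] != (1.0, 1.0):
            raise ValueError("ROC curve must span (0,0) to (1,1)")
        if any(np.diff(fprs) < 0) or any(np.diff(tprs) < 0):
            raise ValueError("ROC curve must be nondecreasing")


def roc_curve(data: ScoredLabelSet) -> RocCurve:
    """Standard descending-threshold ROC sweep; tied scores collapse."""
    data.require_both_classes()
    fpr, tpr, _ = _skm.roc_curve(
        data.labels, data.scores, drop_intermediate=False
    )
    pts = [(float(f), float(t)) for f, t in zip(fpr, tpr)]
    if pts[0] != (0.0, 0.0):
        pts.insert(0, (0.0, 0.0))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    # drop consecutive duplicates
    dedup = [pts[0]]
    for p in pts[1:]:
        if p != dedup[-1]:
            dedup.append(p)
    return RocCurve(dedup)


def auroc(data: ScoredLabelSet) -> float:
    """Area under the ROC curve."""
    data.require_both_classes()
    return float(_skm.roc_auc_score(data.labels, data.scores))


def recall_at_fpr(curve: RocCurve, fpr_target: float) -> float:
    """TPR at a fixed FPR, linearly interpolated from the ROC curve."""
    if not 0.0 <= fpr_target <= 1.0:
        raise ValueError("fpr_target must be in [0, 1]")
    fprs = np.array([p[0] for p in curve.points])
    tprs = np.array([p[1] for p in curve.points])
    exact = fprs == fpr_target
    if exact.any():
        return float(tprs[exact].max())
    return float(np.interp(fpr_target, fprs, tprs))


def average_precision(data: ScoredLabelSet) -> float:
    """Step-function average precision of the descending-score sweep."""
    data.require_both_classes()
    return float(_skm.average_precision_score(data.labels, data.scores))


@dataclass(frozen=True)
class ThresholdPRF:
    """Threshold-level accounting against an evidenced motif set."""

    threshold: float | None
    n_hits: int
    n_true_hits: int
    n_evidenced: int
    precision: float
    recall: float
    f1: float

    @property
    def rounded(self) -> tuple[float, float, float]:
        """(recall, precision, f1) rounded to 2 decimals, table style."""
        return (round(self.recall, 2), round(self.precision, 2), round(self.f1, 2))


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean; 0 when both inputs are 0."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def prf_vs_evidenced(
    n_true_hits: int, n_hits: int, n_evidenced: int, threshold: float | None = None
) -> ThresholdPRF:
    """Precision/recall/F1 of a thresholded hit list against a fixed set
    of independently evidenced motifs.

    Recall is n_true_hits / n_evidenced; precision is n_true_hits /
    n_hits (0 for an empty hit list); F1 is computed from the unrounded
    values.
    """
    if n_evidenced < 1:
        raise ValueError("n_evidenced must be >= 1")
    if not 0 <= n_true_hits <= min(n_hits, n_evidenced):
        raise ValueError(
            f"inconsistent counts: true={n_true_hits}, hits={n_hits}, "
            f"evidenced={n_evidenced}"
        )
    recall = n_true_hits / n_evidenced
    precision = n_true_hits / n_hits if n_hits > 0 else 0.0
    return ThresholdPRF(
        threshold=threshold,
        n_hits=n_hits,
        n_true_hits=n_true_hits,
        n_evidenced=n_evidenced,
        precision=precision,
        recall=recall,
        f1=f1_score(precision, recall),
    )


def retention_rate(scores, threshold: float = 0.5) -> float:
    """Fraction of scores at or above the detection threshold."""
    scores = np.asarray(list(scores), dtype=float)
    if scores.size == 0:
        raise ValueError("retention_rate needs at least one score")
    return float(np.mean(scores >= threshold))
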