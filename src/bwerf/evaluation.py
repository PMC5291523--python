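"""Gold-standard evaluation: confusion counts, PR/ROC curves, trapezoidal areas.

Predictions are scored (regulator, target) pairs; the evaluation universe
defaults to all pool-TF x bottom-gene pairs, with unscored pairs ranked last
at score 0. Sweeping a threshold over the distinct scores (ties grouped at
one threshold) yields confusion counts

    precision = TP / (TP + FP),   recall = TPR = TP / P_total,
    FPR = FP / F_total,

and the curves' areas are computed by the composite trapezoidal rule.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import ValidationError

Pair = tuple[str, str]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("confusion counts must be nonnegative")

    @property
    def p_total(self) -> int:
        return self.tp + self.fn

    @property
    def f_total(self) -> int:
        return self.fp + self.tn


@dataclass
class EvaluationCurve:
    """Ordered curve points; ``kind`` is "PR" (recall, precision) or
    "ROC" (FPR, TPR)."""

    x: np.ndarray
    y: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.kind not in ("PR", "ROC"):
            raise ValidationError(f"unknown curve kind {self.kind!r}")
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValidationError("x and y must be 1-D and equal length")
        if self.kind == "ROC" and np.any(np.diff(self.x) < 0):
            raise ValidationError("ROC FPR values must be non-decreasing")

    @property
    def area(self) -> float:
        return trapz_area(self)


def _score_vector(
    scores: dict[Pair, float], gold: set[Pair], universe: set[Pair]
) -> tuple[np.ndarray, np.ndarray]:
    if not gold <= universe:
        raise ValidationError("gold pairs must be contained in the universe")
    extra = set(scores) - universe
    if extra:
        raise ValidationError(f"scored pairs outside the universe: {sorted(extra)[:5]}")
    pairs = sorted(universe)
    s = np.array([scores.get(p, 0.0) for p in pairs])
    labels = np.array([p in gold for p in pairs])
    return s, labels


def confusion_at_threshold(
    scores: dict[Pair, float],
    gold: set[Pair],
    universe: set[Pair],
    threshold: float,
) -> ConfusionCounts:
    """Counts with "predicted positive" = score >= threshold."""
    s, labels = _score_vector(scores, gold, universe)
    pred = s >= threshold
    tp = int(np.sum(pred & labels))
    fp = int(np.sum(pred & ~labels))
    fn = int(np.sum(~pred & labels))
    tn = int(np.sum(~pred & ~labels))
    return ConfusionCounts(tp, fp, fn, tn)


def _sweep(
    scores: dict[Pair, float], gold: set[Pair], universe: set[Pair]
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Cumulative (TP, FP) at each distinct descending threshold."""
    s, labels = _score_vector(scores, gold, universe)
    p_total = int(labels.sum())
    f_total = int((~labels).sum())
    if p_total == 0:
        raise ValidationError("gold standard contains no positive pairs")
    if f_total == 0:
        raise ValidationError("universe contains no negative pairs")
    order = np.argsort(-s, kind="stable")
    s, labels = s[order], labels[order]
    # last index of each tied-score group -> cumulative counts at ">= score"
    distinct = np.flatnonzero(np.diff(s) != 0)
    ends = np.append(distinct, s.size - 1)
    tp = np.cumsum(labels)[ends]
    fp = np.cumsum(~labels)[ends]
    return tp.astype(float), fp.astype(float), p_total, f_total


def roc_curve(
    scores: dict[Pair, float], gold: set[Pair], universe: set[Pair]
) -> EvaluationCurve:
    """ROC: TPR vs FPR, one point per distinct threshold plus the (0,0) anchor."""
    tp, fp, p_total, f_total = _sweep(scores, gold, universe)
    fpr = np.concatenate(([0.0], fp / f_total))
    tpr = np.concatenate(([0.0], tp / p_total))
    return EvaluationCurve(fpr, tpr, "ROC")


def pr_curve(
    scores: dict[Pair, float], gold: set[Pair], universe: set[Pair]
) -> EvaluationCurve:
    """PR: precision vs recall, anchored at recall 0 with the precision of
    the highest threshold; the final threshold reaches recall 1."""
    tp, fp, p_total, _ = _sweep(scores, gold, universe)
    recall = tp / p_total
    precision = tp / (tp + fp)
    recall = np.concatenate(([0.0], recall))
    precision = np.concatenate(([precision[0]], precision))
    return EvaluationCurve(recall, precision, "PR")


def trapz_area(curve: EvaluationCurve) -> float:
    """Composite trapezoidal rule over the stored points, x ascending."""
    if curve.x.size < 2:
        raise ValidationError("need at least 2 points to integrate")
    if np.any(np.diff(curve.x) < 0):
        raise ValidationError("x must be non-decreasing for integration")
    return float(np.trapezoid(curve.y, curve.x))


def auroc(scores: dict[Pair, float], gold: set[Pair], universe: set[Pair]) -> float:
    return trapz_area(roc_curve(scores, gold, universe))


def aupr(scores: dict[Pair, float], gold: set[Pair], universe: set[Pair]) -> float:
    return trapz_area(pr_curve(scores, gold, universe))
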