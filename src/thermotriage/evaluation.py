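"""Binary-classifier evaluation: the nine performance measures,
ROC/PR curves, and MCC-maximizing threshold selection.

Point metrics follow the usual confusion-matrix definitions, with the
convention that any metric whose denominator is zero is reported as 0
(degenerate predictors therefore get MCC = 0, not NaN). AUC is the
tie-aware Mann-Whitney probability P(S_pos > S_neg) + 0.5 P(S_pos =
S_neg); AUPR uses step-wise interpolation (precision held constant to
the right of each recall step), which avoids the optimistic bias of
trapezoidal PR areas.

Document scores here are small integers or rationals, so candidate
thresholds are exactly the observed distinct score values; under the
inclusive ``score >= TH`` decision rule this is equivalent to a
continuous sweep.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "EvalResult",
    "confusion_metrics",
    "confusion_from_predictions",
    "roc_curve_auc",
    "pr_curve_auc",
    "optimize_threshold",
    "evaluate_scores",
    "subsample_evaluate",
    "METRIC_ORDER",
]

METRIC_ORDER = ("q2", "tnr", "npv", "tpr", "ppv", "mcc", "f1", "auc", "aupr")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class EvalResult:
    """Point metrics plus (optionally) curves, areas and the threshold."""

    q2: float  # overall accuracy
    tnr: float
    npv: float
    tpr: float
    ppv: float
    mcc: float
    f1: float
    auc: Optional[float] = None
    aupr: Optional[float] = None
    roc_points: Optional[List[Tuple[float, float]]] = None
    pr_points: Optional[List[Tuple[float, float]]] = None
    threshold: Optional[float] = None
    counts: Optional[ConfusionCounts] = None

    def as_dict(self) -> Dict[str, Optional[float]]:
        return {k: getattr(self, k) for k in METRIC_ORDER}

    def to_row(self) -> str:
        """One TSV row in the canonical column order."""
        vals = []
        for k in METRIC_ORDER:
            v = getattr(self, k)
            vals.append("" if v is None else f"{v:.4f}")
        return "\t".join(vals)


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def confusion_metrics(c: ConfusionCounts) -> EvalResult:
    """The seven point metrics of a confusion table.

    Zero-denominator metrics (including MCC) are 0 by convention.
    """
    if c.total == 0:
        raise ValueError("empty confusion table")
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    q2 = (tp + tn) / c.total
    tpr = _safe_div(tp, tp + fn)
    tnr = _safe_div(tn, tn + fp)
    ppv = _safe_div(tp, tp + fp)
    npv = _safe_div(tn, tn + fn)
    f1 = _safe_div(2 * ppv * tpr, ppv + tpr)
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe_div(tp * tn - fp * fn, denom)
    return EvalResult(q2=q2, tnr=tnr, npv=npv, tpr=tpr, ppv=ppv,
                      mcc=mcc, f1=f1, counts=c)


def _to_bool_labels(labels: Sequence) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "UO":
        pos_alias = {"pos", "positive", "1", "true"}
        return np.array([str(x).lower() in pos_alias for x in arr])
    return arr.astype(bool)


def confusion_from_predictions(
    scores: Sequence[float], labels: Sequence, threshold: float
) -> ConfusionCounts:
    """Confusion table under the inclusive ``score >= threshold`` rule."""
    s = np.asarray(scores, dtype=float)
    y = _to_bool_labels(labels)
    pred = s >= threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & y)),
        fp=int(np.sum(pred & ~y)),
        tn=int(np.sum(~pred & ~y)),
        fn=int(np.sum(~pred & y)),
    )


def _check_both_classes(y: np.ndarray) -> None:
    if y.all() or not y.any():
        raise ValueError("both classes must be present")


def roc_curve_auc(
    scores: Sequence[float], labels: Sequence
) -> Tuple[List[Tuple[float, float]], float]:
    """ROC points (FPR, TPR) over distinct-score thresholds, and the AUC.

    The AUC is computed as the Mann-Whitney statistic through midranks,
    which handles tied scores exactly.
    """
    s = np.asarray(scores, dtype=float)
    y = _to_bool_labels(labels)
    _check_both_classes(y)
    n_pos, n_neg = int(y.sum()), int((~y).sum())

    points = [(0.0, 0.0)]
    for th in sorted(set(s), reverse=True):
        pred = s >= th
        tpr = np.sum(pred & y) / n_pos
        fpr = np.sum(pred & ~y) / n_neg
        points.append((float(fpr), float(tpr)))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))

    ranks = rankdata(s)  # midranks for ties
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return points, float(auc)


def pr_curve_auc(
    scores: Sequence[float], labels: Sequence
) -> Tuple[List[Tuple[float, float]], float]:
    """PR points (recall, precision) and the step-interpolated area."""
    s = np.asarray(scores, dtype=float)
    y = _to_bool_labels(labels)
    if not y.any():
        raise ValueError("at least one positive required")
    n_pos = int(y.sum())

    points: List[Tuple[float, float]] = []
    area = 0.0
    prev_recall = 0.0
    for th in sorted(set(s), reverse=True):
        pred = s >= th
        tp = int(np.sum(pred & y))
        fp = int(np.sum(pred & ~y))
        recall = tp / n_pos
        precision = _safe_div(tp, tp + fp)
        points.append((recall, precision))
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return points, area


def evaluate_scores(
    scores: Sequence[float], labels: Sequence, threshold: float
) -> EvalResult:
    """Full evaluation of a score vector at a fixed threshold."""
    res = confusion_metrics(confusion_from_predictions(scores, labels, threshold))
    y = _to_bool_labels(labels)
    if y.any() and not y.all():
        roc_points, auc = roc_curve_auc(scores, labels)
        pr_points, aupr = pr_curve_auc(scores, labels)
        res = replace(res, auc=auc, aupr=aupr,
                      roc_points=roc_points, pr_points=pr_points)
    res.threshold = threshold
    return res


def optimize_threshold(
    scores: Sequence[float], labels: Sequence
) -> Tuple[float, EvalResult]:
    """The observed-score threshold maximizing MCC (ties: smallest).

    Every distinct score value is evaluated as a candidate under the
    inclusive ``>=`` rule; the returned :class:`EvalResult` is the full
    evaluation at the winning threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = _to_bool_labels(labels)
    _check_both_classes(y)
    best_th, best_mcc = None, -np.inf
    for th in sorted(set(s)):
        mcc = confusion_metrics(
            confusion_from_predictions(s, y, th)
        ).mcc
        if mcc > best_mcc:
            best_th, best_mcc = th, mcc
    return float(best_th), evaluate_scores(s, y, float(best_th))


def subsample_evaluate(
    pos_scores: Sequence[float],
    neg_pool: Sequence[float],
    threshold: float,
    n_repeats: int = 10,
    seed: int = 0,
    n_neg: Optional[int] = None,
) -> Dict[str, Tuple[float, float, float]]:
    """Repeated-subsampling evaluation against a negative pool.

    Draws ``n_repeats`` random negative subsets of size ``n_neg``
    (default: as many as there are positives) from the pool, evaluates
    the fixed-threshold classifier on each balanced set, and reports
    per metric the (mean, min, max) across draws.
    """
    pos = np.asarray(pos_scores, dtype=float)
    pool = np.asarray(neg_pool, dtype=float)
    if n_neg is None:
        n_neg = len(pos)
    if n_neg > len(pool):
        raise ValueError("negative pool smaller than requested subset")
    rng = np.random.default_rng(seed)
    rows: List[EvalResult] = []
    for _ in range(n_repeats):
        neg = rng.choice(pool, size=n_neg, replace=False)
        scores = np.concatenate([pos, neg])
        labels = np.concatenate([np.ones(len(pos), bool), np.zeros(n_neg, bool)])
        rows.append(evaluate_scores(scores, labels, threshold))
    out: Dict[str, Tuple[float, float, float]] = {}
    for k in METRIC_ORDER:
        vals = [getattr(r, k) for r in rows if getattr(r, k) is not None]
        if vals:
            out[k] = (float(np.mean(vals)), float(np.min(vals)), float(np.max(vals)))
    return out
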