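"""Residue-level classifier evaluation: ROC/PR curves, AUCs, accuracy at
threshold, and cross-fold aggregation (mean, sample sd, min/max envelope)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as _skm

__all__ = ["EvalResult", "roc_pr", "fold_aggregate"]


@dataclass
class EvalResult:
    roc_points: np.ndarray  # (m, 2): (fpr, tpr)
    pr_points: np.ndarray  # (m, 2): (recall, precision)
    roc_auc: float
    pr_auc: float
    accuracy_at: dict[float, float] = field(default_factory=dict)
    counts: dict[float, tuple[int, int, int, int]] = field(default_factory=dict)
    # threshold -> (TP, FP, TN, FN)


def roc_pr(
    labels: np.ndarray,
    scores: np.ndarray,
    mask: np.ndarray | None = None,
    accuracy_thresholds: tuple[float, ...] = (0.5,),
) -> EvalResult:
    """Threshold-swept ROC and PR curves with trapezoidal AUCs.

    Equal scores are grouped at one threshold; requires both classes
    present after masking.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        labels, scores = labels[mask], scores[mask]
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0:
        raise ValueError("no positive examples after masking")
    if n_neg == 0:
        raise ValueError("no negative examples after masking")
    fpr, tpr, _ = _skm.roc_curve(labels, scores)
    precision, recall, _ = _skm.precision_recall_curve(labels, scores)
    roc_auc = float(_skm.auc(fpr, tpr))
    pr_auc = float(_skm.auc(recall[::-1], precision[::-1]))
    acc = {}
    counts = {}
    for t in accuracy_thresholds:
        pred = scores >= t
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        tn = int(np.sum(~pred & (labels == 0)))
        fn = int(np.sum(~pred & (labels == 1)))
        counts[float(t)] = (tp, fp, tn, fn)
        acc[float(t)] = (tp + tn) / labels.size
    return EvalResult(
        roc_points=np.column_stack([fpr, tpr]),
        pr_points=np.column_stack([recall[::-1], precision[::-1]]),
        roc_auc=roc_auc,
        pr_auc=pr_auc,
        accuracy_at=acc,
        counts=counts,
    )


def fold_aggregate(results: list[EvalResult], grid_size: int = 101) -> dict:
    """Mean +/- sample sd AUCs and pointwise min/max curve envelopes on a
    common FPR (ROC) / recall (PR) grid."""
    if len(results) < 2:
        raise ValueError("need at least 2 folds")
    grid = np.linspace(0.0, 1.0, grid_size)
    roc_curves = []
    pr_curves = []
    for r in results:
        roc_curves.append(np.interp(grid, r.roc_points[:, 0], r.roc_points[:, 1]))
        pr_curves.append(np.interp(grid, r.pr_points[:, 0], r.pr_points[:, 1]))
    roc_stack = np.vstack(roc_curves)
    pr_stack = np.vstack(pr_curves)
    roc_aucs = np.array([r.roc_auc for r in results])
    pr_aucs = np.array([r.pr_auc for r in results])
    return {
        "grid": grid,
        "roc_auc_mean": float(roc_aucs.mean()),
        "roc_auc_sd": float(roc_aucs.std(ddof=1)),  # sample sd convention
        "pr_auc_mean": float(pr_aucs.mean()),
        "pr_auc_sd": float(pr_aucs.std(ddof=1)),
        "roc_envelope": (roc_stack.min(axis=0), roc_stack.mean(axis=0), roc_stack.max(axis=0)),
        "pr_envelope": (pr_stack.min(axis=0), pr_stack.mean(axis=0), pr_stack.max(axis=0)),
    }
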