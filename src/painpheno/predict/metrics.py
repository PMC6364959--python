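"""Ranking metrics: pairwise-concordance AUC and ROC curves."""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata


def compute_auc(scores, labels) -> tuple[float, np.ndarray]:
    """AUC as the Mann-Whitney pair statistic plus a threshold-sweep ROC.

    AUC = P(score_pos > score_neg) + 0.5 * P(tie), computed from rank
    sums. The ROC is the usual staircase: one point per distinct score
    threshold (descending), anchored at (0, 0) and (1, 1). Returns
    (auc, roc) where roc is an (m, 2) array of (fpr, tpr) points.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).astype(int).ravel()
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: need both classes present")
    ranks = rankdata(scores)  # average ranks handle ties as half-wins
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    order = np.argsort(-scores, kind="mergesort")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    tp = np.cumsum(sorted_labels)
    fp = np.cumsum(1 - sorted_labels)
    # keep only the last index of each run of equal scores
    distinct = np.r_[np.diff(sorted_scores) != 0, True]
    tpr = tp[distinct] / n_pos
    fpr = fp[distinct] / n_neg
    roc = np.column_stack([np.r_[0.0, fpr], np.r_[0.0, tpr]])
    return float(auc), roc


def mean_roc(fold_rocs: list[np.ndarray], n_points: int = 101) -> np.ndarray:
    """Vertical averaging: mean TPR over folds at a fixed FPR grid."""
    grid = np.linspace(0.0, 1.0, n_points)
    if not fold_rocs:
        return np.column_stack([grid, np.full_like(grid, np.nan)])
    tprs = []
    for roc in fold_rocs:
        fpr, tpr = roc[:, 0], roc[:, 1]
        tprs.append(np.interp(grid, fpr, tpr))
    return np.column_stack([grid, np.mean(tprs, axis=0)])
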