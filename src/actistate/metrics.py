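"""Evaluation metrics for ordinal state classification.

Thin, validated fronts over scipy / scikit-learn: Pearson correlation of
predicted vs true ordinal state indices, quadratic-weighted Cohen kappa
(disagreement penalized by squared ordinal distance), and rank-based
ROC-AUC for the binary severe-vs-normal task.  Degenerate cases (zero
variance, a single class) surface as NaN or an error rather than a silent
zero.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import cohen_kappa_score, roc_auc_score

__all__ = ["pearson_ordinal", "quadratic_weighted_kappa", "roc_auc"]


def pearson_ordinal(pred_states: Sequence[int], true_states: Sequence[int]) -> float:
    """Product-moment correlation of state indices.

    Returns NaN (not 0) when either side has zero variance — a model that
    predicts one state all test set long has no defined correlation.
    """
    pred = np.asarray(pred_states, dtype=float)
    true = np.asarray(true_states, dtype=float)
    if pred.shape != true.shape:
        raise ValueError("prediction and truth lengths differ")
    if pred.size < 2:
        raise ValueError("need at least 2 pairs")
    if np.std(pred) == 0 or np.std(true) == 0:
        return math.nan
    return float(stats.pearsonr(pred, true).statistic)


def quadratic_weighted_kappa(
    pred_states: Sequence[int], true_states: Sequence[int], n_states: int
) -> float:
    """Cohen kappa with quadratic weights w_ij = (i-j)^2 / (S-1)^2 over the
    full state space 0..S-1 (absent states still shape the weights)."""
    if n_states < 2:
        raise ValueError("need at least 2 states")
    pred = np.asarray(pred_states, dtype=int)
    true = np.asarray(true_states, dtype=int)
    if pred.shape != true.shape:
        raise ValueError("prediction and truth lengths differ")
    return float(
        cohen_kappa_score(true, pred, weights="quadratic", labels=list(range(n_states)))
    )


def roc_auc(binary_labels: Sequence[bool], severe_scores: Sequence[float]) -> float:
    """Rank-based AUC: probability a random severe week outscores a random
    normal week, ties counting one half."""
    y = np.asarray(binary_labels, dtype=bool)
    s = np.asarray(severe_scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("label and score lengths differ")
    if y.all() or not y.any():
        raise ValueError("ROC-AUC requires both classes present")
    return float(roc_auc_score(y.astype(int), s))
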