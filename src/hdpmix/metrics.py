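"""Clustering and feature-recovery metrics.

The adjusted Rand index is chance-corrected pair-counting agreement between
two partitions: ARI = (Index - E[Index]) / (Max - E[Index]) with all three
quantities read off the label contingency table. Confusion matrices match
predicted clusters to true classes by Hungarian assignment because predicted
cluster indices are arbitrary.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import rankdata

from .datatypes import ValidationError


def _as_labels(a) -> np.ndarray:
    a = np.asarray(a)
    if a.ndim != 1:
        raise ValidationError("label vectors must be 1-D")
    return a


def contingency_table(a, b) -> np.ndarray:
    a, b = _as_labels(a), _as_labels(b)
    if len(a) != len(b):
        raise ValidationError("label vectors differ in length")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)
    return table


def adjusted_rand_index(a, b) -> float:
    """Chance-corrected pair-counting agreement; 1 for identical partitions,
    0 expected under random labelings, invariant to relabeling."""
    a, b = _as_labels(a), _as_labels(b)
    if len(a) != len(b):
        raise ValidationError("label vectors differ in length")
    if len(a) < 2:
        raise ValidationError("need at least 2 samples")
    t = contingency_table(a, b)
    comb2 = lambda x: x * (x - 1) / 2.0
    index = comb2(t).sum()
    row = comb2(t.sum(axis=1)).sum()
    col = comb2(t.sum(axis=0)).sum()
    total = comb2(len(a))
    expected = row * col / total
    max_index = 0.5 * (row + col)
    if max_index == expected:  # both partitions trivial
        return 1.0
    return float((index - expected) / (max_index - expected))


def confusion_matrix(truth, pred) -> tuple[np.ndarray, np.ndarray]:
    """Counts matrix (true x predicted) after Hungarian matching of predicted
    clusters to true classes, and the per-class accuracies diag/rowsum."""
    t = contingency_table(truth, pred)
    n_true, n_pred = t.shape
    size = max(n_true, n_pred)
    padded = np.zeros((size, size), dtype=np.int64)
    padded[:n_true, :n_pred] = t
    _, cols = linear_sum_assignment(-padded)
    matched = padded[:, cols][:n_true, :]
    acc = matched.diagonal()[:n_true] / np.maximum(matched.sum(axis=1), 1)
    return matched, acc


def phi_recovery_auc(scores, mask) -> float:
    """Rank-based area under the ROC of scores against a boolean mask."""
    scores = np.asarray(scores, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if scores.shape != mask.shape:
        raise ValidationError("scores and mask differ in length")
    n_pos = int(mask.sum())
    n_neg = int((~mask).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("mask must contain both classes")
    ranks = rankdata(scores)
    return float((ranks[mask].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))
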