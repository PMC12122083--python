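"""Per-feature importance scores and ranked core-set tables.

The selection posteriors Phi are per observation (sample x feature); a
feature's importance score is its selection probability averaged over
samples. Ranked tables list features by descending score so users can pick a
core set from the top.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import ValidationError


def average_phi(q_phi: np.ndarray) -> np.ndarray:
    """Column means of an N x D selection-probability matrix."""
    q_phi = np.asarray(q_phi, dtype=float)
    if q_phi.size == 0:
        raise ValidationError("empty selection-probability matrix")
    if np.any(q_phi < 0) or np.any(q_phi > 1):
        raise ValidationError("selection probabilities must lie in [0, 1]")
    return q_phi.mean(axis=0)


def rank_features(
    scores: np.ndarray, ids: Sequence[str], layer: str = "microbiome"
) -> pd.DataFrame:
    """Table of (rank, feature_id, score, layer), descending by score.

    The sort is stable: ties keep the original feature order.
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(ids):
        raise ValidationError("scores and identifiers differ in length")
    order = np.argsort(-scores, kind="stable")
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(scores) + 1),
            "feature_id": [ids[i] for i in order],
            "score": scores[order],
            "layer": layer,
        }
    )


def select_top(
    table: pd.DataFrame,
    n: Optional[int] = None,
    threshold: Optional[float] = None,
) -> pd.DataFrame:
    """Top-n rows, or all rows with score > threshold (exactly one mode)."""
    if (n is None) == (threshold is None):
        raise ValidationError("pass exactly one of n or threshold")
    if n is not None:
        if not (1 <= n <= len(table)):
            raise ValidationError(f"n must lie in [1, {len(table)}]")
        return table.iloc[:n].reset_index(drop=True)
    if not (0.0 <= threshold <= 1.0):
        raise ValidationError("threshold must lie in [0, 1]")
    return table[table["score"] > threshold].reset_index(drop=True)


def score_histogram(scores: np.ndarray, ax=None, bins: int = 40, bound=None):
    """Optional histogram of the score distribution with a user-supplied
    selection bound drawn as a dashed line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.hist(np.asarray(scores, dtype=float), bins=bins)
    if bound is not None:
        ax.axvline(bound, linestyle="--", color="k")
    ax.set_xlabel("average selection probability")
    ax.set_ylabel("features")
    return ax
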