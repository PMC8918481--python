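"""Ranking metrics for imbalanced binary classification."""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from .exceptions import UndefinedAUCError

__all__ = ["auc_score"]


def auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve of ``scores`` against binary ``labels``.

    Rank-based with midrank tie handling: equals U / (n_pos * n_neg)
    where U counts positive-over-negative score pairs with ties counting
    one half — the probability that a random minority sample outscores a
    random majority sample.  Computed from midranks (Mann-Whitney form),
    which is cheap enough for the many evaluations the GA fitness needs.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length vectors")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = scores.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError("AUC undefined on a single-class label vector")
    ranks = rankdata(scores, method="average")
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))
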