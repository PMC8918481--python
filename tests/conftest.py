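"""Shared fixtures and independent oracles.

The oracle functions are deliberately naive (nested loops, full sorts)
and never share code with the package implementation: they are the
reference the fast vectorized paths are checked against.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from imfuse import LabeledDataset, SyntheticSpec, generate_synthetic


# ---------------------------------------------------------------------------
# brute-force oracles


def brute_weighted_loss(L, X, w, pull_pairs, push_triplets, margin):
    """Triple-loop evaluation of the weighted large-margin loss."""
    L = np.asarray(L, dtype=float)
    total = 0.0
    for i, j in pull_pairs:
        diff = L @ (X[i] - X[j])
        total += w[i] * float(diff @ diff)
    for i, j, l in push_triplets:
        dij = L @ (X[i] - X[j])
        dil = L @ (X[i] - X[l])
        h = margin + float(dij @ dij) - float(dil @ dil)
        if h > 0:
            total += w[i] * h
    return total


def brute_pair_auc(scores, labels):
    """O(n^2) positive-over-negative pair count with ties counting 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def brute_sample_weight(X, y, i, k, h, eps=1e-12):
    """Straight-line re-implementation of the density weight of sample i."""
    d = [float(np.linalg.norm(X[i] - X[j])) for j in range(len(y))]
    maj = sorted(d[j] for j in range(len(y)) if y[j] == 0 and j != i)
    mino = sorted(d[j] for j in range(len(y)) if y[j] == 1 and j != i)
    delta_n = 1.0 / max(sum(maj[:k]) / k, eps)
    delta_p = 1.0 / max(sum(mino[:h]) / h, eps)
    own = [X[j] for j in range(len(y)) if y[j] == y[i]]
    center = sum(own) / len(own)
    d_center = max(float(np.linalg.norm(X[i] - center)), eps)
    return (delta_n + delta_p) / (len(own) * d_center)


def mean_anchor_margin(X, y, k_targets=3):
    """Average over anchors of (nearest different-class distance minus
    mean distance to the k nearest same-class neighbors)."""
    D = cdist(X, X)
    n = len(y)
    vals = []
    for i in range(n):
        same = np.flatnonzero((y == y[i]) & (np.arange(n) != i))
        other = np.flatnonzero(y != y[i])
        targets = np.sort(D[i, same])[:k_targets]
        vals.append(D[i, other].min() - targets.mean())
    return float(np.mean(vals))


def random_instance(rng, n_max=30, d_max=5):
    """A small random two-class dataset with guaranteed class sizes."""
    d = int(rng.integers(1, d_max + 1))
    n_min = int(rng.integers(3, 7))
    n_maj = int(rng.integers(n_min, max(n_min + 1, n_max - n_min)))
    X = rng.standard_normal((n_maj + n_min, d))
    y = np.concatenate([np.zeros(n_maj, dtype=int), np.ones(n_min, dtype=int)])
    return LabeledDataset(X, y)


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_dataset():
    """60 majority / 12 minority, 2 informative + 2 noise dims."""
    return generate_synthetic(SyntheticSpec(60, 12, 2, 2, 4.0, seed=5))


@pytest.fixture
def overlap_dataset():
    """Strongly overlapping classes for boundary-sensitive checks."""
    return generate_synthetic(SyntheticSpec(40, 15, 2, 1, 1.0, seed=9))
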