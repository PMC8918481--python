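"""SMOTE oversampling of the minority class.

A synthetic minority sample is a random convex combination of a minority
seed ``x_i`` and one of its ``k`` nearest minority neighbors ``x_n``:

    x* = x_i + (x_n - x_i) * r,   r ~ Uniform[0, 1].

Balancing appends exactly ``n_majority - n_minority`` such rows, cycling
through the minority samples in a shuffled order so that every minority
sample contributes a seed before any repeats.  Neighbor search runs in
the coordinates the data arrives in (in the full pipeline: the current
feature subspace of the transformed data).

An optional provenance log (seed index, neighbor index, interpolation
factor per synthetic row) makes every synthetic point auditable: each
must lie on the closed segment between its seed and neighbor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .datasets import LabeledDataset
from .exceptions import InsufficientSamplesError

__all__ = ["SmoteParams", "SmoteProvenance", "smote_synthesize", "smote_balance"]


@dataclass(frozen=True)
class SmoteParams:
    """``k_neighbors`` candidate minority neighbors per seed sample;
    clipped to minority size - 1 with a warning when too large."""

    k_neighbors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


@dataclass(frozen=True)
class SmoteProvenance:
    """Per-synthetic-row audit trail (indices into the OUTPUT dataset
    for the row, into the INPUT dataset for seed and neighbor)."""

    row_index: np.ndarray
    seed_index: np.ndarray
    neighbor_index: np.ndarray
    r: np.ndarray

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("row_index,seed_index,neighbor_index,r\n")
            for t in zip(self.row_index, self.seed_index, self.neighbor_index, self.r):
                fh.write(f"{t[0]},{t[1]},{t[2]},{t[3]:.17g}\n")


def smote_synthesize(x_i: np.ndarray, x_n: np.ndarray, r: float) -> np.ndarray:
    """Interpolate ``x_i + (x_n - x_i) * r`` with ``r`` in [0, 1]."""
    x_i = np.asarray(x_i, dtype=float)
    x_n = np.asarray(x_n, dtype=float)
    if x_i.shape != x_n.shape:
        raise ValueError("seed and neighbor must have equal length")
    if not (0.0 <= r <= 1.0):
        raise ValueError("interpolation factor r must lie in [0, 1]")
    return x_i + (x_n - x_i) * r


def smote_balance(dataset: LabeledDataset, params: SmoteParams = SmoteParams(),
                  return_provenance: bool = False):
    """Append synthetic minority rows until the classes are balanced.

    Original rows are preserved verbatim and come first; an already
    balanced dataset is returned unchanged.  Deterministic per seed.
    """
    dataset.require_both_classes()
    n_min, n_maj = dataset.n_minority, dataset.n_majority
    if n_min < 2:
        raise InsufficientSamplesError("SMOTE needs at least 2 minority samples")
    quota = n_maj - n_min
    if quota == 0:
        if return_provenance:
            empty = np.empty(0, dtype=np.int64)
            return dataset, SmoteProvenance(empty, empty, empty, np.empty(0))
        return dataset

    k = params.k_neighbors
    if k > n_min - 1:
        warnings.warn(
            f"k_neighbors={k} exceeds minority size - 1; clipping to {n_min - 1}",
            stacklevel=2,
        )
        k = n_min - 1

    rng = np.random.default_rng(params.seed)
    min_idx = np.flatnonzero(dataset.labels == 1)
    Xm = dataset.features[min_idx]
    D = cdist(Xm, Xm)
    np.fill_diagonal(D, np.inf)
    # k nearest minority neighbors per minority sample, ties by lower index
    neigh = np.argsort(D, axis=1, kind="stable")[:, :k]

    # every minority sample seeds once per cycle, in shuffled order
    seeds = np.concatenate([
        rng.permutation(n_min) for _ in range(int(np.ceil(quota / n_min)))
    ])[:quota]
    picks = rng.integers(0, k, size=quota)
    rs = rng.uniform(0.0, 1.0, size=quota)

    synth = np.empty((quota, dataset.d))
    for t in range(quota):
        s = seeds[t]
        nb = neigh[s, picks[t]]
        synth[t] = smote_synthesize(Xm[s], Xm[nb], rs[t])

    X_out = np.vstack([dataset.features, synth])
    y_out = np.concatenate([dataset.labels, np.ones(quota, dtype=np.int64)])
    out = LabeledDataset(X_out, y_out, feature_names=dataset.feature_names,
                         label_mapping=dataset.label_mapping)
    if return_provenance:
        prov = SmoteProvenance(
            row_index=np.arange(dataset.n, dataset.n + quota),
            seed_index=min_idx[seeds],
            neighbor_index=min_idx[neigh[seeds, picks]],
            r=rs,
        )
        return out, prov
    return out
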