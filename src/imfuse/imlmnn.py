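"""Imbalance-weighted large-margin metric learning (ImLMNN).

Large-margin nearest neighbor (LMNN) learns a linear map ``L`` so that
each anchor's same-class *target neighbors* are pulled close while
different-class *impostors* are pushed beyond a unit margin:

    f(L) = sum_{(i,j)} ||L(x_i - x_j)||^2
         + sum_{(i,j),l} [margin + ||L(x_i - x_j)||^2 - ||L(x_i - x_l)||^2]_+

with (i,j) ranging over anchor/target-neighbor pairs and l over
different-class samples.  Plain LMNN treats every anchor equally, which
is a poor fit for imbalanced data: the loss is dominated by the majority
class.  The imbalance-aware variant multiplies each anchor's pull and
push terms by a sample weight

    w_i = delta_i / (|N_c| * d(x_i, mean of x_i's class)),

where delta_i = delta_n + delta_p is a neighborhood density (inverse
mean distance to the k nearest majority-class and h nearest
minority-class neighbors).  The three factors implement three ideas:
class-size normalization (|N_c|) removes the majority's sheer-count
advantage; the density factor emphasizes samples near the decision
boundary (close to both classes); dividing by the distance to the
sample's own class center down-weights outliers.

The optimizer is plain gradient descent on ``L`` with per-iteration
step-halving, identity initialization and static triplets — simple,
monotone and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .datasets import LabeledDataset
from .exceptions import DivergenceError, InsufficientSamplesError

__all__ = [
    "DensityParams",
    "ImlmnnConfig",
    "LinearTransform",
    "TripletSet",
    "class_center",
    "sample_density",
    "sample_weights",
    "build_triplets",
    "imlmnn_loss",
    "imlmnn_gradient",
    "lmnn_loss",
    "fit_imlmnn",
    "fit_lmnn",
    "apply_transform",
    "save_transform",
    "load_transform",
]

EPSILON = 1e-12  # distance clamp guarding divisions


@dataclass(frozen=True)
class DensityParams:
    """Neighbor counts for the density factor: ``k`` nearest
    majority-class and ``h`` nearest minority-class neighbors."""

    k: int = 5
    h: int = 5
    epsilon: float = EPSILON

    def __post_init__(self) -> None:
        if self.k < 1 or self.h < 1:
            raise ValueError("k and h must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass(frozen=True)
class ImlmnnConfig:
    """Hyper-parameters of the metric learner.

    ``margin`` is the unit margin of the hinge; ``output_dim=None``
    keeps the full input dimension.  ``standardize`` rescales features
    to zero mean / unit variance (fitted on the training data only)
    before learning — margin-based metric learning is scale sensitive.
    """

    k_targets: int = 3
    density: DensityParams = field(default_factory=DensityParams)
    margin: float = 1.0
    max_iters: int = 200
    learning_rate: float = 1e-3
    min_rel_improvement: float = 1e-6
    output_dim: int | None = None
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.margin <= 0:
            raise ValueError("margin must be positive")
        if self.max_iters < 0:
            raise ValueError("max_iters must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass(frozen=True)
class LinearTransform:
    """A learned linear map ``x -> L x`` (r x d matrix), optionally
    preceded by the standardization fitted with it.

    ``loss_history`` records the accepted loss sequence of the fit that
    produced the transform (None for hand-built transforms).
    """

    matrix: np.ndarray
    mean: np.ndarray | None = None
    scale: np.ndarray | None = None
    loss_history: tuple[float, ...] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        L = np.asarray(self.matrix, dtype=float)
        if L.ndim != 2 or L.shape[0] < 1:
            raise ValueError("matrix must be r x d with r >= 1")
        if not np.all(np.isfinite(L)):
            raise ValueError("matrix contains non-finite entries")
        object.__setattr__(self, "matrix", L)

    @property
    def r(self) -> int:
        return self.matrix.shape[0]

    @property
    def d(self) -> int:
        return self.matrix.shape[1]

    def preprocess(self, X: np.ndarray) -> np.ndarray:
        if X.shape[1] != self.d:
            raise ValueError(f"expected {self.d} features, got {X.shape[1]}")
        if self.mean is not None:
            X = (X - self.mean) / self.scale
        return X

    def apply(self, X: np.ndarray) -> np.ndarray:
        return self.preprocess(np.asarray(X, dtype=float)) @ self.matrix.T


@dataclass(frozen=True)
class TripletSet:
    """Static pull pairs and push triplets.

    ``pull_pairs``: m x 2 int array of (anchor, target-neighbor);
    ``push_triplets``: p x 3 int array of (anchor, target, impostor).
    Target neighbors are fixed in the original input space.
    """

    pull_pairs: np.ndarray
    push_triplets: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "pull_pairs",
                           np.asarray(self.pull_pairs, dtype=np.int64).reshape(-1, 2))
        object.__setattr__(self, "push_triplets",
                           np.asarray(self.push_triplets, dtype=np.int64).reshape(-1, 3))


# ---------------------------------------------------------------------------
# sample weights


def class_center(dataset: LabeledDataset, c: int) -> np.ndarray:
    """Mean of the class-``c`` rows."""
    mask = dataset.labels == c
    if not mask.any():
        raise InsufficientSamplesError(f"class {c} is empty")
    return dataset.features[mask].mean(axis=0)


def _k_mean_distance(dists: np.ndarray, k: int, epsilon: float) -> float:
    """Mean of the k smallest entries, clamped below by epsilon."""
    if dists.size < k:
        raise InsufficientSamplesError(
            f"need {k} neighbors, only {dists.size} candidates"
        )
    smallest = np.partition(dists, k - 1)[:k]
    return max(float(smallest.mean()), epsilon)


def sample_density(i: int, dataset: LabeledDataset,
                   params: DensityParams = DensityParams()) -> tuple[float, float, float]:
    """Densities ``(delta_n, delta_p, delta)`` of sample ``i``.

    ``delta_n`` is the inverse mean Euclidean distance to the ``k``
    nearest majority-class neighbors (excluding ``i`` itself),
    ``delta_p`` likewise over the ``h`` nearest minority-class
    neighbors; ``delta = delta_n + delta_p``.
    """
    X, y = dataset.features, dataset.labels
    d_i = np.linalg.norm(X - X[i], axis=1)
    maj = np.flatnonzero((y == 0) & (np.arange(dataset.n) != i))
    mino = np.flatnonzero((y == 1) & (np.arange(dataset.n) != i))
    delta_n = 1.0 / _k_mean_distance(d_i[maj], params.k, params.epsilon)
    delta_p = 1.0 / _k_mean_distance(d_i[mino], params.h, params.epsilon)
    return delta_n, delta_p, delta_n + delta_p


def sample_weights(dataset: LabeledDataset,
                   params: DensityParams = DensityParams()) -> np.ndarray:
    """Per-sample weights ``w_i = delta_i / (|N_c| * d(x_i, center_c))``
    where ``c`` is sample i's own class.  All entries strictly positive."""
    dataset.require_both_classes()
    X, y = dataset.features, dataset.labels
    n = dataset.n
    sizes = {0: dataset.n_majority, 1: dataset.n_minority}
    centers = {c: class_center(dataset, c) for c in (0, 1)}
    D = cdist(X, X)
    w = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        maj = (y == 0) & (idx != i)
        mino = (y == 1) & (idx != i)
        delta_n = 1.0 / _k_mean_distance(D[i, maj], params.k, params.epsilon)
        delta_p = 1.0 / _k_mean_distance(D[i, mino], params.h, params.epsilon)
        d_center = max(float(np.linalg.norm(X[i] - centers[y[i]])), params.epsilon)
        w[i] = (delta_n + delta_p) / (sizes[int(y[i])] * d_center)
    return w


# ---------------------------------------------------------------------------
# triplets


def build_triplets(dataset: LabeledDataset, k_targets: int) -> TripletSet:
    """Each anchor paired with its ``k_targets`` nearest same-class
    neighbors (ties broken by lower index), crossed with every
    different-class sample as impostor."""
    dataset.require_both_classes()
    X, y = dataset.features, dataset.labels
    n = dataset.n
    for c, size in ((0, dataset.n_majority), (1, dataset.n_minority)):
        if size < k_targets + 1:
            raise InsufficientSamplesError(
                f"class {c} has {size} samples; needs >= {k_targets + 1} "
                f"for {k_targets} target neighbors"
            )
    D = cdist(X, X)
    pull = []
    for i in range(n):
        same = np.flatnonzero((y == y[i]) & (np.arange(n) != i))
        order = same[np.argsort(D[i, same], kind="stable")]
        for j in order[:k_targets]:
            pull.append((i, j))
    pull = np.asarray(pull, dtype=np.int64)
    push = []
    other_idx = {0: np.flatnonzero(y == 1), 1: np.flatnonzero(y == 0)}
    for i, j in pull:
        for l in other_idx[int(y[i])]:
            push.append((i, j, l))
    return TripletSet(pull, np.asarray(push, dtype=np.int64))


# ---------------------------------------------------------------------------
# loss / gradient


class _LossContext:
    """Cached difference vectors for fast repeated loss/gradient
    evaluation with a fixed dataset, weights and triplet set."""

    def __init__(self, X: np.ndarray, w: np.ndarray, triplets: TripletSet,
                 margin: float):
        if margin <= 0:
            raise ValueError("margin must be positive")
        w = np.asarray(w, dtype=float)
        if w.shape != (X.shape[0],):
            raise ValueError("weights must be a length-n vector")
        self.margin = float(margin)
        pull = triplets.pull_pairs
        push = triplets.push_triplets
        self.D_pull = X[pull[:, 0]] - X[pull[:, 1]]
        self.w_pull = w[pull[:, 0]]
        self.w_push = w[push[:, 0]]
        # unique (i,j) and (i,l) difference vectors referenced by pushes
        self.u_ij, self.ij_inv = np.unique(push[:, :2], axis=0, return_inverse=True) \
            if len(push) else (np.empty((0, 2), np.int64), np.empty(0, np.int64))
        self.u_il, self.il_inv = np.unique(push[:, [0, 2]], axis=0, return_inverse=True) \
            if len(push) else (np.empty((0, 2), np.int64), np.empty(0, np.int64))
        self.D_ij = X[self.u_ij[:, 0]] - X[self.u_ij[:, 1]]
        self.D_il = X[self.u_il[:, 0]] - X[self.u_il[:, 1]]

    @staticmethod
    def _sqnorm(D: np.ndarray, L: np.ndarray) -> np.ndarray:
        T = D @ L.T
        return np.einsum("ij,ij->i", T, T)

    def _hinge(self, L: np.ndarray) -> np.ndarray:
        dij = self._sqnorm(self.D_ij, L)
        dil = self._sqnorm(self.D_il, L)
        return self.margin + dij[self.ij_inv] - dil[self.il_inv]

    def loss(self, L: np.ndarray) -> float:
        pull = float(self.w_pull @ self._sqnorm(self.D_pull, L))
        if len(self.w_push) == 0:
            return pull
        h = self._hinge(L)
        return pull + float(self.w_push @ np.maximum(h, 0.0))

    def gradient(self, L: np.ndarray) -> np.ndarray:
        d = self.D_pull.shape[1] if len(self.D_pull) else self.D_il.shape[1]
        M = self.D_pull.T @ (self.w_pull[:, None] * self.D_pull) \
            if len(self.D_pull) else np.zeros((d, d))
        if len(self.w_push):
            active = self._hinge(L) > 0.0  # zero contribution at the kink
            wa = np.where(active, self.w_push, 0.0)
            c_ij = np.bincount(self.ij_inv, weights=wa, minlength=len(self.u_ij))
            c_il = np.bincount(self.il_inv, weights=wa, minlength=len(self.u_il))
            M = M + self.D_ij.T @ (c_ij[:, None] * self.D_ij)
            M = M - self.D_il.T @ (c_il[:, None] * self.D_il)
        return 2.0 * (L @ M)


def imlmnn_loss(L, dataset: LabeledDataset, w: np.ndarray,
                triplets: TripletSet, margin: float = 1.0) -> float:
    """Weighted large-margin loss at ``L`` (matrix or LinearTransform).

    The anchor's weight ``w_i`` multiplies both its pull and push terms.
    """
    Lm = L.matrix if isinstance(L, LinearTransform) else np.asarray(L, float)
    _check_dims(Lm, dataset)
    return _LossContext(dataset.features, w, triplets, margin).loss(Lm)


def imlmnn_gradient(L, dataset: LabeledDataset, w: np.ndarray,
                    triplets: TripletSet, margin: float = 1.0) -> np.ndarray:
    """Exact subgradient of :func:`imlmnn_loss` with respect to ``L``;
    triplets exactly at the hinge kink contribute zero."""
    Lm = L.matrix if isinstance(L, LinearTransform) else np.asarray(L, float)
    _check_dims(Lm, dataset)
    return _LossContext(dataset.features, w, triplets, margin).gradient(Lm)


def lmnn_loss(L, dataset: LabeledDataset, triplets: TripletSet,
              margin: float = 1.0) -> float:
    """Unweighted large-margin loss (all sample weights equal to 1)."""
    return imlmnn_loss(L, dataset, np.ones(dataset.n), triplets, margin)


def _check_dims(L: np.ndarray, dataset: LabeledDataset) -> None:
    if L.ndim != 2 or L.shape[1] != dataset.d:
        raise ValueError(
            f"transform shape {L.shape} incompatible with d={dataset.d}"
        )


# ---------------------------------------------------------------------------
# fitting


def fit_imlmnn(dataset: LabeledDataset,
               config: ImlmnnConfig = ImlmnnConfig()) -> LinearTransform:
    """Learn the imbalance-weighted transform by gradient descent.

    Weights and triplets are computed once in the (optionally
    standardized) input space; ``L`` starts at the identity truncated to
    ``output_dim`` rows.  Each iteration proposes ``L - lr * grad`` and
    halves the step (up to 20 times) whenever the loss would not
    decrease, so the accepted loss sequence is non-increasing.
    Deterministic for a fixed config.
    """
    return _fit(dataset, config, weighted=True)


def fit_lmnn(dataset: LabeledDataset,
             config: ImlmnnConfig = ImlmnnConfig()) -> LinearTransform:
    """Plain LMNN: identical optimization with unit sample weights."""
    return _fit(dataset, config, weighted=False)


def _fit(dataset: LabeledDataset, config: ImlmnnConfig,
         weighted: bool) -> LinearTransform:
    dataset.require_both_classes()
    X = dataset.features
    if config.standardize:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale < EPSILON, 1.0, scale)
        Z = (X - mean) / scale
    else:
        mean = scale = None
        Z = X
    zd = dataset.with_features(Z)

    r = config.output_dim if config.output_dim is not None else dataset.d
    if not (1 <= r <= dataset.d):
        raise ValueError("output_dim must lie in [1, d]")
    L = np.eye(r, dataset.d)

    if weighted:
        w = sample_weights(zd, config.density)
    else:
        w = np.ones(dataset.n)
    triplets = build_triplets(zd, config.k_targets)
    ctx = _LossContext(Z, w, triplets, config.margin)

    loss = ctx.loss(L)
    if not np.isfinite(loss):
        raise DivergenceError("non-finite loss at the initial transform")
    history = [loss]
    # The loss is not scale-anchored: a global shrinkage of L lowers the
    # pull term without changing which directions discriminate.  Fixing
    # the Frobenius norm of L at its identity-initialization value
    # (projected gradient descent on the sphere) removes that degenerate
    # mode, so descent must reallocate scale across directions instead
    # of shrinking everything.
    target_norm = np.linalg.norm(L)
    lr = config.learning_rate
    for _ in range(config.max_iters):
        grad = ctx.gradient(L)
        accepted = False
        for _half in range(21):
            cand = L - lr * grad
            norm = np.linalg.norm(cand)
            if norm > 0:
                cand = cand * (target_norm / norm)
            cand_loss = ctx.loss(cand)
            if np.isfinite(cand_loss) and cand_loss < loss:
                accepted = True
                break
            lr *= 0.5
        if not accepted:
            break
        rel = (loss - cand_loss) / max(loss, np.finfo(float).tiny)
        L, loss = cand, cand_loss
        history.append(loss)
        if rel < config.min_rel_improvement:
            break
    return LinearTransform(L, mean=mean, scale=scale,
                           loss_history=tuple(history))


def apply_transform(transform: LinearTransform,
                    dataset: LabeledDataset) -> LabeledDataset:
    """Map every row through the transform; labels unchanged."""
    Xt = transform.apply(dataset.features)
    names = [f"z{j}" for j in range(transform.r)]
    return dataset.with_features(Xt, names=names)


# ---------------------------------------------------------------------------
# serialization

_FMT = "{:.17g}"


def save_transform(transform: LinearTransform, path) -> None:
    """Write the transform as delimited text: a header line with r, d
    and a standardization flag, then mean/scale (if any) and the rows
    of L, all at 17 significant digits."""
    std = transform.mean is not None
    lines = [f"# imfuse-transform r={transform.r} d={transform.d} "
             f"standardize={int(std)}"]
    if std:
        lines.append(",".join(_FMT.format(v) for v in transform.mean))
        lines.append(",".join(_FMT.format(v) for v in transform.scale))
    for row in transform.matrix:
        lines.append(",".join(_FMT.format(v) for v in row))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def load_transform(path) -> LinearTransform:
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    header = lines[0]
    if not header.startswith("# imfuse-transform"):
        raise ValueError("not an imfuse transform file")
    fields = dict(tok.split("=") for tok in header.split()[2:])
    std = bool(int(fields["standardize"]))
    body = [np.array([float(t) for t in ln.split(",")]) for ln in lines[1:]]
    if std:
        mean, scale, rows = body[0], body[1], body[2:]
    else:
        mean = scale = None
        rows = body
    return LinearTransform(np.vstack(rows), mean=mean, scale=scale)
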