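"""Random feature-subspace ensemble over the transformed data.

The full pipeline is:

1. learn a linear transform on the training data (imbalance-weighted
   metric learning by default; plain LMNN or no transform as ablations);
2. draw N random feature subspaces of the transformed space (each a
   uniform M-subset of the columns, M = floor(feature_ratio * r));
3. per subspace: SMOTE-balance the projected training data and fit a
   fresh base classifier (default: linear max-margin classifier, C=1,
   signed distance to the hyperplane as score);
4. combine member scores by weighted voting — the weight vector lives on
   the simplex and is optimized by a genetic algorithm on an internal
   stratified validation split held out from both the metric learning
   and the member training.

Member scores are continuous decision values, not hard labels: both the
AUC evaluation and the GA fitness need a ranking.  The hard prediction
thresholds the combined score at 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.svm import LinearSVC

from .datasets import LabeledDataset
from .exceptions import InsufficientSamplesError
from .ga_weights import GAConfig, GAState, evolve
from .imlmnn import (
    ImlmnnConfig,
    LinearTransform,
    apply_transform,
    fit_imlmnn,
    fit_lmnn,
    load_transform,
    save_transform,
)
from .seeding import derive_seed
from .smote import SmoteParams, smote_balance

__all__ = [
    "SubspaceSpec",
    "LinearMaxMargin",
    "PipelineConfig",
    "EnsembleModel",
    "sample_subspaces",
    "train_ensemble",
    "member_scores",
    "weighted_vote",
    "predict",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class SubspaceSpec:
    """Strictly increasing, duplicate-free column indices into the
    transformed feature space."""

    feature_indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.feature_indices, dtype=np.int64)
        if idx.ndim != 1 or idx.size < 1:
            raise ValueError("feature_indices must be a non-empty vector")
        if not (np.diff(idx) > 0).all():
            raise ValueError("feature_indices must be strictly increasing")
        object.__setattr__(self, "feature_indices", idx)

    def project(self, X: np.ndarray) -> np.ndarray:
        return X[:, self.feature_indices]


class LinearMaxMargin:
    """Linear max-margin base classifier (soft-margin linear SVM,
    regularization constant C).  ``score`` returns the signed distance
    to the separating hyperplane, positive toward the minority class."""

    def __init__(self, C: float = 1.0, seed: int = 0):
        self.C = C
        self.seed = seed
        self.coef_: np.ndarray | None = None
        self.intercept_: float | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LinearMaxMargin":
        clf = LinearSVC(C=self.C, dual=False, max_iter=5000,
                        random_state=self.seed % (2**32))
        clf.fit(X, y)
        self.coef_ = clf.coef_.ravel().copy()
        self.intercept_ = float(clf.intercept_[0])
        return self

    def score(self, X: np.ndarray) -> np.ndarray:
        if self.coef_ is None:
            raise RuntimeError("classifier is not fitted")
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_


class LinearScorer:
    """A deserialized linear member: score(X) = X @ coef + intercept."""

    def __init__(self, coef: np.ndarray, intercept: float):
        self.coef_ = np.asarray(coef, dtype=float)
        self.intercept_ = float(intercept)

    def score(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to train the full ensemble from one seed.

    ``transform`` selects the data-transformation stage: ``"imlmnn"``
    (imbalance-weighted metric learning, default), ``"lmnn"`` (the
    unweighted ablation) or ``"none"`` (identity map; standardization is
    still applied when ``imlmnn.standardize`` is set, so the ablation
    isolates the metric learning itself).  ``validation_fraction`` is
    the share of the training partition held out for GA fitness; 0
    disables the GA and keeps uniform weights.
    """

    n_subspaces: int = 15
    feature_ratio: float = 0.7
    transform: str = "imlmnn"
    imlmnn: ImlmnnConfig = field(default_factory=ImlmnnConfig)
    smote_k: int = 5
    ga: GAConfig = field(default_factory=GAConfig)
    validation_fraction: float = 0.25
    base_C: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subspaces < 1:
            raise ValueError("n_subspaces must be >= 1")
        if not (0.0 < self.feature_ratio <= 1.0):
            raise ValueError("feature_ratio must lie in (0, 1]")
        if self.transform not in ("imlmnn", "lmnn", "none"):
            raise ValueError("transform must be 'imlmnn', 'lmnn' or 'none'")
        if not (0.0 <= self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must lie in [0, 1)")


@dataclass
class EnsembleModel:
    """Fitted pipeline: transform + N subspaces + N members + simplex
    voting weights."""

    transform: LinearTransform
    subspaces: list[SubspaceSpec]
    members: list
    weights: np.ndarray
    ga_state: GAState | None = None

    def __post_init__(self) -> None:
        if not (len(self.subspaces) == len(self.members) == len(self.weights)):
            raise ValueError("subspaces, members and weights must have equal length")
        _check_simplex(self.weights)


def _check_simplex(weights: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or (w < -tol).any() or abs(w.sum() - 1.0) > tol:
        raise ValueError("weights must be nonnegative and sum to 1")
    return w


def sample_subspaces(r: int, feature_ratio: float, N: int, seed: int) -> list[SubspaceSpec]:
    """Draw N uniform M-subsets of {0..r-1}, M = max(1, floor(ratio*r));
    subspaces are independent, so repeats across subspaces may occur."""
    if N < 1:
        raise ValueError("N must be >= 1")
    if not (0.0 < feature_ratio <= 1.0):
        raise ValueError("feature_ratio must lie in (0, 1]")
    M = max(1, int(np.floor(feature_ratio * r)))
    rng = np.random.default_rng(seed)
    return [SubspaceSpec(np.sort(rng.choice(r, size=M, replace=False)))
            for _ in range(N)]


def _fit_transform(train: LabeledDataset, config: PipelineConfig) -> LinearTransform:
    if config.transform == "imlmnn":
        return fit_imlmnn(train, config.imlmnn)
    if config.transform == "lmnn":
        return fit_lmnn(train, config.imlmnn)
    # identity map, optionally standardized like the learned transforms
    X = train.features
    if config.imlmnn.standardize:
        scale = X.std(axis=0)
        scale = np.where(scale < 1e-12, 1.0, scale)
        return LinearTransform(np.eye(train.d), mean=X.mean(axis=0), scale=scale)
    return LinearTransform(np.eye(train.d))


def _validation_split(train: LabeledDataset, fraction: float, seed: int):
    """Stratified fit/validation split; falls back to no split when the
    minority is too small to appear in both parts."""
    if fraction <= 0.0:
        return train, None
    n_val_min = int(np.floor(train.n_minority * fraction))
    if n_val_min < 1 or train.n_minority - n_val_min < 2:
        return train, None
    splitter = StratifiedShuffleSplit(n_splits=1, test_size=fraction,
                                      random_state=seed % (2**32))
    fit_idx, val_idx = next(splitter.split(train.features, train.labels))
    return train.subset(np.sort(fit_idx)), train.subset(np.sort(val_idx))


def train_ensemble(train: LabeledDataset,
                   config: PipelineConfig = PipelineConfig()) -> EnsembleModel:
    """Fit the full pipeline on the training partition only.

    All stage seeds derive from ``config.seed``, so two calls with the
    same configuration produce identical models.
    """
    train.require_both_classes()
    fit_part, val_part = _validation_split(
        train, config.validation_fraction, derive_seed(config.seed, "val-split")
    )

    transform = _fit_transform(fit_part, config)
    Xt = apply_transform(transform, fit_part)
    subspaces = sample_subspaces(transform.r, config.feature_ratio,
                                 config.n_subspaces,
                                 derive_seed(config.seed, "subspaces"))

    members = []
    for m, sub in enumerate(subspaces):
        projected = Xt.with_features(sub.project(Xt.features))
        try:
            balanced = smote_balance(
                projected,
                SmoteParams(k_neighbors=config.smote_k,
                            seed=derive_seed(config.seed, "smote", m)),
            )
        except InsufficientSamplesError as exc:
            raise InsufficientSamplesError(
                f"member {m}: {exc}"
            ) from exc
        clf = LinearMaxMargin(C=config.base_C,
                              seed=derive_seed(config.seed, "member", m))
        clf.fit(balanced.features, balanced.labels)
        members.append(clf)

    N = config.n_subspaces
    weights = np.full(N, 1.0 / N)
    ga_state = None
    if val_part is not None and N > 1:
        model0 = EnsembleModel(transform, subspaces, members, weights)
        val_scores = member_scores(model0, val_part)
        ga_cfg = replace(config.ga, seed=derive_seed(config.seed, "ga"))
        weights, ga_state = evolve(val_scores, val_part.labels, ga_cfg)
    return EnsembleModel(transform, subspaces, members, weights, ga_state)


def member_scores(model: EnsembleModel, data: LabeledDataset) -> np.ndarray:
    """n x N matrix: column j holds member j's decision scores on the
    transformed-and-projected data."""
    Xt = model.transform.apply(data.features)
    cols = [member.score(sub.project(Xt))
            for sub, member in zip(model.subspaces, model.members)]
    return np.column_stack(cols)


def weighted_vote(scores: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weights-weighted sum of member score columns (the fused
    continuous score; label 1 is predicted when it exceeds 0)."""
    scores = np.asarray(scores, dtype=float)
    w = _check_simplex(weights)
    if scores.ndim != 2 or scores.shape[1] != w.size:
        raise ValueError("scores must be n x N with N = len(weights)")
    return scores @ w


def predict(model: EnsembleModel, data: LabeledDataset) -> tuple[np.ndarray, np.ndarray]:
    """Fused scores and hard labels (score > 0 -> minority)."""
    fused = weighted_vote(member_scores(model, data), model.weights)
    return fused, (fused > 0).astype(np.int64)


# ---------------------------------------------------------------------------
# serialization

_FORMAT_VERSION = 1
_FMT = "{:.17g}"


def save_model(model: EnsembleModel, directory) -> None:
    """Write the model as a directory of delimited-text files plus a
    small JSON manifest."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    save_transform(model.transform, d / "transform.txt")
    with open(d / "subspaces.txt", "w", encoding="utf-8") as fh:
        for sub in model.subspaces:
            fh.write(",".join(map(str, sub.feature_indices)) + "\n")
    with open(d / "weights.txt", "w", encoding="utf-8") as fh:
        for w in model.weights:
            fh.write(_FMT.format(w) + "\n")
    mdir = d / "members"
    mdir.mkdir(exist_ok=True)
    for m, member in enumerate(model.members):
        with open(mdir / f"member_{m:03d}.txt", "w", encoding="utf-8") as fh:
            fh.write(",".join(_FMT.format(v) for v in member.coef_) + "\n")
            fh.write(_FMT.format(member.intercept_) + "\n")
    manifest = {
        "format_version": _FORMAT_VERSION,
        "n_members": len(model.members),
        "member_type": "linear",
        "r": model.transform.r,
        "d": model.transform.d,
    }
    with open(d / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_model(directory) -> EnsembleModel:
    d = Path(directory)
    with open(d / "manifest.json", encoding="utf-8") as fh:
        manifest = json.load(fh)
    if manifest["format_version"] != _FORMAT_VERSION:
        raise ValueError(f"unsupported model format {manifest['format_version']}")
    transform = load_transform(d / "transform.txt")
    with open(d / "subspaces.txt", encoding="utf-8") as fh:
        subspaces = [SubspaceSpec(np.array([int(t) for t in ln.split(",")]))
                     for ln in fh.read().splitlines() if ln.strip()]
    with open(d / "weights.txt", encoding="utf-8") as fh:
        weights = np.array([float(ln) for ln in fh.read().splitlines() if ln.strip()])
    members = []
    for m in range(manifest["n_members"]):
        with open(d / "members" / f"member_{m:03d}.txt", encoding="utf-8") as fh:
            lines = fh.read().splitlines()
        members.append(LinearScorer(
            np.array([float(t) for t in lines[0].split(",")]), float(lines[1])
        ))
    return EnsembleModel(transform, subspaces, members, weights)
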