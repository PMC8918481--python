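"""Dataset container, file readers/writers, stratified folds and the
synthetic imbalanced-data generator.

The universal carrier between pipeline stages is :class:`LabeledDataset`:
an ``n x d`` matrix of finite reals with binary labels.  By convention
label ``1`` is the MINORITY (positive) class — the class of interest in
imbalance learning and the positive class for AUC.  Readers enforce the
convention by mapping the rarer raw label to 1 unless told otherwise.

Two text dialects are supported:

* plain delimited text (header row, comma separated, ``.csv``);
* KEEL ``.dat`` files (``@relation`` / ``@attribute`` / ``@data``),
  restricted to numeric inputs and a binary nominal output, which covers
  the standard KEEL imbalance benchmarks.

The synthetic generator produces two Gaussian classes with a configurable
imbalance ratio, a configurable number of informative dimensions (class
means separated along the first axis) and pure-noise dimensions, so tests
can emulate benchmark regimes (imbalance ratios roughly 3-30, tens to low
thousands of samples) without downloading anything.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .exceptions import (
    DataFormatError,
    InsufficientSamplesError,
    ParseError,
    UnsupportedMulticlassError,
)

__all__ = [
    "LabeledDataset",
    "SyntheticSpec",
    "FoldAssignment",
    "read_delimited",
    "read_keel_dat",
    "write_delimited",
    "write_keel_dat",
    "generate_synthetic",
    "stratified_folds",
]

# 17 significant digits round-trips any IEEE double through text.
_FLOAT_FMT = "{:.17g}"


@dataclass(frozen=True)
class LabeledDataset:
    """An ``n x d`` feature matrix with binary labels.

    Label 1 denotes the minority (positive) class.  ``label_mapping``
    records how raw file labels were mapped, for reporting.
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str] | None = None
    label_mapping: dict | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        X = np.asarray(self.features, dtype=float)
        y = np.asarray(self.labels)
        if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
            raise ValueError(f"features must be n>=2 by d>=1, got shape {X.shape}")
        if not np.all(np.isfinite(X)):
            raise ValueError("features contain non-finite entries")
        if y.shape != (X.shape[0],):
            raise ValueError("labels must be a length-n vector")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("labels must take values in {0, 1}")
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "labels", y.astype(np.int64))
        if self.feature_names is not None and len(self.feature_names) != X.shape[1]:
            raise ValueError("feature_names length must equal d")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def d(self) -> int:
        return self.features.shape[1]

    @property
    def n_minority(self) -> int:
        return int(np.sum(self.labels == 1))

    @property
    def n_majority(self) -> int:
        return int(np.sum(self.labels == 0))

    def require_both_classes(self) -> None:
        if self.n_minority == 0 or self.n_majority == 0:
            raise InsufficientSamplesError(
                "both classes must be present for training"
            )

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        return replace(
            self, features=self.features[idx], labels=self.labels[idx]
        )

    def with_features(self, X: np.ndarray, names: list[str] | None = None) -> "LabeledDataset":
        return LabeledDataset(X, self.labels, feature_names=names,
                              label_mapping=self.label_mapping)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the Gaussian two-class generator.

    ``class_separation`` is the distance between the class means in the
    informative subspace, in units of the within-class standard
    deviation, so overlap is directly interpretable (0 = identical
    distributions, >= 4 = nearly separable).
    """

    n_majority: int
    n_minority: int
    d_informative: int = 2
    d_noise: int = 0
    class_separation: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.n_majority >= self.n_minority >= 2):
            raise ValueError("require n_majority >= n_minority >= 2")
        if self.d_informative < 1 or self.d_noise < 0:
            raise ValueError("require d_informative >= 1 and d_noise >= 0")
        if self.class_separation < 0:
            raise ValueError("class_separation must be nonnegative")

    @property
    def imbalance_ratio(self) -> float:
        return self.n_majority / self.n_minority


@dataclass(frozen=True)
class FoldAssignment:
    """Stratified K-fold assignment: ``fold_index[i]`` in ``[0, K)``."""

    fold_index: np.ndarray
    K: int

    def __post_init__(self) -> None:
        fi = np.asarray(self.fold_index, dtype=np.int64)
        if fi.ndim != 1 or not ((fi >= 0) & (fi < self.K)).all():
            raise ValueError("fold_index entries must lie in [0, K)")
        object.__setattr__(self, "fold_index", fi)

    def test_indices(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index == k)

    def train_indices(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index != k)


# ---------------------------------------------------------------------------
# readers / writers


def _map_labels(raw: pd.Series, positive_label) -> tuple[np.ndarray, dict]:
    values = raw.astype(str).str.strip()
    uniques = sorted(values.unique())
    if len(uniques) < 2:
        raise DataFormatError("label column is constant")
    if len(uniques) > 2:
        raise UnsupportedMulticlassError(
            f"expected 2 distinct labels, found {len(uniques)}: {uniques}"
        )
    if positive_label in (None, "auto"):
        counts = values.value_counts()
        # rarer raw label -> 1 (minority convention); ties broken by
        # sorted order so the mapping is deterministic
        if counts[uniques[0]] == counts[uniques[1]]:
            positive = uniques[1]
        else:
            positive = counts.idxmin()
    else:
        positive = str(positive_label).strip()
        if positive not in uniques:
            raise DataFormatError(
                f"positive_label {positive!r} not among labels {uniques}"
            )
    mapping = {u: int(u == positive) for u in uniques}
    return values.map(mapping).to_numpy(dtype=np.int64), mapping


def _numeric_features(df: pd.DataFrame) -> np.ndarray:
    X = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            # astype goes through the correctly-rounded strtod path, so
            # 17-significant-digit text round-trips bit-exactly
            values = df[col].astype(float).to_numpy()
        except (ValueError, TypeError):
            for i, cell in enumerate(df[col]):
                try:
                    float(cell)
                except (ValueError, TypeError):
                    raise ParseError(
                        f"non-numeric value in column {col!r}, "
                        f"row {i}: {cell!r}"
                    ) from None
            raise
        bad = np.flatnonzero(~np.isfinite(values))
        if bad.size:
            raise ParseError(
                f"non-finite value in column {col!r}, row {int(bad[0])}"
            )
        X[:, j] = values
    return X


def read_delimited(path, label_column=-1, positive_label="auto") -> LabeledDataset:
    """Read a comma-separated file with a header row.

    ``label_column`` may be a column name or an integer position
    (default: last column).  With ``positive_label='auto'`` the rarer
    raw label is mapped to 1.
    """
    # dtype=str defers numeric conversion to the correctly-rounded
    # astype path in _numeric_features (bit-exact text round-trips)
    df = pd.read_csv(path, skipinitialspace=True, dtype=str)
    if isinstance(label_column, int):
        label_name = df.columns[label_column]
    else:
        if label_column not in df.columns:
            raise DataFormatError(f"label column {label_column!r} not found")
        label_name = label_column
    y, mapping = _map_labels(df[label_name], positive_label)
    feats = df.drop(columns=[label_name])
    if feats.shape[1] == 0:
        raise DataFormatError("no feature columns")
    X = _numeric_features(feats)
    return LabeledDataset(X, y, feature_names=list(feats.columns),
                          label_mapping=mapping)


def read_keel_dat(path, positive_label="auto") -> LabeledDataset:
    """Read a KEEL ``.dat`` file (numeric inputs, binary nominal output)."""
    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            lines = fh.read().splitlines()

    attrs: list[tuple[str, bool]] = []  # (name, is_numeric)
    inputs: list[str] | None = None
    outputs: list[str] | None = None
    data_start = None
    for ln, line in enumerate(lines):
        s = line.strip()
        if not s:
            continue
        low = s.lower()
        if low.startswith("@relation"):
            continue
        if low.startswith("@attribute"):
            body = s[len("@attribute"):].strip()
            if "{" in body:
                name = body.split("{", 1)[0].strip().rstrip(",")
                attrs.append((name, False))
            else:
                name = body.split()[0].rstrip(",")
                attrs.append((name, True))
        elif low.startswith("@inputs"):
            inputs = [t.strip() for t in s.split(None, 1)[1].split(",")]
        elif low.startswith("@outputs"):
            outputs = [t.strip() for t in s.split(None, 1)[1].split(",")]
        elif low.startswith("@data"):
            data_start = ln + 1
            break
    if data_start is None:
        raise DataFormatError("missing @data section")
    if not attrs:
        raise DataFormatError("no @attribute declarations")

    names = [a[0] for a in attrs]
    if outputs is None:
        outputs = [names[-1]]
    if len(outputs) != 1:
        raise UnsupportedMulticlassError("exactly one output attribute required")
    out_name = outputs[0]
    if out_name not in names:
        raise DataFormatError(f"output attribute {out_name!r} not declared")
    if inputs is None:
        inputs = [n for n in names if n != out_name]
    for name in inputs:
        numeric = dict(attrs)[name]
        if not numeric:
            raise DataFormatError(
                f"nominal input attribute {name!r} is not supported"
            )

    rows = [ln.strip() for ln in lines[data_start:] if ln.strip()]
    if not rows:
        raise DataFormatError("empty @data section")
    df = pd.read_csv(
        io.StringIO("\n".join(rows)), header=None, names=names,
        skipinitialspace=True, dtype=str,
    )
    df = df.apply(lambda c: c.str.strip())
    y, mapping = _map_labels(df[out_name], positive_label)
    X = _numeric_features(df[inputs])
    return LabeledDataset(X, y, feature_names=list(inputs), label_mapping=mapping)


def _fmt(x: float) -> str:
    return _FLOAT_FMT.format(float(x))


def write_delimited(dataset: LabeledDataset, path) -> None:
    """Write the delimited dialect bit-stably (17 significant digits)."""
    names = dataset.feature_names or [f"f{j}" for j in range(dataset.d)]
    lines = [",".join([*names, "class"])]
    for i in range(dataset.n):
        cells = [_fmt(v) for v in dataset.features[i]]
        cells.append(str(int(dataset.labels[i])))
        lines.append(",".join(cells))
    _write_text(path, "\n".join(lines) + "\n")


def write_keel_dat(dataset: LabeledDataset, path, relation: str = "dataset") -> None:
    """Write the KEEL dialect; label 1 becomes ``positive``."""
    names = dataset.feature_names or [f"f{j}" for j in range(dataset.d)]
    lines = [f"@relation {relation}"]
    for j, name in enumerate(names):
        lo = _fmt(dataset.features[:, j].min())
        hi = _fmt(dataset.features[:, j].max())
        lines.append(f"@attribute {name} real [{lo}, {hi}]")
    lines.append("@attribute class {negative, positive}")
    lines.append("@inputs " + ", ".join(names))
    lines.append("@outputs class")
    lines.append("@data")
    for i in range(dataset.n):
        cells = [_fmt(v) for v in dataset.features[i]]
        cells.append("positive" if dataset.labels[i] == 1 else "negative")
        lines.append(",".join(cells))
    _write_text(path, "\n".join(lines) + "\n")


def _write_text(path, text: str) -> None:
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)


# ---------------------------------------------------------------------------
# synthetic generator and folds


def generate_synthetic(spec: SyntheticSpec) -> LabeledDataset:
    """Draw a two-class Gaussian dataset under ``spec``.

    Majority samples are isotropic unit-variance Gaussians at the origin
    of the informative subspace; minority samples sit at mean
    ``(class_separation, 0, ..., 0)``.  Noise dimensions are independent
    standard Gaussians for both classes.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_majority + spec.n_minority
    X_inf = rng.standard_normal((n, spec.d_informative))
    X_inf[spec.n_majority:, 0] += spec.class_separation
    if spec.d_noise:
        X = np.hstack([X_inf, rng.standard_normal((n, spec.d_noise))])
    else:
        X = X_inf
    y = np.concatenate(
        [np.zeros(spec.n_majority, dtype=np.int64),
         np.ones(spec.n_minority, dtype=np.int64)]
    )
    return LabeledDataset(X, y)


def stratified_folds(dataset: LabeledDataset, K: int, seed: int) -> FoldAssignment:
    """Stratified K-fold assignment, deterministic per seed."""
    dataset.require_both_classes()
    if min(dataset.n_minority, dataset.n_majority) < K:
        raise InsufficientSamplesError(
            f"each class needs >= {K} samples for {K}-fold stratification"
        )
    skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed % (2**32))
    fold_index = np.empty(dataset.n, dtype=np.int64)
    for k, (_, test) in enumerate(skf.split(dataset.features, dataset.labels)):
        fold_index[test] = k
    return FoldAssignment(fold_index, K)
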