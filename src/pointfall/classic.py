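"""Classical posture classifiers, implemented from their defining equations.

* K-nearest neighbours: Euclidean distance ranking with majority vote;
  distance ties resolve to the lower training index, vote ties to the
  smallest class code.
* Random forest: bagged axis-aligned decision trees whose splits maximize
  the reduction of the Shannon entropy ``H = -Σ p_i log2 p_i``; prediction
  is the modal vote over trees.
* Linear SVM: a maximum-margin separator for exactly two classes (by default
  standing vs falling), trained by deterministic hinge-loss subgradient
  descent and rescaled to canonical form, so on separable data every
  training point satisfies ``y_i (w·x_i + b) - 1 >= 0``.

These are deliberately dependency-free reference implementations; their
correctness is checked in the test suite against exhaustive-search and
closed-form oracles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import ParameterError, SchemaError

__all__ = [
    "LabeledPointSet",
    "entropy",
    "knn_classify",
    "knn_classify_batch",
    "DecisionTree",
    "DecisionForest",
    "forest_train",
    "forest_classify",
    "LinearSeparator",
    "svm_train",
    "svm_classify",
    "FeatureScaler",
]


@dataclass
class LabeledPointSet:
    """Feature vectors with posture labels (3D spot coordinates or the
    7-dim ellipsoid features)."""

    vectors: np.ndarray  # (n, d)
    labels: np.ndarray  # (n,) class codes

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.vectors.ndim != 2:
            raise SchemaError("vectors must be 2-dimensional (n, d)")
        if len(self.vectors) != len(self.labels):
            raise SchemaError("vectors and labels must have equal length")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


@dataclass
class FeatureScaler:
    """Per-feature z-scoring fitted on the training split."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "FeatureScaler":
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std = np.where(std < 1e-12, 1.0, std)
        return cls(mean=mean, std=std)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.std


# ---------------------------------------------------------------------------
# k-nearest neighbours


def _check_query(train: LabeledPointSet, query: np.ndarray) -> np.ndarray:
    q = np.atleast_2d(np.asarray(query, dtype=float))
    if q.shape[1] != train.dim:
        raise ParameterError(f"query dimension {q.shape[1]} != training dimension {train.dim}")
    return q


def knn_classify(train: LabeledPointSet, query: np.ndarray, k: int = 5) -> int:
    """Classify one query point by majority vote over its k nearest neighbours."""
    return int(knn_classify_batch(train, np.atleast_2d(query), k)[0])


def knn_classify_batch(train: LabeledPointSet, queries: np.ndarray, k: int = 5) -> np.ndarray:
    if k < 1 or k > train.n:
        raise ParameterError(f"k must be in [1, {train.n}], got {k}")
    Q = _check_query(train, queries)
    out = np.empty(len(Q), dtype=int)
    X, y = train.vectors, train.labels
    # chunked to bound the distance-matrix memory
    for s in range(0, len(Q), 1024):
        block = Q[s : s + 1024]
        d2 = ((block[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
        # stable sort => distance ties resolve to the lower training index
        nn = np.argsort(d2, axis=1, kind="stable")[:, :k]
        for r, row in enumerate(nn):
            votes = np.bincount(y[row])
            out[s + r] = int(np.argmax(votes))  # argmax -> smallest class code on ties
    return out


# ---------------------------------------------------------------------------
# entropy decision trees and the forest


def entropy(proportions: Sequence[float]) -> float:
    """Shannon entropy in bits of a class-frequency vector."""
    p = np.asarray(proportions, dtype=float)
    p = p[p > 0]
    if p.size == 0:
        return 0.0
    p = p / p.sum()
    return float(-(p * np.log2(p)).sum())


@dataclass
class _Node:
    feature: int = -1
    threshold: float = 0.0
    left: Optional["_Node"] = None
    right: Optional["_Node"] = None
    prediction: int = -1  # leaf class when feature < 0


@dataclass
class DecisionTree:
    root: _Node
    max_depth: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        out = np.empty(len(X), dtype=int)
        for i, x in enumerate(np.asarray(X, dtype=float)):
            node = self.root
            while node.feature >= 0:
                node = node.left if x[node.feature] <= node.threshold else node.right
            out[i] = node.prediction
        return out


def _class_counts(y: np.ndarray, n_classes: int) -> np.ndarray:
    return np.bincount(y, minlength=n_classes)


def _entropy_counts(counts: np.ndarray) -> np.ndarray:
    """Entropy (bits) for each row of a count matrix; vectorized."""
    totals = counts.sum(axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / np.where(totals == 0, 1, totals)
        terms = np.where(p > 0, -p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return terms.sum(axis=-1)


def _best_split(X: np.ndarray, y: np.ndarray, n_classes: int) -> Optional[tuple[int, float, float]]:
    """Greedy entropy-minimizing axis split; returns (feature, threshold, gain)."""
    n, d = X.shape
    counts = _class_counts(y, n_classes)
    h_parent = _entropy_counts(counts[None, :])[0]
    best: Optional[tuple[int, float, float]] = None
    onehot = np.eye(n_classes, dtype=float)[y]
    for j in range(d):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        prefix = np.cumsum(onehot[order], axis=0)  # (n, C) counts left of each cut
        cut = np.flatnonzero(np.diff(xs) > 0)  # split after position k
        if cut.size == 0:
            continue
        left = prefix[cut]
        right = counts[None, :] - left
        nl = left.sum(axis=1)
        nr = n - nl
        h = (nl * _entropy_counts(left) + nr * _entropy_counts(right)) / n
        gains = h_parent - h
        k = int(np.argmax(gains))
        if gains[k] > 1e-12 and (best is None or gains[k] > best[2] + 1e-15):
            threshold = 0.5 * (xs[cut[k]] + xs[cut[k] + 1])
            best = (j, float(threshold), float(gains[k]))
    return best


def _grow(X: np.ndarray, y: np.ndarray, depth: int, max_depth: int, n_classes: int) -> _Node:
    counts = _class_counts(y, n_classes)
    majority = int(np.argmax(counts))  # smallest class code on ties
    if depth >= max_depth or np.count_nonzero(counts) <= 1:
        return _Node(prediction=majority)
    split = _best_split(X, y, n_classes)
    if split is None:
        return _Node(prediction=majority)
    j, thr, _gain = split
    mask = X[:, j] <= thr
    return _Node(
        feature=j,
        threshold=thr,
        left=_grow(X[mask], y[mask], depth + 1, max_depth, n_classes),
        right=_grow(X[~mask], y[~mask], depth + 1, max_depth, n_classes),
    )


@dataclass
class DecisionForest:
    trees: list[DecisionTree]
    bootstrap_indices: list[np.ndarray]
    n_trees: int
    max_depth: int
    seed: int
    n_classes: int


def forest_train(
    train: LabeledPointSet,
    n_trees: int = 50,
    seed: int = 0,
    max_depth: int = 8,
    bootstrap_fraction: float = 0.7,
) -> DecisionForest:
    """Train a bagged ensemble of entropy decision trees.

    Each tree grows greedily on a bootstrap sample (with replacement,
    ``bootstrap_fraction`` of the training size); a single-class training
    set degrades to a constant classifier with a warning.
    """
    if n_trees < 1:
        raise ParameterError("n_trees must be >= 1")
    y = train.labels
    if len(np.unique(y)) < 2:
        warnings.warn("single-class training set: forest is a constant classifier", stacklevel=2)
    n_classes = int(y.max()) + 1
    rng = np.random.default_rng(seed)
    m = max(1, int(round(bootstrap_fraction * train.n)))
    trees, samples = [], []
    for _ in range(n_trees):
        idx = rng.integers(0, train.n, size=m)
        trees.append(
            DecisionTree(_grow(train.vectors[idx], y[idx], 0, max_depth, n_classes), max_depth)
        )
        samples.append(idx)
    return DecisionForest(trees, samples, n_trees, max_depth, seed, n_classes)


def forest_classify(forest: DecisionForest, queries: np.ndarray) -> np.ndarray:
    """Modal vote over all trees; ties resolve to the smallest class code."""
    Q = np.atleast_2d(np.asarray(queries, dtype=float))
    votes = np.stack([t.predict(Q) for t in forest.trees], axis=1)  # (n, n_trees)
    out = np.empty(len(Q), dtype=int)
    for i, row in enumerate(votes):
        out[i] = int(np.argmax(np.bincount(row, minlength=forest.n_classes)))
    return out


def forest_vote_fractions(forest: DecisionForest, queries: np.ndarray) -> np.ndarray:
    Q = np.atleast_2d(np.asarray(queries, dtype=float))
    votes = np.stack([t.predict(Q) for t in forest.trees], axis=1)
    frac = np.zeros((len(Q), forest.n_classes))
    for i, row in enumerate(votes):
        frac[i] = np.bincount(row, minlength=forest.n_classes) / forest.n_trees
    return frac


# ---------------------------------------------------------------------------
# linear SVM


@dataclass
class LinearSeparator:
    w: np.ndarray
    b: float
    classes: tuple[int, int]  # (positive class, negative class)

    def decision(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(X, dtype=float)) @ self.w + self.b


def svm_train(
    train: LabeledPointSet,
    classes: tuple[int, int] = (1, 3),
    C_reg: float = 10.0,
    n_iter: int = 2000,
) -> LinearSeparator:
    """Train a maximum-margin linear separator on exactly two classes.

    Deterministic full-batch subgradient descent on the regularized hinge
    loss ``λ/2 ||w||² + mean hinge`` with λ = 1/(C_reg·n) and step 1/(λ·t).
    After training, on separable data (w, b) are rescaled so the smallest
    functional margin is exactly 1, the canonical form in which the margin
    constraints read ``y_i (w·x_i + b) >= 1``.
    """
    if len(classes) != 2 or classes[0] == classes[1]:
        raise ParameterError(
            "svm_train separates exactly two classes; use knn or the forest for multiclass"
        )
    mask = np.isin(train.labels, classes)
    X = train.vectors[mask]
    y = np.where(train.labels[mask] == classes[0], 1.0, -1.0)
    if len(np.unique(y)) < 2:
        raise ParameterError(f"both classes {classes} must be present in the training set")
    n = len(y)
    lam = 1.0 / (C_reg * n)
    w = np.zeros(train.dim)
    b = 0.0
    for t in range(1, n_iter + 1):
        eta = 1.0 / (lam * t)
        margins = y * (X @ w + b)
        viol = margins < 1.0
        grad_w = lam * w - (y[viol, None] * X[viol]).sum(axis=0) / n
        grad_b = -(y[viol]).sum() / n
        w -= eta * grad_w
        b -= eta * grad_b
        norm = np.linalg.norm(np.append(w, b))
        radius = 1.0 / np.sqrt(lam)
        if norm > radius:  # Pegasos-style projection keeps the iterates bounded
            w *= radius / norm
            b *= radius / norm
    final = y * (X @ w + b)
    m_min = final.min()
    if m_min > 1e-9:  # separable: canonicalize the scale
        w, b = w / m_min, b / m_min
    return LinearSeparator(w=w, b=float(b), classes=(int(classes[0]), int(classes[1])))


def svm_classify(sep: LinearSeparator, queries: np.ndarray) -> np.ndarray:
    """Sign classification; points exactly on the plane take the positive class."""
    scores = sep.decision(queries)
    return np.where(scores >= 0.0, sep.classes[0], sep.classes[1])
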