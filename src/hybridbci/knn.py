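"""k-nearest-neighbor classification and k selection.

The classifier implements majority vote among the k nearest training rows
under one of four distances (Euclidean, city block, cosine, correlation).
Vote ties are broken by the class of the single nearest neighbor among the
tied classes, then by the smallest class index.  ``select_k`` chooses k by
systematic random subsampling: repeated stratified 80/20 splits of the
training set, highest mean inner-validation accuracy wins, ties to the
smallest k.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .datamodel import ValidationError

__all__ = [
    "euclidean_distance",
    "KNNClassifier",
    "knn_predict",
    "select_k",
    "baseline_classify",
    "DEFAULT_K_CANDIDATES",
]

METRICS = ("euclidean", "cosine", "cityblock", "correlation")
DEFAULT_K_CANDIDATES = (1, 3, 5, 7, 9, 11, 13, 15)


def euclidean_distance(g, h) -> float:
    """sqrt(sum (g_i - h_i)^2) between equal-length vectors."""
    g = np.asarray(g, dtype=float)
    h = np.asarray(h, dtype=float)
    if g.shape != h.shape:
        raise ValidationError("vectors have mismatched lengths")
    return float(np.sqrt(np.sum((g - h) ** 2)))


def _vote(neighbor_labels: np.ndarray) -> np.ndarray:
    """Majority vote over rows of (n_queries, k) labels ordered by distance.

    Ties: class of the earliest-ranked neighbor among the tied classes, then
    smallest class label.  (The earliest-ranked rule already resolves every
    tie to a single class; picking the first occurrence of the sole majority
    class reduces to that class, so one vectorized rule covers both cases.)
    """
    nl = np.asarray(neighbor_labels)
    n, _ = nl.shape
    classes = np.unique(nl)
    counts = (nl[:, :, None] == classes[None, None, :]).sum(axis=1)
    tied = counts == counts.max(axis=1, keepdims=True)       # (n, n_classes)
    elem_tied = tied[np.arange(n)[:, None], np.searchsorted(classes, nl)]
    first = elem_tied.argmax(axis=1)        # earliest rank among tied classes
    return nl[np.arange(n), first].astype(int)


class KNNClassifier(ClassifierMixin, BaseEstimator):
    """k-NN with the four distance metrics used in the evaluation."""

    def __init__(self, n_neighbors: int = 1, metric: str = "euclidean"):
        self.n_neighbors = n_neighbors
        self.metric = metric

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) == 0:
            raise ValidationError("training matrix must be 2-D and non-empty")
        if len(X) != len(y):
            raise ValidationError("X and y length mismatch")
        if self.metric not in METRICS:
            raise ValidationError(f"unknown metric {self.metric!r}")
        if not 1 <= self.n_neighbors <= len(X):
            raise ValidationError("need 1 <= n_neighbors <= n train rows")
        self.X_ = X
        self.y_ = y
        self.classes_ = np.unique(y)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.X_.shape[1]:
            raise ValidationError("feature count differs from training data")
        D = cdist(X, self.X_, metric=self.metric)
        order = np.argsort(D, axis=1, kind="stable")[:, : self.n_neighbors]
        return _vote(self.y_[order])


def knn_predict(train_X, train_y, test_X, k: int, distance: str = "euclidean"):
    """Functional wrapper over :class:`KNNClassifier`."""
    return KNNClassifier(n_neighbors=k, metric=distance).fit(train_X, train_y).predict(test_X)


def _stratified_indices(y: np.ndarray, train_fraction: float,
                        rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-class shuffled split guaranteeing both sides see every class."""
    tr, va = [], []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        if len(idx) < 2:
            raise ValidationError(f"class {c} has fewer than 2 rows")
        idx = rng.permutation(idx)
        n_tr = int(round(train_fraction * len(idx)))
        n_tr = min(max(n_tr, 1), len(idx) - 1)
        tr.append(idx[:n_tr])
        va.append(idx[n_tr:])
    return np.concatenate(tr), np.concatenate(va)


def select_k(
    X,
    y,
    candidate_ks=DEFAULT_K_CANDIDATES,
    n_subsamples: int = 20,
    inner_train_fraction: float = 0.8,
    metric: str = "euclidean",
    seed: int = 0,
) -> int:
    """Pick k by repeated stratified subsampling of the training set.

    All candidates are scored from a single neighbor ordering per subsample,
    so every k sees exactly the same splits.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    ks = sorted(set(int(k) for k in candidate_ks))
    if not ks or ks[0] < 1:
        raise ValidationError("candidate ks must be >= 1")
    if ks[-1] >= len(X):
        raise ValidationError("largest candidate k must be < number of rows")
    rng = np.random.default_rng(seed)
    scores = np.zeros((n_subsamples, len(ks)))
    for s in range(n_subsamples):
        tr, va = _stratified_indices(y, inner_train_fraction, rng)
        if ks[-1] > len(tr):
            raise ValidationError("largest candidate k exceeds inner-train size")
        D = cdist(X[va], X[tr], metric=metric)
        order = np.argsort(D, axis=1, kind="stable")
        ordered = y[tr][order]
        for j, k in enumerate(ks):
            scores[s, j] = np.mean(_vote(ordered[:, :k]) == y[va])
    mean_scores = scores.mean(axis=0)
    return ks[int(np.argmax(mean_scores))]  # argmax -> first max -> smallest k


def baseline_classify(train_X, train_y, test_X, algorithm: str, seed: int = 0):
    """SVM/decision-tree/random-forest baselines (fixed hyperparameters).

    Exists to compare the comparison's shape against k-NN, delegating to
    scikit-learn: RBF-kernel SVC (C=1), CART, 100-tree random forest.
    """
    alg = algorithm.lower()
    train_y = np.asarray(train_y)
    classes = np.unique(train_y)
    if alg in ("svm", "dt", "rf") and len(classes) == 1:
        return np.full(len(np.asarray(test_X)), classes[0])
    if alg == "svm":
        clf = SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed)
    elif alg == "dt":
        clf = DecisionTreeClassifier(random_state=seed)
    elif alg == "rf":
        clf = RandomForestClassifier(n_estimators=100, random_state=seed)
    else:
        raise ValidationError(f"unknown baseline algorithm {algorithm!r}")
    return clf.fit(np.asarray(train_X, float), np.asarray(train_y)).predict(
        np.asarray(test_X, float)
    )
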