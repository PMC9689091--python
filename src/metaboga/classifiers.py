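"""The three fitness classifiers and cross-validated average accuracy.

All three methods are distance-based on Euclidean geometry:

* KNN -- majority vote among the k nearest training samples;
* nearest centroid -- assign the class whose training mean is closest;
* SVM with a radial basis kernel K(x, x') = exp(-||x - x'||^2 / (2 sigma^2)).

Average accuracy -- the mean held-out accuracy over repeated stratified
k-fold cross-validation -- is the single figure of merit used throughout,
both as the genetic algorithm's fitness and for the final models.  Features
are z-scored inside each fold using training-fold statistics only, so no
information leaks from held-out samples into the scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist
from sklearn.model_selection import RepeatedStratifiedKFold, KFold
from sklearn.svm import SVC

from .datasets import ConfigurationError

try:  # low-level libsvm binding: same solver as SVC, far less call overhead
    from sklearn.svm import _libsvm

    _libsvm.set_verbosity_wrap(0)
except ImportError:  # pragma: no cover
    _libsvm = None

__all__ = [
    "ClassifierSpec",
    "CVScheme",
    "knn_predict",
    "nearcent_fit_predict",
    "svm_fit_predict",
    "rbf_kernel_value",
    "median_heuristic_sigma",
    "make_folds",
    "cv_average_accuracy",
    "cv_accuracy_given_folds",
    "FoldEvaluator",
]

METHODS = ("knn", "nearcent", "svm")


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier serves as the fitness function, and its settings.

    k is the KNN neighbour count (odd, to avoid voting ties in binary
    problems); sigma the RBF width (``None`` = median heuristic on the
    pairwise training distances); cost the SVM margin penalty.
    """

    method: str = "knn"
    k: int = 3
    sigma: float | None = None
    cost: float = 1.0

    def validate(self) -> None:
        if self.method not in METHODS:
            raise ConfigurationError(f"unknown method {self.method!r}")
        if self.k < 1 or self.k % 2 == 0:
            raise ConfigurationError("k must be odd and >= 1")
        if self.sigma is not None and self.sigma <= 0:
            raise ConfigurationError("sigma must be > 0")
        if self.cost <= 0:
            raise ConfigurationError("cost must be > 0")


@dataclass(frozen=True)
class CVScheme:
    """Repeated (stratified) k-fold cross-validation settings."""

    n_splits: int = 5
    n_repeats: int = 4
    stratified: bool = True
    seed: int = 0

    def validate(self, y: np.ndarray) -> None:
        if self.n_splits < 2:
            raise ConfigurationError("n_splits must be >= 2")
        _, counts = np.unique(y, return_counts=True)
        if self.n_splits > counts.min():
            raise ConfigurationError(
                f"n_splits={self.n_splits} exceeds the smallest class size "
                f"({counts.min()})"
            )


# -- individual classifiers ------------------------------------------------

def _check_dims(train_X: np.ndarray, test_X: np.ndarray) -> None:
    if train_X.shape[1] != test_X.shape[1]:
        raise ValueError(
            f"dimension mismatch: train has {train_X.shape[1]} features, "
            f"test has {test_X.shape[1]}"
        )


def knn_predict(train_X, train_y, test_X, k: int = 3) -> np.ndarray:
    """k-nearest-neighbour labels under Euclidean distance.

    Voting ties (possible with even k) are broken in favour of the label
    whose voters are nearer in summed distance, then by the
    lexicographically smaller label, so predictions are deterministic.
    """
    train_X = np.asarray(train_X, dtype=float)
    test_X = np.atleast_2d(np.asarray(test_X, dtype=float))
    train_y = np.asarray(train_y)
    _check_dims(train_X, test_X)
    if not 1 <= k <= len(train_X):
        raise ValueError(f"k={k} outside [1, {len(train_X)}]")

    dist = cdist(test_X, train_X)
    # stable sort: equidistant neighbours resolved by training index
    nearest = np.argsort(dist, axis=1, kind="stable")[:, :k]
    classes, codes = np.unique(train_y, return_inverse=True)
    neigh_codes = codes[nearest]  # (n_test, k)
    votes = np.stack([(neigh_codes == c).sum(axis=1) for c in range(len(classes))],
                     axis=1)
    winner = votes.argmax(axis=1)
    tied = (votes == votes.max(axis=1, keepdims=True)).sum(axis=1) > 1
    for i in np.flatnonzero(tied):
        idx = nearest[i]
        top = np.flatnonzero(votes[i] == votes[i].max())
        sums = {c: dist[i, idx[neigh_codes[i] == c]].sum() for c in top}
        # nearer summed distance wins; iterating labels in sorted order
        # breaks remaining ties toward the smaller label
        winner[i] = min(sorted(top, key=lambda c: str(classes[c])),
                        key=lambda c: sums[c])
    return classes[winner]


def nearcent_fit_predict(train_X, train_y, test_X) -> np.ndarray:
    """Nearest-centroid labels: per-class training means, Euclidean argmin."""
    train_X = np.asarray(train_X, dtype=float)
    test_X = np.atleast_2d(np.asarray(test_X, dtype=float))
    train_y = np.asarray(train_y)
    _check_dims(train_X, test_X)
    classes = np.unique(train_y)
    if any((train_y == c).sum() == 0 for c in classes) or len(classes) == 0:
        raise ValueError("every class needs at least one training sample")
    centroids = np.stack([train_X[train_y == c].mean(axis=0) for c in classes])
    d = cdist(test_X, centroids)
    return classes[np.argmin(d, axis=1)]


def rbf_kernel_value(x, x_prime, sigma: float) -> float:
    """K(x, x') = exp(-||x - x'||^2 / (2 sigma^2))."""
    diff = np.asarray(x, dtype=float) - np.asarray(x_prime, dtype=float)
    return float(np.exp(-np.dot(diff, diff) / (2.0 * sigma**2)))


def median_heuristic_sigma(train_X: np.ndarray) -> float:
    """Median of the non-zero pairwise Euclidean training distances."""
    d = pdist(train_X)
    vals = d[d > 0]
    if len(vals) == 0:
        return 1.0
    return float(np.median(vals))


def _svm_codes(train_X, code_y, test_X, gamma: float, cost: float) -> np.ndarray:
    """RBF C-SVC via libsvm; ``code_y`` must be integer class codes."""
    if _libsvm is not None:
        Xtr = np.ascontiguousarray(train_X, dtype=np.float64)
        Xte = np.ascontiguousarray(test_X, dtype=np.float64)
        model = _libsvm.fit(
            Xtr, code_y.astype(np.float64), svm_type=0, kernel="rbf",
            C=cost, gamma=gamma,
        )
        pred = _libsvm.predict(
            Xte, *model[:7], svm_type=0, kernel="rbf", gamma=gamma
        )
        return pred.astype(int)
    clf = SVC(C=cost, kernel="rbf", gamma=gamma)  # pragma: no cover
    clf.fit(train_X, code_y)
    return clf.predict(test_X)


def svm_fit_predict(train_X, train_y, test_X, spec: ClassifierSpec | None = None) -> np.ndarray:
    """Soft-margin SVM with the radial basis kernel.

    sigma defaults to the median heuristic on the training distances; the
    kernel width is passed to the underlying solver as
    gamma = 1 / (2 sigma^2).
    """
    spec = spec or ClassifierSpec(method="svm")
    train_X = np.asarray(train_X, dtype=float)
    test_X = np.atleast_2d(np.asarray(test_X, dtype=float))
    train_y = np.asarray(train_y)
    _check_dims(train_X, test_X)
    classes, codes = np.unique(train_y, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("SVM training requires two classes")
    sigma = spec.sigma if spec.sigma is not None else median_heuristic_sigma(train_X)
    gamma = 1.0 / (2.0 * sigma**2)
    return classes[_svm_codes(train_X, codes, test_X, gamma, spec.cost)]


def _predict(train_X, train_y, test_X, spec: ClassifierSpec) -> np.ndarray:
    if spec.method == "knn":
        return knn_predict(train_X, train_y, test_X, k=spec.k)
    if spec.method == "nearcent":
        return nearcent_fit_predict(train_X, train_y, test_X)
    return svm_fit_predict(train_X, train_y, test_X, spec)


# -- cross-validation ------------------------------------------------------

def make_folds(y: np.ndarray, scheme: CVScheme) -> list[tuple[np.ndarray, np.ndarray]]:
    """Materialized (train, test) index pairs for the scheme.

    Folds depend only on ``y`` and the scheme, so the same fold set can be
    reused across many feature subsets (this is what makes fitness caching
    valid).  Non-stratified folds whose training half lacks a class are
    redrawn from the seeded stream.
    """
    y = np.asarray(y)
    scheme.validate(y)
    if scheme.stratified:
        cv = RepeatedStratifiedKFold(
            n_splits=scheme.n_splits,
            n_repeats=scheme.n_repeats,
            random_state=scheme.seed,
        )
        return [(tr, te) for tr, te in cv.split(np.zeros(len(y)), y)]

    n_classes = len(np.unique(y))
    folds: list[tuple[np.ndarray, np.ndarray]] = []
    for attempt in range(100):
        folds.clear()
        ok = True
        for rep in range(scheme.n_repeats):
            cv = KFold(
                n_splits=scheme.n_splits,
                shuffle=True,
                random_state=scheme.seed + 1000 * attempt + rep,
            )
            for tr, te in cv.split(np.zeros(len(y))):
                if len(np.unique(y[tr])) < n_classes:
                    ok = False
                    break
                folds.append((tr, te))
            if not ok:
                break
        if ok:
            return folds
    raise ConfigurationError("could not draw folds with all classes in training")


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


def cv_accuracy_given_folds(
    X: np.ndarray,
    y: np.ndarray,
    spec: ClassifierSpec,
    folds: list[tuple[np.ndarray, np.ndarray]],
) -> tuple[float, np.ndarray]:
    """Average accuracy over pre-materialized folds (z-scored per fold)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    accs = np.empty(len(folds))
    for j, (tr, te) in enumerate(folds):
        if len(np.unique(y[tr])) < 2:
            raise ConfigurationError("training fold contains a single class")
        Xtr, Xte = _standardize(X[tr], X[te])
        pred = _predict(Xtr, y[tr], Xte, spec)
        accs[j] = float(np.mean(pred == y[te]))
    return float(accs.mean()), accs


class FoldEvaluator:
    """Repeated subset scoring against one fixed fold set.

    Standardization statistics and label codes depend on the fold, not on
    the feature subset, so they are computed once here; ``accuracy(genes)``
    then only slices columns and classifies.  Numerically identical to
    :func:`cv_accuracy_given_folds` on the same folds -- this is a fast
    path, not a different estimator.
    """

    def __init__(self, X, y, spec: ClassifierSpec, folds):
        spec.validate()
        self.spec = spec
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, codes = np.unique(y, return_inverse=True)
        self._binary = len(self.classes_) == 2
        self.folds: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = []
        for tr, te in folds:
            if len(np.unique(codes[tr])) < 2:
                raise ConfigurationError("training fold contains a single class")
            Xtr, Xte = _standardize(X[tr], X[te])
            self.folds.append((Xtr, codes[tr], Xte, codes[te]))

    def _predict_codes(self, Xtr, ctr, Xte) -> np.ndarray:
        spec = self.spec
        if spec.method == "svm":
            sigma = spec.sigma
            if sigma is None:
                sigma = median_heuristic_sigma(Xtr)
            return _svm_codes(Xtr, ctr, Xte, 1.0 / (2.0 * sigma**2), spec.cost)
        if spec.method == "nearcent":
            centroids = np.stack(
                [Xtr[ctr == c].mean(axis=0) for c in range(len(self.classes_))]
            )
            return np.argmin(cdist(Xte, centroids), axis=1)
        # knn; odd k on a binary problem cannot tie, so the vote is a sum
        dist = cdist(Xte, Xtr)
        nearest = np.argsort(dist, axis=1, kind="stable")[:, : spec.k]
        if self._binary:
            return (2 * ctr[nearest].sum(axis=1) > spec.k).astype(int)
        pred_labels = knn_predict(Xtr, self.classes_[ctr], Xte, k=spec.k)
        return np.searchsorted(self.classes_, pred_labels)

    def accuracy(self, genes) -> float:
        cols = list(genes)
        total = 0.0
        for Xtr, ctr, Xte, cte in self.folds:
            pred = self._predict_codes(Xtr[:, cols], ctr, Xte[:, cols])
            total += np.mean(pred == cte)
        return float(total / len(self.folds))


def cv_average_accuracy(
    X,
    y,
    spec: ClassifierSpec | None = None,
    scheme: CVScheme | None = None,
    return_splits: bool = False,
):
    """Mean held-out accuracy of ``spec``'s classifier over the CV scheme.

    Deterministic under a fixed scheme seed.  With ``return_splits`` the
    per-split accuracies come back too.
    """
    spec = spec or ClassifierSpec()
    scheme = scheme or CVScheme()
    spec.validate()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ConfigurationError("feature subset must be a non-empty 2-D matrix")
    folds = make_folds(np.asarray(y), scheme)
    mean, accs = cv_accuracy_given_folds(X, y, spec, folds)
    return (mean, accs) if return_splits else mean
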