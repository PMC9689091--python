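"""Scikit-learn estimator facade over the GA blast + forward selection."""

from __future__ import annotations

import numbers

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, check_X_y

from .classifiers import ClassifierSpec, CVScheme
from .datasets import ConfigurationError
from .forward import forward_select
from .ga import GAConfig, rank_stability, run_blast
from .preprocess import ComparisonDataset
from .table import FeatureTable

__all__ = ["GeneticAlgorithmSelector"]


class GeneticAlgorithmSelector(SelectorMixin, BaseEstimator):
    """GA wrapper feature selection for binary classification.

    ``fit`` runs a blast of independently seeded genetic-algorithm searches
    whose fitness is the cross-validated average accuracy of the chosen
    classifier on each chromosome's feature subset, aggregates gene
    frequencies into a gene rank, and forward-selects the most compact
    nested model near the maximal accuracy.  ``transform`` keeps the
    selected feature columns, so the selector drops into an sklearn
    ``Pipeline`` ahead of any downstream classifier.

    Parameters
    ----------
    method : {"knn", "nearcent", "svm"}, default="knn"
        Fitness classifier.
    k : int, default=3
        KNN neighbour count (odd).
    sigma : float or None, default=None
        RBF width for the SVM; ``None`` uses the median heuristic per fold.
    cost : float, default=1.0
        SVM margin penalty.
    chromosome_size : int, default=5
        Feature-subset size evolved by the GA.
    n_bigbangs : int, default=2100
        Independent GA searches aggregated into the gene rank.
    max_generations : int, default=200
    goal_fitness : float, default=1.0
        A bigbang stops early once its best fitness reaches this.
    population_size : int, default=50
    mutation_rate : float, default=0.05
    elite_count : int, default=2
    cv_splits, cv_repeats : int, defaults 5 and 4
        Repeated stratified k-fold used for every fitness evaluation.
    forward_max_size : int, default=30
        Largest nested model examined by forward selection.
    forward_tolerance : float, default=0.01
        Accuracy slack defining "as accurate as the best" when choosing
        the compact model.
    random_state : int, default=0
        Master seed for the blast and the CV folds.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
    gene_frequency_ : ndarray of shape (n_features,)
        How often each feature appears among the bigbang solutions.
    gene_rank_ : ndarray of shape (n_features,)
        Feature indices by descending frequency (ties by index).
    result_ : GARunResult
        Full blast output (solutions, fitness traces, rank snapshots).
    size_curve_ : ndarray
        Average accuracy of the nested models of sizes 1..forward_max_size.
    chosen_size_ : int
    average_accuracy_ : float
        Cross-validated average accuracy of the selected model.
    support_ : ndarray of bool, shape (n_features,)

    Examples
    --------
    >>> sel = GeneticAlgorithmSelector(method="nearcent", n_bigbangs=20,
    ...                                max_generations=30, random_state=7)
    >>> Xt = sel.fit_transform(X, y)           # doctest: +SKIP
    """

    def __init__(
        self,
        method: str = "knn",
        k: int = 3,
        sigma: float | None = None,
        cost: float = 1.0,
        chromosome_size: int = 5,
        n_bigbangs: int = 2100,
        max_generations: int = 200,
        goal_fitness: float = 1.0,
        population_size: int = 50,
        mutation_rate: float = 0.05,
        elite_count: int = 2,
        cv_splits: int = 5,
        cv_repeats: int = 4,
        forward_max_size: int = 30,
        forward_tolerance: float = 0.01,
        random_state: int = 0,
    ):
        self.method = method
        self.k = k
        self.sigma = sigma
        self.cost = cost
        self.chromosome_size = chromosome_size
        self.n_bigbangs = n_bigbangs
        self.max_generations = max_generations
        self.goal_fitness = goal_fitness
        self.population_size = population_size
        self.mutation_rate = mutation_rate
        self.elite_count = elite_count
        self.cv_splits = cv_splits
        self.cv_repeats = cv_repeats
        self.forward_max_size = forward_max_size
        self.forward_tolerance = forward_tolerance
        self.random_state = random_state

    # -- configuration -----------------------------------------------------
    def _classifier_spec(self) -> ClassifierSpec:
        return ClassifierSpec(
            method=self.method, k=self.k, sigma=self.sigma, cost=self.cost
        )

    def _cv_scheme(self) -> CVScheme:
        seed = self.random_state if isinstance(self.random_state, numbers.Integral) else 0
        return CVScheme(
            n_splits=self.cv_splits, n_repeats=self.cv_repeats, seed=int(seed)
        )

    def _ga_config(self) -> GAConfig:
        return GAConfig(
            chromosome_size=self.chromosome_size,
            goal_fitness=self.goal_fitness,
            max_generations=self.max_generations,
            n_bigbangs=self.n_bigbangs,
            population_size=self.population_size,
            mutation_rate=self.mutation_rate,
            elite_count=self.elite_count,
            classifier=self._classifier_spec(),
            cv=self._cv_scheme(),
            seed=int(self.random_state),
        )

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y):
        """Run the blast and forward selection on a binary problem."""
        feature_names = None
        if isinstance(X, pd.DataFrame):
            feature_names = [str(c) for c in X.columns]
        X, y = check_X_y(X, y, dtype=float)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ConfigurationError(
                f"binary problems only; got {len(self.classes_)} classes"
            )
        self.n_features_in_ = X.shape[1]
        if feature_names is not None:
            self.feature_names_in_ = np.asarray(feature_names, dtype=object)
        names = feature_names or [f"x{i}" for i in range(X.shape[1])]

        frame = pd.DataFrame(X, columns=names)
        frame.index = [f"s{i}" for i in range(len(frame))]
        stages = pd.Series([str(v) for v in y], index=frame.index)
        data = ComparisonDataset(
            name=f"{self.classes_[0]}-{self.classes_[1]}",
            table=FeatureTable(frame, stages),
            positive_label=str(self.classes_[1]),
        )

        self.result_ = run_blast(data, self._ga_config())
        self.gene_frequency_ = self.result_.gene_frequency
        self.gene_rank_ = self.result_.gene_rank

        model = forward_select(
            self.gene_rank_,
            data,
            classifier=self._classifier_spec(),
            scheme=self._cv_scheme(),
            max_size=self.forward_max_size,
            tolerance=self.forward_tolerance,
        )
        self.forward_model_ = model
        self.size_curve_ = model.size_curve
        self.chosen_size_ = model.chosen_size
        self.average_accuracy_ = model.average_accuracy
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[model.feature_indices] = True
        self.support_ = mask
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_

    def rank_stability(self, window: int = 100) -> np.ndarray:
        """Per-feature rank dispersion over the trailing bigbang snapshots."""
        check_is_fitted(self, "result_")
        return rank_stability(self.result_, window=window)

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.required = True
        return tags
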