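"""Genetic-algorithm wrapper feature selection (GALGO-style blast).

A *chromosome* is a fixed-size set of distinct feature indices; its fitness
is the cross-validated average accuracy of a classifier restricted to those
features.  One *bigbang* is a complete, independently seeded evolutionary
search: random initial population, then fitness-proportional parent
selection, uniform gene crossover, per-gene mutation to unused indices and
elitism, until the goal fitness is reached or the generation budget runs
out.  A *blast* runs many bigbangs and aggregates how often each feature
appears among the final solutions (gene frequency), the induced gene rank,
its stability as bigbangs accumulate, and the per-bigbang fitness traces.

Because the cross-validation folds are fixed per blast, fitness depends
only on the gene *set*; identical subsets recur constantly across bigbangs,
so results are memoized (this changes runtime, never results).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .classifiers import (
    ClassifierSpec,
    CVScheme,
    FoldEvaluator,
    make_folds,
)
from .datasets import ConfigurationError
from .preprocess import ComparisonDataset

__all__ = [
    "GAConfig",
    "GARunResult",
    "Solution",
    "evolve_one",
    "run_blast",
    "rank_stability",
    "gene_rank_from_frequency",
    "bigbang_seed",
    "exhaustive_best_subset",
]

Genes = tuple[int, ...]


@dataclass(frozen=True)
class GAConfig:
    """Search settings for one blast.

    Defaults follow the published configuration of this analysis:
    chromosome size 5, goal fitness 1.0 (stop a bigbang as soon as a
    perfect cross-validated subset is found), 200 generations and 2100
    bigbangs.  Population size, mutation rate, elite count and parent
    selection are this engine's own conventions (see docs/methods.md).
    """

    chromosome_size: int = 5
    goal_fitness: float = 1.0
    max_generations: int = 200
    n_bigbangs: int = 2100
    population_size: int = 50
    mutation_rate: float = 0.05
    elite_count: int = 2
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    cv: CVScheme = field(default_factory=CVScheme)
    seed: int = 0

    def validate(self, n_features: int) -> None:
        if not 0 < self.goal_fitness <= 1:
            raise ConfigurationError("goal_fitness must be in (0, 1]")
        if self.max_generations < 1:
            raise ConfigurationError("max_generations must be >= 1")
        if self.n_bigbangs < 1:
            raise ConfigurationError("n_bigbangs must be >= 1")
        if self.population_size < 2:
            raise ConfigurationError("population_size must be >= 2")
        if not 0 <= self.mutation_rate <= 1:
            raise ConfigurationError("mutation_rate must be in [0, 1]")
        if not 0 <= self.elite_count < self.population_size:
            raise ConfigurationError("elite_count must be in [0, population_size)")
        if not 1 <= self.chromosome_size <= n_features:
            raise ConfigurationError(
                f"chromosome_size={self.chromosome_size} incompatible with "
                f"{n_features} features"
            )
        self.classifier.validate()


@dataclass(frozen=True)
class Solution:
    """The best chromosome of one bigbang."""

    genes: Genes
    fitness: float
    generations: int  # generations evaluated before stopping


@dataclass
class GARunResult:
    """Aggregated outcome of a blast over one comparison dataset."""

    comparison: str
    method: str
    n_features: int
    solutions: list[Solution]
    gene_frequency: np.ndarray = field(repr=False)
    gene_rank: np.ndarray = field(repr=False)  # feature idx, descending frequency
    rank_stability_trace: np.ndarray = field(repr=False)  # (n_bigbangs, n_features) rank positions
    fitness_traces: list[np.ndarray] = field(repr=False)
    feature_names: list[str] | None = None

    @property
    def best_solution(self) -> Solution:
        return max(self.solutions, key=lambda s: (s.fitness, -s.generations))

    def top_features(self, n: int) -> list[int]:
        return [int(i) for i in self.gene_rank[:n]]

    def to_json_dict(self) -> dict:
        return {
            "comparison": self.comparison,
            "method": self.method,
            "n_features": self.n_features,
            "solutions": [
                {"genes": list(map(int, s.genes)), "fitness": s.fitness,
                 "generations": s.generations}
                for s in self.solutions
            ],
            "gene_frequency": [int(c) for c in self.gene_frequency],
            "gene_rank": [int(i) for i in self.gene_rank],
            "fitness_traces": [[float(v) for v in t] for t in self.fitness_traces],
        }


def gene_rank_from_frequency(freq: np.ndarray) -> np.ndarray:
    """Features ordered by descending frequency, ties broken by index."""
    return np.lexsort((np.arange(len(freq)), -np.asarray(freq)))


def bigbang_seed(master_seed: int, index: int) -> np.random.SeedSequence:
    """Child seed of bigbang ``index``.

    The rule is stateless in ``index``, so a blast with fewer bigbangs is an
    exact prefix of a longer blast with the same master seed.
    """
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))


# -- genetic operators -----------------------------------------------------

def _check_chromosome(genes: np.ndarray, size: int, n_features: int) -> None:
    if len(genes) != size or len(np.unique(genes)) != size:
        raise AssertionError(f"invalid chromosome {genes}")
    if genes.min() < 0 or genes.max() >= n_features:
        raise AssertionError(f"gene out of range in {genes}")

def _random_chromosome(rng, n_features: int, size: int) -> np.ndarray:
    return rng.choice(n_features, size=size, replace=False)


def _repair(genes: np.ndarray, rng, n_features: int) -> np.ndarray:
    """Replace duplicate genes with random unused feature indices."""
    seen: set[int] = set()
    dup_pos = []
    for pos, g in enumerate(genes):
        if g in seen:
            dup_pos.append(pos)
        seen.add(int(g))
    for pos in dup_pos:
        g = int(rng.integers(n_features))
        while g in seen:
            g = int(rng.integers(n_features))
        genes[pos] = g
        seen.add(g)
    return genes


def _crossover(pa: np.ndarray, pb: np.ndarray, rng, n_features: int) -> np.ndarray:
    """Uniform gene crossover followed by duplicate repair."""
    take_a = rng.random(len(pa)) < 0.5
    child = np.where(take_a, pa, pb).copy()
    return _repair(child, rng, n_features)


def _mutate(genes: np.ndarray, rng, n_features: int, rate: float) -> np.ndarray:
    hit = rng.random(len(genes)) < rate
    if hit.any():
        present = set(int(g) for g in genes)
        for pos in np.flatnonzero(hit):
            g = int(rng.integers(n_features))
            while g in present:
                g = int(rng.integers(n_features))
            present.discard(int(genes[pos]))
            present.add(g)
            genes[pos] = g
    return genes


def _roulette(fitness: np.ndarray, rng) -> int:
    total = fitness.sum()
    if total <= 0:
        return int(rng.integers(len(fitness)))
    return int(rng.choice(len(fitness), p=fitness / total))


# -- evolution -------------------------------------------------------------

def _evolve(
    n_features: int,
    cfg: GAConfig,
    rng: np.random.Generator,
    evaluate: Callable[[Genes], float],
) -> tuple[Solution, np.ndarray]:
    size = cfg.chromosome_size
    pop = [_random_chromosome(rng, n_features, size) for _ in range(cfg.population_size)]
    best_genes: Genes = ()
    best_fit = -np.inf
    trace: list[float] = []

    for gen in range(cfg.max_generations):
        fitness = np.empty(cfg.population_size)
        for i, genes in enumerate(pop):
            _check_chromosome(genes, size, n_features)
            fitness[i] = evaluate(tuple(sorted(int(g) for g in genes)))
        gen_best = int(np.argmax(fitness))
        if fitness[gen_best] > best_fit:
            best_fit = float(fitness[gen_best])
            best_genes = tuple(sorted(int(g) for g in pop[gen_best]))
        trace.append(best_fit)
        if best_fit >= cfg.goal_fitness or gen == cfg.max_generations - 1:
            return Solution(best_genes, best_fit, gen + 1), np.array(trace)

        # elites survive unchanged; the rest are offspring
        elite_order = np.lexsort((np.arange(cfg.population_size), -fitness))
        next_pop = [pop[i].copy() for i in elite_order[: cfg.elite_count]]
        while len(next_pop) < cfg.population_size:
            pa = pop[_roulette(fitness, rng)]
            pb = pop[_roulette(fitness, rng)]
            child = _crossover(pa, pb, rng, n_features)
            child = _mutate(child, rng, n_features, cfg.mutation_rate)
            _check_chromosome(child, size, n_features)
            next_pop.append(child)
        pop = next_pop

    raise AssertionError("unreachable")  # pragma: no cover


def evolve_one(
    data: ComparisonDataset,
    cfg: GAConfig,
    bigbang_seed_value,
    cache: dict[Genes, float] | None = None,
    folds=None,
) -> tuple[Genes, float, np.ndarray]:
    """Run a single bigbang; returns (best genes, fitness, max-fitness trace).

    ``bigbang_seed_value`` may be an int or a ``numpy.random.SeedSequence``.
    A shared ``cache`` and pre-made ``folds`` let a blast reuse fitness
    evaluations across bigbangs.
    """
    X, y = data.X, data.y
    cfg.validate(X.shape[1])
    if folds is None:
        folds = make_folds(y, cfg.cv)
    if cache is None:
        cache = {}
    scorer = FoldEvaluator(X, y, cfg.classifier, folds)

    def evaluate(genes: Genes) -> float:
        hit = cache.get(genes)
        if hit is None:
            hit = scorer.accuracy(genes)
            cache[genes] = hit
        return hit

    rng = np.random.default_rng(bigbang_seed_value)
    sol, trace = _evolve(X.shape[1], cfg, rng, evaluate)
    return sol.genes, sol.fitness, trace


def run_blast(data: ComparisonDataset, cfg: GAConfig) -> GARunResult:
    """Run ``cfg.n_bigbangs`` independent searches and aggregate them.

    Deterministic under ``cfg.seed``; bigbang *i* always receives the same
    child seed regardless of how many bigbangs run, so a short blast is a
    prefix of a long one.
    """
    X, y = data.X, data.y
    n_features = X.shape[1]
    cfg.validate(n_features)
    folds = make_folds(y, cfg.cv)
    cache: dict[Genes, float] = {}
    scorer = FoldEvaluator(X, y, cfg.classifier, folds)

    def evaluate(genes: Genes) -> float:
        hit = cache.get(genes)
        if hit is None:
            hit = scorer.accuracy(genes)
            cache[genes] = hit
        return hit

    solutions: list[Solution] = []
    traces: list[np.ndarray] = []
    freq = np.zeros(n_features, dtype=np.int64)
    rank_positions = np.empty((cfg.n_bigbangs, n_features), dtype=np.int32)

    for i in range(cfg.n_bigbangs):
        rng = np.random.default_rng(bigbang_seed(cfg.seed, i))
        sol, trace = _evolve(n_features, cfg, rng, evaluate)
        solutions.append(sol)
        traces.append(trace)
        freq[list(sol.genes)] += 1
        order = gene_rank_from_frequency(freq)
        rank_positions[i, order] = np.arange(n_features)

    return GARunResult(
        comparison=data.name,
        method=cfg.classifier.method,
        n_features=n_features,
        solutions=solutions,
        gene_frequency=freq,
        gene_rank=gene_rank_from_frequency(freq),
        rank_stability_trace=rank_positions,
        fitness_traces=traces,
        feature_names=data.feature_names,
    )


def rank_stability(result: GARunResult, window: int = 100) -> np.ndarray:
    """Per-feature dispersion (standard deviation) of its rank position over
    the trailing ``window`` bigbang snapshots.  Lower is more stable; a
    converged top feature has dispersion near zero.
    """
    trace = np.asarray(result.rank_stability_trace)
    if trace.shape[0] < 2:
        raise ConfigurationError("rank stability needs at least 2 snapshots")
    if window > trace.shape[0]:
        warnings.warn(
            f"window {window} exceeds the {trace.shape[0]} snapshots; clipping",
            stacklevel=2,
        )
        window = trace.shape[0]
    return trace[-window:].std(axis=0)


def exhaustive_best_subset(
    data: ComparisonDataset,
    size: int,
    classifier: ClassifierSpec | None = None,
    cv: CVScheme | None = None,
) -> tuple[Genes, float]:
    """Evaluate every size-``size`` subset; the independent optimum.

    Intended for small problems (the subset count is combinatorial); used
    to certify that the GA attains the global best fitness.
    """
    classifier = classifier or ClassifierSpec()
    cv = cv or CVScheme()
    X, y = data.X, data.y
    folds = make_folds(y, cv)
    scorer = FoldEvaluator(X, y, classifier, folds)
    best: tuple[Genes, float] = ((), -np.inf)
    for comb in itertools.combinations(range(X.shape[1]), size):
        fit = scorer.accuracy(comb)
        if fit > best[1]:
            best = (comb, fit)
    return best
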