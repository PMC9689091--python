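import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import metaboga as mg
from metaboga.ga import (
    _check_chromosome,
    _crossover,
    _mutate,
    _random_chromosome,
    _repair,
    bigbang_seed,
)


def _tiny_cfg(**kw):
    base = dict(
        chromosome_size=3,
        n_bigbangs=4,
        max_generations=10,
        population_size=12,
        classifier=mg.ClassifierSpec("knn"),
        cv=mg.CVScheme(n_repeats=2, seed=1),
        seed=0,
    )
    base.update(kw)
    return mg.GAConfig(**base)


# -- genetic operators preserve chromosome validity ------------------------

@settings(max_examples=40, derandomize=True, deadline=None)
@given(
    seed=st.integers(0, 10_000),
    n_features=st.integers(6, 60),
    size=st.integers(1, 5),
    rate=st.floats(0.0, 1.0),
)
def test_operators_preserve_size_uniqueness_range(seed, n_features, size, rate):
    rng = np.random.default_rng(seed)
    size = min(size, n_features)
    pa = _random_chromosome(rng, n_features, size)
    pb = _random_chromosome(rng, n_features, size)
    child = _crossover(pa, pb, rng, n_features)
    _check_chromosome(child, size, n_features)
    mutated = _mutate(child.copy(), rng, n_features, rate)
    _check_chromosome(mutated, size, n_features)
    broken = np.full(size, pa[0])  # worst case: all duplicates
    _check_chromosome(_repair(broken.copy(), rng, n_features), size, n_features)


# -- evolve_one ------------------------------------------------------------

def test_goal_reached_in_generation_zero_stops_immediately(planted_pair):
    data, _ = planted_pair
    # chromosome_size == n_features: every generation-0 chromosome contains
    # the perfectly separating planted features, so fitness 1 is immediate
    small = mg.ComparisonDataset(
        name=data.name,
        table=mg.FeatureTable(
            data.table.intensities.iloc[:, :3], data.table.stages
        ),
        positive_label=data.positive_label,
    )
    cfg = _tiny_cfg(chromosome_size=3, max_generations=50)
    genes, fitness, trace = mg.evolve_one(small, cfg, bigbang_seed(0, 0))
    assert fitness == 1.0
    assert len(trace) == 1  # stopped after the first evaluated generation


def test_single_generation_returns_fittest_of_population(planted_pair):
    data, _ = planted_pair
    cfg = _tiny_cfg(max_generations=1, population_size=6, goal_fitness=1.0)
    genes, fitness, trace = mg.evolve_one(data, cfg, bigbang_seed(3, 0))
    assert len(trace) == 1 and trace[0] == fitness
    # replay generation 0 by hand with the same child seed
    rng = np.random.default_rng(bigbang_seed(3, 0))
    pop = [rng.choice(data.X.shape[1], size=3, replace=False) for _ in range(6)]
    fits = [
        mg.cv_average_accuracy(data.X[:, sorted(c)], data.y, cfg.classifier, cfg.cv)
        for c in pop
    ]
    assert fitness == max(fits)


def test_max_fitness_trace_is_non_decreasing(planted_pair):
    data, _ = planted_pair
    # noise-only columns: the goal is unreachable, so the trace runs long
    noise = mg.ComparisonDataset(
        name=data.name,
        table=mg.FeatureTable(data.table.intensities.iloc[:, 2:], data.table.stages),
        positive_label=data.positive_label,
    )
    cfg = _tiny_cfg(max_generations=15)
    _, _, trace = mg.evolve_one(noise, cfg, bigbang_seed(5, 0))
    assert len(trace) == 15
    assert (np.diff(trace) >= 0).all()


def test_oversized_chromosome_rejected(planted_pair):
    data, _ = planted_pair
    with pytest.raises(mg.ConfigurationError, match="chromosome_size"):
        mg.evolve_one(data, _tiny_cfg(chromosome_size=10_000), 0)


# -- run_blast -------------------------------------------------------------

def test_gene_frequency_conservation(planted_pair):
    data, _ = planted_pair
    res = mg.run_blast(data, _tiny_cfg(n_bigbangs=5))
    assert res.gene_frequency.sum() == 3 * 5
    res1 = mg.run_blast(data, _tiny_cfg(n_bigbangs=1))
    assert res1.gene_frequency.sum() == 3


def test_blast_deterministic_and_prefix_stable(planted_pair):
    data, _ = planted_pair
    a = mg.run_blast(data, _tiny_cfg(n_bigbangs=6))
    b = mg.run_blast(data, _tiny_cfg(n_bigbangs=6))
    assert a.solutions == b.solutions
    assert (a.gene_frequency == b.gene_frequency).all()
    assert (a.gene_rank == b.gene_rank).all()
    shorter = mg.run_blast(data, _tiny_cfg(n_bigbangs=3))
    assert shorter.solutions == a.solutions[:3]


def test_planted_features_dominate_gene_rank(planted_pair):
    data, truth = planted_pair
    cfg = _tiny_cfg(n_bigbangs=20, max_generations=20)
    res = mg.run_blast(data, cfg)
    top5 = set(res.top_features(5))
    assert {0, 1} <= top5  # the two planted features
    # oracle: marginal single-feature CV accuracy also ranks them first
    marg = [
        mg.cv_average_accuracy(data.X[:, [j]], data.y, cfg.classifier, cfg.cv)
        for j in range(data.X.shape[1])
    ]
    assert set(np.argsort(marg)[-2:]) == {0, 1}


def test_perfect_feature_has_strictly_maximal_frequency():
    rng = np.random.default_rng(77)
    n = 30
    X = rng.lognormal(0.0, 0.3, size=(n, 12))
    y = np.array(["A"] * 15 + ["B"] * 15)
    X[:, 4] = np.where(y == "A", 1.0, 20.0) + rng.normal(0, 0.1, n)
    ids = pd.Index([f"s{i}" for i in range(n)], name="sample_id")
    frame_table = mg.FeatureTable(
        pd.DataFrame(X, index=ids, columns=[f"M{j}" for j in range(12)]),
        pd.Series(y, index=ids),
    )
    data = mg.ComparisonDataset("A-B", frame_table, "B")
    cfg = _tiny_cfg(chromosome_size=2, n_bigbangs=50, max_generations=15)
    res = mg.run_blast(data, cfg)
    best = res.gene_frequency.argmax()
    assert best == 4
    others = np.delete(res.gene_frequency, 4)
    assert res.gene_frequency[4] > others.max()


def test_blast_matches_exhaustive_enumeration(planted_pair):
    data, _ = planted_pair
    cfg = _tiny_cfg(
        chromosome_size=2, n_bigbangs=8, max_generations=20, population_size=20
    )
    small = mg.ComparisonDataset(
        name=data.name,
        table=mg.FeatureTable(data.table.intensities.iloc[:, :10], data.table.stages),
        positive_label=data.positive_label,
    )
    res = mg.run_blast(small, cfg)
    best_ga = res.best_solution.fitness
    _, best_exhaustive = mg.exhaustive_best_subset(
        small, 2, cfg.classifier, cfg.cv
    )
    assert best_ga == pytest.approx(best_exhaustive, abs=1e-12)


def test_zero_bigbangs_rejected(planted_pair):
    data, _ = planted_pair
    with pytest.raises(mg.ConfigurationError, match="bigbangs"):
        mg.run_blast(data, _tiny_cfg(n_bigbangs=0))


# -- rank stability --------------------------------------------------------

def test_rank_stability_contrasts_planted_and_noise(planted_pair):
    data, _ = planted_pair
    res = mg.run_blast(data, _tiny_cfg(n_bigbangs=20, max_generations=20))
    disp = mg.rank_stability(res, window=10)
    assert disp.shape == (data.X.shape[1],)
    planted_disp = disp[[0, 1]].mean()
    noise_disp = disp[2:].mean()
    assert planted_disp < noise_disp


def test_never_selected_features_sit_in_index_ordered_tail(planted_pair):
    """Zero-frequency features occupy the rank tail, tie-broken by index;
    once gene frequencies stop changing their dispersion is exactly zero."""
    data, _ = planted_pair
    res = mg.run_blast(data, _tiny_cfg(n_bigbangs=10, max_generations=20))
    never = np.flatnonzero(res.gene_frequency == 0)
    tail = res.gene_rank[-len(never):] if len(never) else []
    assert sorted(map(int, tail)) == list(map(int, tail))  # index order
    assert set(map(int, tail)) == set(map(int, never))
    # frequencies are frozen after the last bigbang, so a single-snapshot
    # window is exactly stable for every feature
    disp = mg.rank_stability(res, window=1)
    assert np.allclose(disp, 0.0)


def test_window_clipped_with_warning(planted_pair):
    data, _ = planted_pair
    res = mg.run_blast(data, _tiny_cfg(n_bigbangs=3))
    with pytest.warns(UserWarning, match="clipping"):
        mg.rank_stability(res, window=100)


def test_stability_requires_two_snapshots(planted_pair):
    data, _ = planted_pair
    res = mg.run_blast(data, _tiny_cfg(n_bigbangs=1))
    with pytest.raises(mg.ConfigurationError):
        mg.rank_stability(res)
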