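"""Genetic-algorithm descriptor selection with LOO-PRESS fitness.

A chromosome is a fixed-cardinality set of N descriptor indices (the model
size is a constraint, chosen by the 5:1 observations-per-parameter
guideline, not part of the objective).  Fitness is the leave-one-out PRESS
of the shielding-coefficient activity model restricted to the subset —
lower is better.  Selection is tournament (size 2) with elitism; uniform
crossover exchanges indices and repairs duplicates by refilling from unused
indices; per-gene mutation replaces an index with a random unused one.
Every run is fully reproducible from its seed, and fitness values are
memoized by canonical (sorted) subset, so revisited subsets cost nothing.

An exhaustive enumerator over all C(p, N) subsets serves as the optimality
oracle for small instances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .activity_model import ActivityDataset, loo_predictions
from .validation_stats import press


@dataclass
class GAConfig:
    """GA hyperparameters.  Defaults mirror the published configuration
    (population 500, 500 generations, crossover 0.5, mutation 0.01, N=12)."""

    seed: int
    population_size: int = 500
    generations: int = 500
    crossover_prob: float = 0.5
    mutation_prob: float = 0.01
    subset_size: int = 12
    tournament_size: int = 2
    elitism: int = 1
    early_stop_patience: Optional[int] = None
    restarts: int = 1

    def validate(self, p: int) -> None:
        if not (0 <= self.crossover_prob <= 1 and 0 <= self.mutation_prob <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.subset_size > p:
            raise ValueError(f"subset_size {self.subset_size} exceeds p={p}")
        if self.population_size < 2:
            raise ValueError("population must hold at least 2 individuals")
        if self.subset_size < 1 or self.generations < 1 or self.restarts < 1:
            raise ValueError("counts must be >= 1")
        if self.elitism < 0 or self.elitism >= self.population_size:
            raise ValueError("elitism must lie in [0, population_size)")


@dataclass
class GAResult:
    best_subset: tuple[int, ...]
    best_fitness: float
    fitness_trace: list[tuple[float, float]]   # per-generation (best, mean)
    evaluations: int
    seed: int


def fitness(subset: Sequence[int], dataset: ActivityDataset,
            seed: int = 0) -> float:
    """LOO-PRESS of the kappa model restricted to ``subset`` (1-based)."""
    idx = list(subset)
    if len(set(idx)) != len(idx):
        raise ValueError(f"duplicate indices in subset {idx}")
    table = loo_predictions(dataset, sorted(idx), seed=seed)
    return press(table["a_exp"], table["a_calc"])


class _Memo:
    """Canonical-subset fitness cache; counts true evaluations."""

    def __init__(self, fn: Callable[[tuple[int, ...]], float]):
        self.fn = fn
        self.cache: dict[tuple[int, ...], float] = {}
        self.evaluations = 0

    def __call__(self, subset: Sequence[int]) -> float:
        key = tuple(sorted(subset))
        if key not in self.cache:
            self.cache[key] = self.fn(key)
            self.evaluations += 1
        return self.cache[key]


def _repair(genes: np.ndarray, n_target: int, p: int,
            rng: np.random.Generator) -> np.ndarray:
    """Deduplicate and refill a chromosome to exactly n_target unique indices."""
    unique = list(dict.fromkeys(genes.tolist()))
    if len(unique) < n_target:
        unused = np.setdiff1d(np.arange(1, p + 1), unique)
        extra = rng.choice(unused, size=n_target - len(unique), replace=False)
        unique.extend(int(x) for x in extra)
    return np.array(sorted(unique[:n_target]), dtype=int)


def ga_search(dataset: ActivityDataset, config: GAConfig,
              fitness_fn: Optional[Callable[[Sequence[int]], float]] = None
              ) -> GAResult:
    """Run the GA; fully reproducible for a given config seed.

    ``fitness_fn`` defaults to the LOO-PRESS kappa-model fitness on
    ``dataset``; any callable on 1-based index tuples may replace it.
    """
    p = dataset.p
    config.validate(p)
    N = config.subset_size
    memo = _Memo(fitness_fn or (lambda s: fitness(s, dataset)))
    rng = np.random.default_rng(config.seed)

    if N == p:
        full = tuple(range(1, p + 1))
        value = memo(full)
        return GAResult(best_subset=full, best_fitness=value,
                        fitness_trace=[(value, value)],
                        evaluations=memo.evaluations, seed=config.seed)

    best_subset: Optional[tuple[int, ...]] = None
    best_fitness = math.inf
    trace: list[tuple[float, float]] = []

    for _restart in range(config.restarts):
        population = [np.sort(rng.choice(np.arange(1, p + 1), size=N,
                                         replace=False))
                      for _ in range(config.population_size)]
        stall = 0
        run_best = math.inf
        for _gen in range(config.generations):
            values = np.array([memo(ind) for ind in population])
            order = np.argsort(values, kind="stable")
            gen_best = float(values[order[0]])
            trace.append((gen_best, float(values.mean())))
            if gen_best < best_fitness:
                best_fitness = gen_best
                best_subset = tuple(int(i) for i in population[order[0]])
            if gen_best < run_best - 1e-15:
                run_best, stall = gen_best, 0
            else:
                stall += 1
                if (config.early_stop_patience is not None
                        and stall >= config.early_stop_patience):
                    break

            elite = [population[i].copy() for i in order[:config.elitism]]
            children = list(elite)
            while len(children) < config.population_size:
                pa = _tournament(population, values, config.tournament_size, rng)
                pb = _tournament(population, values, config.tournament_size, rng)
                if rng.random() < config.crossover_prob:
                    swap = rng.random(N) < 0.5
                    ca = np.where(swap, pb, pa)
                    cb = np.where(swap, pa, pb)
                else:
                    ca, cb = pa.copy(), pb.copy()
                for child in (ca, cb):
                    child = _repair(child, N, p, rng)
                    mutate = rng.random(N) < config.mutation_prob
                    if mutate.any():
                        unused = np.setdiff1d(np.arange(1, p + 1), child)
                        for pos in np.flatnonzero(mutate):
                            if unused.size == 0:
                                break
                            pick = rng.integers(unused.size)
                            child[pos], unused[pick] = unused[pick], child[pos]
                        child = np.sort(child)
                    if len(children) < config.population_size:
                        children.append(child)
            population = children

    # Score of the final population's survivors is already folded into trace.
    assert best_subset is not None
    return GAResult(best_subset=best_subset, best_fitness=best_fitness,
                    fitness_trace=trace, evaluations=memo.evaluations,
                    seed=config.seed)


def _tournament(population: list[np.ndarray], values: np.ndarray,
                size: int, rng: np.random.Generator) -> np.ndarray:
    picks = rng.integers(len(population), size=size)
    winner = picks[np.argmin(values[picks])]
    return population[winner]


def exhaustive_search(dataset: ActivityDataset, subset_size: int,
                      fitness_fn: Optional[Callable[[Sequence[int]], float]]
                      = None, guard: int = 100_000
                      ) -> tuple[tuple[int, ...], float]:
    """Evaluate every C(p, N) subset; ties break lexicographically."""
    import itertools

    p = dataset.p
    total = math.comb(p, subset_size)
    if total > guard:
        raise ValueError(
            f"exhaustive search guard exceeded: C({p},{subset_size}) = {total}")
    fn = fitness_fn or (lambda s: fitness(s, dataset))
    best_subset, best_value = None, math.inf
    for subset in itertools.combinations(range(1, p + 1), subset_size):
        value = fn(subset)
        if value < best_value:
            best_subset, best_value = subset, value
    return best_subset, best_value
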