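"""Evolution Strategy over scaling-factor vectors.

The one method here that optimizes a success metric directly: an
individual is a vector of per-sample scaling factors ``y`` (canonicalized
to product 1, since the uniform-gene count is invariant under global
rescaling), and its fitness ``F(y)`` is the number of uniform genes
(CoV < ``cov_cutoff``) after scaling the raw matrix by ``y``.

The population is grown, sorted and trimmed in rounds.  Each round adds
four classes of five offspring: (a) mutants of the current best
individual, (b) mutants of parents drawn from ranks 2-10, (c) mutants of
parents from the remaining individuals, (d) recombinations of two
distinct random individuals.  Mutation is multiplicative in log2 space
(each coordinate times ``2**u``, ``u ~ U[-delta, delta)``); recombination
is per-coordinate uniform crossover.  Parents and offspring are sorted
together by decreasing fitness (stable, ties by insertion order) and the
population truncated to the 200 fittest, so the best fitness never
decreases.  The run stops after 100 improvement-free rounds, a round
limit, or a wall-clock budget.

The initial population is either 10 random factor vectors (``2**r``,
``r ~ U[-0.5, 0.5)``) plus the identity, or user-supplied seed solutions
(e.g. factors from a deterministic method, to be refined) plus the
identity.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gmean

from ._exceptions import DomainError
from .io import validate_matrix
from .scalers import BaseFactorScaler, adjust_factors

__all__ = ["ESConfig", "ESIndividual", "ESResult", "mutate", "recombine", "evolve", "EvolutionStrategyScaler"]


@dataclass
class ESConfig:
    """Tunables of the evolution strategy.

    ``delta`` is the mutation half-width in log2 units (a coordinate moves
    by at most ``2**delta``-fold per mutation); ``cov_cutoff`` defines the
    uniform-gene fitness; ``time_budget`` is in seconds (None = no limit);
    ``max_rounds`` bounds the total rounds regardless of convergence.
    """

    population_cap: int = 200
    offspring_per_class: int = 5
    init_size: int = 10
    convergence_rounds: int = 100
    delta: float = 0.02
    cov_cutoff: float = 0.25
    max_rounds: int | None = None
    time_budget: float | None = None
    seed: int = 0

    def validate(self) -> "ESConfig":
        for name in ("population_cap", "offspring_per_class", "init_size", "convergence_rounds"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")
        if self.delta <= 0 or self.cov_cutoff <= 0:
            raise DomainError("delta and cov_cutoff must be positive")
        return self


@dataclass
class ESIndividual:
    """One candidate solution: a product-1 factor vector and its fitness
    (uniform-gene count, an integer in [0, number of genes])."""

    y: np.ndarray
    fitness: int


@dataclass
class ESResult:
    best: ESIndividual
    factors: pd.Series
    trajectory: list[int] = field(repr=False, default_factory=list)
    rounds: int = 0
    converged: bool = False


def _canonicalize(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if (y <= 0).any():
        raise DomainError("factor vectors must be strictly positive")
    return y / gmean(y)


def mutate(parent: np.ndarray, delta: float, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative mutation: each coordinate times ``2**u`` with
    ``u ~ U[-delta, delta)``, then re-canonicalized to product 1."""
    if delta <= 0:
        raise DomainError("delta must be positive")
    u = rng.uniform(-delta, delta, size=len(parent))
    return _canonicalize(parent * np.exp2(u))


def recombine(a: np.ndarray, b: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-coordinate uniform crossover of two parents, re-canonicalized."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise DomainError("parents have mismatched sample dimensions")
    take_a = rng.integers(0, 2, size=len(a)).astype(bool)
    return _canonicalize(np.where(take_a, a, b))


def _fitness_fn(values: np.ndarray, cov_cutoff: float):
    """Uniform-gene count as a function of a factor vector, over a fixed
    raw value matrix (genes x samples)."""

    def fitness(y: np.ndarray) -> int:
        scaled = values * y[None, :]
        mean = scaled.mean(axis=1)
        sd = scaled.std(axis=1, ddof=1)
        ok = mean > 0
        return int(np.count_nonzero(ok & (sd < cov_cutoff * np.maximum(mean, 0))))

    return fitness


def evolve(matrix: pd.DataFrame, config: ESConfig | None = None, seeds=None) -> ESResult:
    """Run the evolution strategy on an expression matrix.

    ``seeds`` is an optional list of factor Series/arrays used (after
    canonicalization) as the initial population together with the identity
    vector; without seeds the initial population is ``init_size`` random
    vectors plus the identity, so the fitness trajectory starts at the
    unnormalized matrix's uniform-gene count.
    """
    config = (config or ESConfig()).validate()
    validate_matrix(matrix)
    values = matrix.to_numpy(dtype=float)
    n_samples = values.shape[1]
    fitness = _fitness_fn(values, config.cov_cutoff)
    rng = np.random.default_rng(config.seed)

    population: list[ESIndividual] = []

    def add(y: np.ndarray) -> None:
        population.append(ESIndividual(y=y, fitness=fitness(y)))

    if seeds is not None:
        # previously computed solutions to refine; listed first so elitist
        # tie-breaking (insertion order) retains the best seed unless a
        # strictly fitter solution is found
        for s in seeds:
            y = np.asarray(pd.Series(s).reindex(matrix.columns) if isinstance(s, pd.Series) else s, dtype=float)
            if y.shape != (n_samples,):
                raise DomainError("seed solution has wrong sample dimension")
            add(_canonicalize(y))
    else:
        # identity first, so the trajectory starts at the unnormalized fitness
        add(np.ones(n_samples))
        for _ in range(config.init_size):
            add(_canonicalize(np.exp2(rng.uniform(-0.5, 0.5, size=n_samples))))

    def rank() -> None:
        # stable sort by decreasing fitness; Python's sort preserves
        # insertion order among ties
        population.sort(key=lambda ind: -ind.fitness)
        del population[config.population_cap:]

    # the trace starts at the first individual's fitness: the unnormalized
    # matrix in the unseeded case, the first seed otherwise
    trajectory = [population[0].fitness]
    rank()
    best_fitness = population[0].fitness
    stale = 0
    rounds = 0
    deadline = None if config.time_budget is None else time.monotonic() + config.time_budget

    while True:
        if config.max_rounds is not None and rounds >= config.max_rounds:
            break
        if stale >= config.convergence_rounds:
            break
        if deadline is not None and time.monotonic() >= deadline:
            break
        rounds += 1
        k = config.offspring_per_class
        parents_elite = population[0]
        mid = population[1:10] or population
        rest = population[10:] or population
        offspring: list[np.ndarray] = []
        offspring += [mutate(parents_elite.y, config.delta, rng) for _ in range(k)]
        offspring += [mutate(mid[rng.integers(len(mid))].y, config.delta, rng) for _ in range(k)]
        offspring += [mutate(rest[rng.integers(len(rest))].y, config.delta, rng) for _ in range(k)]
        if len(population) >= 2:
            for _ in range(k):
                i, j = rng.choice(len(population), size=2, replace=False)
                offspring.append(recombine(population[i].y, population[j].y, rng))
        for y in offspring:
            add(y)
        rank()
        if population[0].fitness > best_fitness:
            best_fitness = population[0].fitness
            stale = 0
        else:
            stale += 1
        trajectory.append(best_fitness)

    best = population[0]
    factors = adjust_factors(pd.Series(best.y, index=matrix.columns))
    return ESResult(
        best=best,
        factors=factors,
        trajectory=trajectory,
        rounds=rounds,
        converged=stale >= config.convergence_rounds,
    )


class EvolutionStrategyScaler(BaseFactorScaler):
    """scikit-learn estimator wrapping :func:`evolve`.

    ``seeds`` may hold previously computed factor vectors (e.g. from the
    network-centrality or total-ubiquitous methods) to refine; elitist
    truncation guarantees the final fitness is at least the best seed's.
    Fitted attributes: ``factors_``, ``fitness_``, ``trajectory_``,
    ``rounds_``, ``converged_``.
    """

    method_name = "es"

    def __init__(
        self,
        cov_cutoff: float = 0.25,
        delta: float = 0.02,
        convergence_rounds: int = 100,
        max_rounds: int | None = None,
        time_budget: float | None = None,
        population_cap: int = 200,
        init_size: int = 10,
        seed: int = 0,
        seeds=None,
    ):
        self.cov_cutoff = cov_cutoff
        self.delta = delta
        self.convergence_rounds = convergence_rounds
        self.max_rounds = max_rounds
        self.time_budget = time_budget
        self.population_cap = population_cap
        self.init_size = init_size
        self.seed = seed
        self.seeds = seeds

    def _compute_factors(self, X: pd.DataFrame) -> pd.Series:
        config = ESConfig(
            population_cap=self.population_cap,
            init_size=self.init_size,
            convergence_rounds=self.convergence_rounds,
            delta=self.delta,
            cov_cutoff=self.cov_cutoff,
            max_rounds=self.max_rounds,
            time_budget=self.time_budget,
            seed=self.seed,
        )
        result = evolve(X, config, seeds=self.seeds)
        self.fitness_ = result.best.fitness
        self.trajectory_ = result.trajectory
        self.rounds_ = result.rounds
        self.converged_ = result.converged
        self.metadata_ = {"fitness": self.fitness_, "rounds": self.rounds_, "seed": self.seed}
        return result.factors
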