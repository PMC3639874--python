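"""Evolutionary optimization of assignment-edge weights.

The raw search space is the box [-0.5, 0.5]^m over the query's m heavy
atoms; a candidate is mapped onto the weight constraint set (w >= 0,
sum w = m) by :func:`oascreen.assignment.normalize_weights` inside the
fitness function.  The fitness of a weight vector is 1 - metric of the
virtual-screening ranking it produces on the optimization dataset
(metrics are maximized; the optimizers minimize).

Two optimizer families are provided with their conventional defaults:

* constriction particle swarm optimization (PSO): phi1 = phi2 = 2.05,
  chi ~ 0.73 from the constriction formula, initial velocity 0.2,
  population 30, 2D-grid neighborhood of range two (torus wrap);
* differential evolution (DE) variants DE/rand/1, DE/best/2 and
  DE/current-to-best/1 with binomial recombination: F = 0.8, CR = 0.6,
  lambda = 0.6, population 30, greedy one-to-one replacement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .assignment import VirtualScreen, normalize_weights
from .chemgraph import MoleculeGraph, ScreeningDataset
from .vsmetrics import RankedList, auc, bedroc

__all__ = [
    "constriction_coefficient",
    "OptimizerConfig",
    "FitnessFunction",
    "VSFitness",
    "fitness_vs",
    "Particle",
    "DEIndividual",
    "pso_step",
    "de_mutate",
    "grid_neighborhoods",
    "OptimizationRun",
    "run_optimization",
]

BOUND = 0.5

DE_VARIANTS = ("rand1", "best2", "current_to_best1")
ALGORITHMS = ("pso",) + tuple(f"de_{v}" for v in DE_VARIANTS)


def constriction_coefficient(phi1: float = 2.05, phi2: float = 2.05) -> float:
    """Clerc constriction factor chi = 2 / |2 - phi - sqrt(phi^2 - 4 phi)|.

    Requires phi = phi1 + phi2 > 4; at the default phi = 4.1 this gives
    chi ~ 0.7298 (0.73 at two decimals).
    """
    phi = phi1 + phi2
    if phi <= 4.0:
        raise ValueError("constriction requires phi1 + phi2 > 4")
    return 2.0 / abs(2.0 - phi - math.sqrt(phi * phi - 4.0 * phi))


@dataclass
class OptimizerConfig:
    """Algorithm choice and hyperparameters for a weight optimization."""

    algorithm: str = "pso"
    population: int = 30
    # PSO
    phi1: float = 2.05
    phi2: float = 2.05
    chi: float | None = None  # None -> constriction formula
    initial_velocity: float = 0.2
    grid_range: int = 2
    # DE
    F: float = 0.8
    CR: float = 0.6
    lam: float = 0.6

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}")
        if self.population < 2:
            raise ValueError("population must be at least 2")

    @property
    def de_variant(self) -> str:
        if not self.algorithm.startswith("de_"):
            raise ValueError(f"{self.algorithm} is not a DE algorithm")
        return self.algorithm[3:]

    def resolved_chi(self) -> float:
        return self.chi if self.chi is not None else constriction_coefficient(self.phi1, self.phi2)


class FitnessFunction:
    """Minimized fitness wrapper with an exact evaluation counter."""

    def __init__(self, func, metric: str = ""):
        self._func = func
        self.metric = metric
        self.n_evaluations = 0

    def __call__(self, raw: np.ndarray) -> float:
        self.n_evaluations += 1
        return float(self._func(raw))


class VSFitness(FitnessFunction):
    """1 - VS metric of the weighted OA ranking on an optimization dataset.

    Deterministic for a fixed dataset and weight vector; the expensive
    pairwise similarity matrices are precomputed once, so each evaluation
    only re-solves the row-scaled assignments and the ranking metric.
    """

    def __init__(self, query: MoleculeGraph, dataset: ScreeningDataset,
                 metric: str = "auc", alpha: float = 53.6,
                 screen: VirtualScreen | None = None):
        metric = metric.lower()
        if metric not in ("auc", "bedroc"):
            raise ValueError("metric must be 'auc' or 'bedroc'")
        if dataset.n_actives == 0 or dataset.n_decoys == 0:
            raise ValueError("optimization dataset needs both actives and decoys")
        super().__init__(self._evaluate, metric=metric)
        self.query = query
        self.dataset = dataset
        self.alpha = alpha
        self.screen = screen if screen is not None else VirtualScreen(query, dataset.molecules)

    def _evaluate(self, raw: np.ndarray) -> float:
        w = normalize_weights(raw)
        scores = self.screen.scores(w)
        ranked = RankedList.from_records(self.dataset.ids, scores, self.dataset.labels)
        value = auc(ranked) if self.metric == "auc" else bedroc(ranked, self.alpha)
        return 1.0 - value


def fitness_vs(raw: np.ndarray, query: MoleculeGraph, dataset: ScreeningDataset,
               metric: str = "auc", alpha: float = 53.6) -> float:
    """One-shot fitness (1 - metric) of a raw weight vector; see VSFitness."""
    return VSFitness(query, dataset, metric=metric, alpha=alpha)(np.asarray(raw, dtype=float))


@dataclass
class Particle:
    """PSO particle: position, velocity, personal and neighborhood bests."""

    position: np.ndarray
    velocity: np.ndarray
    best_position: np.ndarray
    best_fitness: float = math.inf
    nbhd_best: np.ndarray | None = None


@dataclass
class DEIndividual:
    position: np.ndarray
    fitness: float = math.inf


def grid_neighborhoods(population: int, grid_range: int = 2) -> list[np.ndarray]:
    """Torus 2D-grid neighborhood indices (Manhattan range, wrap-around).

    The grid uses the most-square factorization of the population size;
    a prime population degenerates to a 1 x p ring.  Each particle's
    neighborhood includes itself.
    """
    best = (1, population)
    for a in range(2, int(math.isqrt(population)) + 1):
        if population % a == 0:
            best = (a, population // a)
    rows, cols = best
    coords = [(i // cols, i % cols) for i in range(population)]
    hoods = []
    for r, c in coords:
        members = [
            k for k, (rr, cc) in enumerate(coords)
            if (min(abs(rr - r), rows - abs(rr - r))
                + min(abs(cc - c), cols - abs(cc - c))) <= grid_range
        ]
        hoods.append(np.array(members, dtype=np.intp))
    return hoods


def pso_step(swarm: list[Particle], phi1: float, phi2: float, chi: float,
             rng: np.random.Generator) -> list[Particle]:
    """Constriction velocity/position update (in place, synchronous).

    v <- chi [v + r1 phi1 (x^h - x) + r2 phi2 (x^n - x)] with component-wise
    r1, r2 ~ U(0,1); x <- x + v, clipped to the box.  A particle sitting at
    its own personal and neighborhood best with zero velocity stays put.
    """
    if not swarm:
        raise ValueError("empty swarm")
    for p in swarm:
        nbest = p.nbhd_best if p.nbhd_best is not None else p.best_position
        r1 = rng.uniform(size=p.position.shape)
        r2 = rng.uniform(size=p.position.shape)
        p.velocity = chi * (p.velocity
                            + r1 * phi1 * (p.best_position - p.position)
                            + r2 * phi2 * (nbest - p.position))
        p.position = np.clip(p.position + p.velocity, -BOUND, BOUND)
    return swarm


def de_mutate(pop: list[DEIndividual], i: int, variant: str, F: float,
              lam: float, CR: float, rng: np.random.Generator,
              best_index: int | None = None) -> np.ndarray:
    """Build one DE candidate by differential mutation + binomial crossover.

    u_j = x_a,j + F sum_k (x_{r1k},j - x_{r2k},j)  if U(0,1) <= CR or j = j_r
          x_i,j                                     otherwise

    The base vector x_a is a random individual (rand1), the current best
    (best2), or x_i + lambda (x_best - x_i) (current_to_best1).  b = 1
    difference pair for rand1/current_to_best1, b = 2 for best2.  The
    donor indices are mutually exclusive and exclude i; out-of-bounds
    components are repaired by clipping.
    """
    if variant not in DE_VARIANTS:
        raise ValueError(f"unknown DE variant {variant!r}")
    n = len(pop)
    b = 2 if variant == "best2" else 1
    exclude = {i}
    if best_index is None:
        best_index = min(range(n), key=lambda k: pop[k].fitness)
    need = 2 * b + (1 if variant == "rand1" else 0)
    if n - len(exclude) < need:
        raise ValueError(f"population of {n} too small for variant {variant!r}")
    pool = [k for k in range(n) if k not in exclude]
    chosen = rng.choice(len(pool), size=need, replace=False)
    chosen = [pool[k] for k in chosen]
    if variant == "rand1":
        base = pop[chosen[0]].position
        pairs = chosen[1:]
    elif variant == "best2":
        base = pop[best_index].position
        pairs = chosen
    else:  # current_to_best1: arithmetic recombination toward the best
        base = pop[i].position + lam * (pop[best_index].position - pop[i].position)
        pairs = chosen
    diff = np.zeros_like(pop[i].position)
    for k in range(b):
        diff = diff + (pop[pairs[2 * k]].position - pop[pairs[2 * k + 1]].position)
    mutant = base + F * diff
    m = mutant.size
    j_r = int(rng.integers(m))
    take = rng.uniform(size=m) <= CR
    take[j_r] = True
    candidate = np.where(take, mutant, pop[i].position)
    return np.clip(candidate, -BOUND, BOUND)


@dataclass
class OptimizationRun:
    """Reproducible record of one optimization: seed, trace, best solution."""

    seed: int
    config: OptimizerConfig
    best_position: np.ndarray
    best_fitness: float
    trace: np.ndarray  # best-so-far fitness after each evaluation
    n_evaluations: int
    algorithm: str = ""

    @property
    def best_weights(self) -> np.ndarray:
        return normalize_weights(self.best_position)


class _Tracker:
    """Budgeted evaluation loop shared by the optimizers."""

    def __init__(self, fitness, budget: int):
        self.fitness = fitness
        self.budget = budget
        self.trace: list[float] = []
        self.best_fitness = math.inf
        self.best_position: np.ndarray | None = None

    @property
    def exhausted(self) -> bool:
        return len(self.trace) >= self.budget

    def evaluate(self, position: np.ndarray) -> float:
        f = self.fitness(position)
        if f < self.best_fitness:
            self.best_fitness = f
            self.best_position = position.copy()
        self.trace.append(self.best_fitness)
        return f


def run_optimization(fitness, dim: int, config: OptimizerConfig,
                     budget: int, seed: int) -> OptimizationRun:
    """Run the configured optimizer for exactly ``budget`` evaluations.

    ``fitness`` is any callable mapping a raw vector in [-0.5, 0.5]^dim to
    a minimized scalar (e.g. a :class:`VSFitness`).  The run is fully
    reproducible from the seed; the returned trace holds the best-so-far
    fitness after each of the ``budget`` evaluations.
    """
    if budget < config.population:
        raise ValueError("budget must be at least the population size")
    rng = np.random.default_rng(seed)
    tracker = _Tracker(fitness, budget)
    if config.algorithm == "pso":
        _run_pso(tracker, dim, config, rng)
    else:
        _run_de(tracker, dim, config, rng)
    return OptimizationRun(
        seed=seed, config=replace(config), best_position=tracker.best_position,
        best_fitness=tracker.best_fitness, trace=np.array(tracker.trace),
        n_evaluations=len(tracker.trace), algorithm=config.algorithm)


def _run_pso(tracker: _Tracker, dim: int, config: OptimizerConfig,
             rng: np.random.Generator) -> None:
    pop = config.population
    chi = config.resolved_chi()
    hoods = grid_neighborhoods(pop, config.grid_range)
    swarm = [
        Particle(position=rng.uniform(-BOUND, BOUND, dim),
                 velocity=rng.uniform(-config.initial_velocity, config.initial_velocity, dim),
                 best_position=np.zeros(dim))
        for _ in range(pop)
    ]
    for p in swarm:
        p.best_position = p.position.copy()
    while not tracker.exhausted:
        for p in swarm:  # synchronous evaluation sweep
            if tracker.exhausted:
                break
            f = tracker.evaluate(p.position)
            if f < p.best_fitness:
                p.best_fitness = f
                p.best_position = p.position.copy()
        if tracker.exhausted:
            break
        for k, p in enumerate(swarm):
            members = hoods[k]
            j = min(members, key=lambda idx: (swarm[idx].best_fitness, idx))
            p.nbhd_best = swarm[j].best_position
        pso_step(swarm, config.phi1, config.phi2, chi, rng)


def _run_de(tracker: _Tracker, dim: int, config: OptimizerConfig,
            rng: np.random.Generator) -> None:
    variant = config.de_variant
    pop = [DEIndividual(position=rng.uniform(-BOUND, BOUND, dim)) for _ in range(config.population)]
    for ind in pop:
        if tracker.exhausted:
            return
        ind.fitness = tracker.evaluate(ind.position)
    while not tracker.exhausted:
        best_index = min(range(len(pop)), key=lambda k: (pop[k].fitness, k))
        for i in range(len(pop)):
            if tracker.exhausted:
                return
            candidate = de_mutate(pop, i, variant, config.F, config.lam,
                                  config.CR, rng, best_index=best_index)
            f = tracker.evaluate(candidate)
            if f <= pop[i].fitness:  # greedy one-to-one replacement
                pop[i] = DEIndividual(position=candidate, fitness=f)
                if f < pop[best_index].fitness:
                    best_index = i
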