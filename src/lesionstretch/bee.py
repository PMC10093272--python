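"""Artificial-bee-colony phase of the hybrid optimizer.

Karaboga's swarm scheme over "food sources" (candidate parameter
vectors).  Each iteration runs three passes:

* employed bees: every source spawns a single-component mutant against a
  random partner and is replaced only on strict fitness improvement;
* onlooker bees: sources are revisited with probability proportional to
  a floored fitness ratio, spending one mutation budget per visit until
  the colony size is exhausted;
* scout bee: at most one stagnant source (trial counter past the limit)
  is replaced by a fresh uniform draw, with no greedy comparison.

The raw cost handed to the fitness map follows the minimization
convention, C = -CF, so larger quality values yield larger fitness
(fitness = 1 + CF for positive CF).  The global best is tracked across
every evaluation, so the best-so-far trace never decreases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bat import init_population
from .local_transform import ParameterBounds

__all__ = [
    "FoodSource",
    "ABCConfig",
    "ColonyState",
    "to_fitness",
    "mutate_source",
    "greedy_select",
    "selection_probability",
    "scout_replace",
    "run_abc",
]


def to_fitness(c: float) -> float:
    """Map a minimization-convention cost C to a positive fitness.

    1 + |C| for negative C, 1 / (1 + C) otherwise; strictly decreasing
    in C, hence strictly increasing in the quality value CF = -C.
    """
    return 1.0 + abs(c) if c < 0 else 1.0 / (1.0 + c)


@dataclass
class FoodSource:
    """One candidate solution with its quality, fitness and failure count."""

    position: np.ndarray
    cf: float  # maximized quality value
    fitness: float  # to_fitness(-cf)
    trial: int = 0

    @classmethod
    def evaluate(cls, position: np.ndarray, objective) -> "FoodSource":
        cf = float(objective(position))
        return cls(position=position.copy(), cf=cf, fitness=to_fitness(-cf))


@dataclass(frozen=True)
class ABCConfig:
    colony_size: int | None = None  # None: inherit the handed-over population
    limit: int = 20  # trial threshold triggering the scout
    n_iterations: int = 30

    def __post_init__(self) -> None:
        if self.colony_size is not None and self.colony_size < 2:
            raise ValueError("colony size must be at least 2")
        if self.limit < 1:
            raise ValueError("trial limit must be at least 1")
        if self.n_iterations < 0:
            raise ValueError("iteration count must be non-negative")


@dataclass
class ColonyState:
    """Colony plus the running global optimum and its trace."""

    sources: list[FoodSource]
    best_position: np.ndarray
    best_cf: float
    iteration: int
    trace: list[float] = field(default_factory=list)
    n_evaluations: int = 0

    def observe(self, position: np.ndarray, cf: float) -> None:
        self.n_evaluations += 1
        if cf > self.best_cf:
            self.best_cf = cf
            self.best_position = position.copy()


def mutate_source(
    position: np.ndarray,
    partner: np.ndarray,
    u: int,
    theta: float,
    bounds: ParameterBounds,
) -> np.ndarray:
    """Single-component mutation X_u + theta * (X_u - partner_u), clipped."""
    position = np.asarray(position, dtype=float)
    partner = np.asarray(partner, dtype=float)
    if not 0 <= u < position.size:
        raise ValueError(f"dimension index {u} out of range")
    child = position.copy()
    child[u] = position[u] + theta * (position[u] - partner[u])
    return bounds.clip(child)


def greedy_select(parent: FoodSource, child: FoodSource) -> FoodSource:
    """Strict selection: the child survives only with strictly higher
    fitness (trial reset); ties and losses keep the parent and bump its
    trial counter."""
    if child.fitness > parent.fitness:
        child.trial = 0
        return child
    parent.trial += 1
    return parent


def selection_probability(fitnesses) -> np.ndarray:
    """Floored fitness-proportional visiting probabilities in [0.1, 1]."""
    fitnesses = np.asarray(fitnesses, dtype=float)
    if fitnesses.size == 0:
        raise ValueError("at least one food source required")
    return 0.1 + 0.9 * fitnesses / fitnesses.max()


def scout_replace(
    state: ColonyState,
    objective,
    bounds: ParameterBounds,
    config: ABCConfig,
    rng: np.random.Generator,
) -> None:
    """Replace (at most) the single most-stagnant source past the limit.

    The replacement is a fresh uniform draw evaluated without greedy
    comparison; ties on the trial count break towards the lowest index.
    """
    trials = [s.trial for s in state.sources]
    worst = int(np.argmax(trials))
    if trials[worst] <= config.limit:
        return
    position = bounds.lower + rng.random(bounds.dimension) * bounds.span
    fresh = FoodSource.evaluate(position, objective)
    state.sources[worst] = fresh
    state.observe(fresh.position, fresh.cf)


def _mutation_step(
    state: ColonyState,
    v: int,
    objective,
    bounds: ParameterBounds,
    rng: np.random.Generator,
) -> None:
    """One employed/onlooker exploitation of source v."""
    sources = state.sources
    partner = int(rng.integers(len(sources) - 1))
    if partner >= v:
        partner += 1
    u = int(rng.integers(bounds.dimension))
    theta = float(rng.uniform(-1.0, 1.0))
    child_pos = mutate_source(
        sources[v].position, sources[partner].position, u, theta, bounds
    )
    child = FoodSource.evaluate(child_pos, objective)
    state.observe(child.position, child.cf)
    sources[v] = greedy_select(sources[v], child)


def run_abc(
    objective,
    initial_population: np.ndarray,
    bounds: ParameterBounds,
    config: ABCConfig | None = None,
    rng: np.random.Generator | None = None,
    initial_best: tuple[np.ndarray, float] | None = None,
) -> ColonyState:
    """Run the colony; returns the final state with its best-so-far trace.

    ``objective`` maps a parameter vector to the maximized quality value.
    ``initial_best`` seeds the cross-phase optimum (elitism) so a chained
    run can never lose the preceding phase's best.
    """
    config = config or ABCConfig()
    rng = rng if rng is not None else np.random.default_rng()

    positions = np.atleast_2d(np.asarray(initial_population, dtype=float))
    if config.colony_size is not None and config.colony_size != positions.shape[0]:
        if config.colony_size < positions.shape[0]:
            positions = positions[: config.colony_size]
        else:
            extra = init_population(
                bounds, max(config.colony_size - positions.shape[0], 2), rng
            )
            positions = np.vstack([positions, extra])[: config.colony_size]
    if positions.shape[0] < 2:
        raise ValueError("colony size must be at least 2")

    sources = [FoodSource.evaluate(pos, objective) for pos in positions]
    best_idx = int(np.argmax([s.cf for s in sources]))
    best_position = sources[best_idx].position.copy()
    best_cf = sources[best_idx].cf
    if initial_best is not None and initial_best[1] > best_cf:
        best_position = np.asarray(initial_best[0], dtype=float).copy()
        best_cf = float(initial_best[1])
    state = ColonyState(
        sources=sources,
        best_position=best_position,
        best_cf=best_cf,
        iteration=0,
        n_evaluations=len(sources),
    )
    state.trace.append(state.best_cf)

    n = len(sources)
    for it in range(1, config.n_iterations + 1):
        for v in range(n):
            _mutation_step(state, v, objective, bounds, rng)
        probabilities = selection_probability([s.fitness for s in sources])
        visits, v = 0, 0
        while visits < n:
            if rng.random() < probabilities[v]:
                _mutation_step(state, v, objective, bounds, rng)
                visits += 1
            v = (v + 1) % n
        scout_replace(state, objective, bounds, config, rng)
        state.iteration = it
        state.trace.append(state.best_cf)

    return state
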