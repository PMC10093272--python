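"""Bat-algorithm phase of the hybrid optimizer.

Echolocation-inspired population search (Yang's scheme): each agent
("bat") carries a position in parameter space, a velocity, a frequency
drawn per move, a loudness that decays on every accepted improvement and
a pulse rate that grows towards its initial ceiling.  Per iteration each
bat

1. moves with a frequency-scaled velocity update pulled against the
   global best,
2. with probability (1 - pulse rate) replaces its candidate by a random
   walk around the global best scaled by the swarm's average loudness,
3. keeps the candidate only if it improves the bat's own cost AND a
   uniform draw falls below its loudness (simulated-annealing-like
   acceptance).

Loudness decays and pulse rate grows on a per-iteration schedule for
every bat, mirroring the temperature schedule of simulated annealing:
the decaying average loudness shrinks the random-walk radius
geometrically, which is what lets the swarm refine the optimum late in
the run instead of only exploring.

The global best is updated greedily after every objective evaluation, so
the best-so-far trace is non-decreasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .local_transform import ParameterBounds

__all__ = [
    "Bat",
    "BatConfig",
    "SwarmState",
    "init_population",
    "bat_move",
    "local_random_walk",
    "update_loudness_pulse",
    "run_bat",
]


@dataclass
class Bat:
    """One search agent."""

    position: np.ndarray
    velocity: np.ndarray
    frequency: float
    loudness: float
    pulse_rate: float
    cost: float


@dataclass(frozen=True)
class BatConfig:
    freq_min: float = 0.0
    freq_max: float = 2.0
    loudness_init: float = 1.0
    loudness_decay: float = 0.9  # epsilon in the loudness schedule
    pulse_init: float = 0.5  # pulse-rate ceiling phi0
    pulse_growth: float = 0.9  # eta in the pulse schedule
    n_bats: int = 20
    n_iterations: int = 30

    def __post_init__(self) -> None:
        if self.freq_min > self.freq_max:
            raise ValueError("freq_min must not exceed freq_max")
        if not 0.0 <= self.loudness_decay <= 1.0:
            raise ValueError("loudness decay must lie in [0, 1]")
        if self.pulse_growth <= 0.0:
            raise ValueError("pulse growth rate must be positive")
        if self.n_bats < 2:
            raise ValueError("need at least 2 bats")
        if self.n_iterations < 0:
            raise ValueError("iteration count must be non-negative")


@dataclass
class SwarmState:
    """Population plus the running global optimum and its trace."""

    bats: list[Bat]
    best_position: np.ndarray
    best_cost: float
    iteration: int
    trace: list[float] = field(default_factory=list)
    n_evaluations: int = 0

    def observe(self, position: np.ndarray, cost: float) -> None:
        """Register one objective evaluation; keeps the best greedily."""
        self.n_evaluations += 1
        if cost > self.best_cost:
            self.best_cost = cost
            self.best_position = position.copy()


def init_population(
    bounds: ParameterBounds, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform draws lower + U(0,1) * (upper - lower), one row per agent."""
    if n < 2:
        raise ValueError("population size must be at least 2")
    return bounds.lower + rng.random((n, bounds.dimension)) * bounds.span


def bat_move(
    bat: Bat,
    best: np.ndarray,
    bounds: ParameterBounds,
    config: BatConfig,
    phi: float,
) -> Bat:
    """Frequency/velocity/position update towards the global best.

    phi in (0, 1) interpolates the frequency between freq_min and
    freq_max; the returned bat has the moved (bounds-clipped) position
    and the persisted velocity, with cost not yet re-evaluated.
    """
    frequency = config.freq_min + phi * (config.freq_max - config.freq_min)
    velocity = bat.velocity + frequency * (bat.position - best)
    position = bounds.clip(bat.position + velocity)
    return replace(bat, position=position, velocity=velocity, frequency=frequency)


def local_random_walk(
    position: np.ndarray,
    avg_loudness: float,
    theta,
    bounds: ParameterBounds,
) -> np.ndarray:
    """Step of at most the average loudness per component, then clip."""
    theta = np.asarray(theta, dtype=float)
    if np.any(np.abs(theta) > 1.0):
        raise ValueError("theta components must lie in [-1, 1]")
    return bounds.clip(position + theta * avg_loudness)


def update_loudness_pulse(bat: Bat, config: BatConfig, tau: int) -> Bat:
    """Cooling schedules: loudness decays geometrically, pulse rate
    rises as phi0 * (1 - exp(-eta * tau)); applied once per iteration."""
    return replace(
        bat,
        loudness=config.loudness_decay * bat.loudness,
        pulse_rate=config.pulse_init * (1.0 - np.exp(-config.pulse_growth * tau)),
    )


def run_bat(
    objective,
    bounds: ParameterBounds,
    config: BatConfig | None = None,
    rng: np.random.Generator | None = None,
    initial_population: np.ndarray | None = None,
) -> SwarmState:
    """Run the bat phase; returns the final swarm with its best-so-far trace.

    ``objective`` maps a parameter vector to the (maximized) quality
    value.  ``initial_population`` overrides the random initialization,
    e.g. to chain phases.
    """
    config = config or BatConfig()
    rng = rng if rng is not None else np.random.default_rng()

    if initial_population is None:
        positions = init_population(bounds, config.n_bats, rng)
    else:
        positions = np.atleast_2d(np.asarray(initial_population, dtype=float))
        if positions.shape[0] < 2:
            raise ValueError("population size must be at least 2")

    bats = [
        Bat(
            position=pos.copy(),
            velocity=np.zeros_like(pos),
            frequency=config.freq_min,
            loudness=config.loudness_init,
            pulse_rate=0.0,  # the tau=0 value of the pulse schedule
            cost=float(objective(pos)),
        )
        for pos in positions
    ]
    best_idx = int(np.argmax([b.cost for b in bats]))
    state = SwarmState(
        bats=bats,
        best_position=bats[best_idx].position.copy(),
        best_cost=bats[best_idx].cost,
        iteration=0,
        n_evaluations=len(bats),
    )
    state.trace.append(state.best_cost)

    for tau in range(1, config.n_iterations + 1):
        avg_loudness = float(np.mean([b.loudness for b in bats]))
        for j, bat in enumerate(bats):
            moved = bat_move(bat, state.best_position, bounds, config, rng.random())
            candidate = moved.position
            if rng.random() > bat.pulse_rate:
                theta = rng.uniform(-1.0, 1.0, size=bounds.dimension)
                candidate = local_random_walk(
                    state.best_position, avg_loudness, theta, bounds
                )
            cost = float(objective(candidate))
            state.observe(candidate, cost)
            if cost > bat.cost and rng.random() < bat.loudness:
                moved = replace(moved, position=candidate, cost=cost)
            else:
                # Move rejected: keep the old position and cost, but the
                # velocity and frequency persist (velocity is never clipped).
                moved = replace(moved, position=bat.position, cost=bat.cost)
            bats[j] = update_loudness_pulse(moved, config, tau)
        state.iteration = tau
        state.trace.append(state.best_cost)

    return state
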