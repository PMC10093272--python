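"""Artificial-bee-colony mechanics: fitness map, mutation, selection, scouts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lesionstretch.bee import (
    ABCConfig,
    ColonyState,
    FoodSource,
    greedy_select,
    mutate_source,
    run_abc,
    scout_replace,
    selection_probability,
    to_fitness,
)
from lesionstretch.bat import init_population
from lesionstretch.local_transform import DEFAULT_BOUNDS


class TestToFitness:
    @pytest.mark.parametrize(
        "cost, expected", [(0.0, 1.0), (3.0, 0.25), (-2.0, 3.0)]
    )
    def test_reference_values(self, cost, expected):
        assert to_fitness(cost) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=60)
    @given(st.floats(-50, 50), st.floats(0.001, 10))
    def test_strictly_increasing_in_quality(self, cf, delta):
        # under the C = -CF convention, better quality -> larger fitness
        assert to_fitness(-(cf + delta)) > to_fitness(-cf)


class TestMutateSource:
    def test_zero_theta_returns_parent(self):
        x = np.array([0.5, 0.1, 0.2, 1.0])
        partner = np.array([1.0, 0.3, 0.6, 0.7])
        np.testing.assert_array_equal(
            mutate_source(x, partner, 2, 0.0, DEFAULT_BOUNDS), x
        )

    def test_single_component_changes(self):
        x = np.array([0.5, 0.1, 0.2, 1.0])
        partner = np.array([1.0, 0.3, 0.6, 0.7])
        child = mutate_source(x, partner, 1, 0.5, DEFAULT_BOUNDS)
        assert np.count_nonzero(child != x) <= 1
        assert child[1] == pytest.approx(0.1 + 0.5 * (0.1 - 0.3))

    def test_equal_components_give_identical_child(self):
        x = np.array([0.5, 0.1, 0.2, 1.0])
        partner = x.copy()
        for theta in (-1.0, 0.3, 1.0):
            np.testing.assert_array_equal(
                mutate_source(x, partner, 3, theta, DEFAULT_BOUNDS), x
            )

    def test_bad_dimension_rejected(self):
        with pytest.raises(ValueError):
            mutate_source(np.zeros(4), np.ones(4), 4, 0.5, DEFAULT_BOUNDS)


class TestGreedySelect:
    def _source(self, fitness, trial=0):
        return FoodSource(
            position=np.zeros(4), cf=0.0, fitness=fitness, trial=trial
        )

    def test_better_child_kept_with_trial_reset(self):
        kept = greedy_select(self._source(0.5, trial=3), self._source(0.9))
        assert kept.fitness == 0.9 and kept.trial == 0

    def test_worse_child_increments_parent_trial(self):
        parent = self._source(0.5, trial=3)
        kept = greedy_select(parent, self._source(0.4))
        assert kept is parent and kept.trial == 4

    def test_tie_keeps_parent(self):
        parent = self._source(0.5, trial=0)
        kept = greedy_select(parent, self._source(0.5))
        assert kept is parent and kept.trial == 1


class TestSelectionProbability:
    def test_best_member_probability_one(self):
        probs = selection_probability([0.2, 0.8, 0.4])
        assert probs[1] == pytest.approx(1.0)

    def test_all_equal_all_one(self):
        np.testing.assert_allclose(selection_probability([0.3, 0.3, 0.3]), 1.0)

    def test_floor_at_point_one(self):
        probs = selection_probability([1e-9, 1.0])
        assert np.all(probs >= 0.1)


class TestScoutReplace:
    def _state(self, trials):
        sources = [
            FoodSource(position=np.full(4, 0.5), cf=1.0, fitness=2.0, trial=t)
            for t in trials
        ]
        return ColonyState(
            sources=sources,
            best_position=np.full(4, 0.5),
            best_cf=1.0,
            iteration=0,
        )

    def test_no_source_above_limit_unchanged(self):
        state = self._state([0, 3, 5])
        before = [s.position.copy() for s in state.sources]
        scout_replace(
            state, lambda x: 0.0, DEFAULT_BOUNDS, ABCConfig(limit=5), np.random.default_rng(0)
        )
        for prev, src in zip(before, state.sources):
            np.testing.assert_array_equal(prev, src.position)

    def test_single_replacement_resets_trial(self):
        state = self._state([0, 6, 2])
        scout_replace(
            state, lambda x: 0.0, DEFAULT_BOUNDS, ABCConfig(limit=5), np.random.default_rng(1)
        )
        replaced = state.sources[1]
        assert replaced.trial == 0
        assert np.all(replaced.position >= DEFAULT_BOUNDS.lower)
        assert np.all(replaced.position <= DEFAULT_BOUNDS.upper)

    def test_tie_breaks_to_lowest_index(self):
        state = self._state([7, 7, 2])
        scout_replace(
            state, lambda x: 0.0, DEFAULT_BOUNDS, ABCConfig(limit=5), np.random.default_rng(2)
        )
        assert state.sources[0].trial == 0  # replaced
        assert state.sources[1].trial == 7  # untouched this iteration


def _sphere_objective(center):
    return lambda x: -float(np.sum((np.asarray(x) - center) ** 2))


class TestRunAbc:
    def test_zero_iterations_returns_best_of_initial_population(self):
        objective = _sphere_objective(DEFAULT_BOUNDS.lower + 0.5 * DEFAULT_BOUNDS.span)
        pop = init_population(DEFAULT_BOUNDS, 8, np.random.default_rng(0))
        state = run_abc(objective, pop, DEFAULT_BOUNDS, ABCConfig(n_iterations=0))
        assert state.best_cf == pytest.approx(max(s.cf for s in state.sources))

    @pytest.mark.parametrize("seed", range(5))
    def test_best_so_far_trace_non_decreasing(self, seed):
        objective = _sphere_objective(DEFAULT_BOUNDS.lower + 0.3 * DEFAULT_BOUNDS.span)
        rng = np.random.default_rng(seed)
        pop = init_population(DEFAULT_BOUNDS, 8, rng)
        state = run_abc(objective, pop, DEFAULT_BOUNDS, ABCConfig(n_iterations=15), rng)
        assert all(b >= a for a, b in zip(state.trace, state.trace[1:]))

    def test_initial_best_is_elitist(self):
        objective = _sphere_objective(DEFAULT_BOUNDS.lower + 0.5 * DEFAULT_BOUNDS.span)
        pop = init_population(DEFAULT_BOUNDS, 5, np.random.default_rng(3))
        carried = (np.full(4, 99.0), 1e9)  # unbeatable phase-one optimum
        state = run_abc(
            objective,
            pop,
            DEFAULT_BOUNDS,
            ABCConfig(n_iterations=3),
            np.random.default_rng(3),
            initial_best=carried,
        )
        assert state.best_cf == pytest.approx(1e9)

    def test_fixed_seed_identical_trajectory(self):
        objective = _sphere_objective(DEFAULT_BOUNDS.lower + 0.4 * DEFAULT_BOUNDS.span)
        pop = init_population(DEFAULT_BOUNDS, 6, np.random.default_rng(4))
        a = run_abc(objective, pop, DEFAULT_BOUNDS, ABCConfig(n_iterations=10),
                    np.random.default_rng(7))
        b = run_abc(objective, pop, DEFAULT_BOUNDS, ABCConfig(n_iterations=10),
                    np.random.default_rng(7))
        np.testing.assert_array_equal(a.best_position, b.best_position)
        assert a.trace == b.trace

    def test_positions_and_fitness_invariants(self):
        objective = _sphere_objective(DEFAULT_BOUNDS.lower + 0.6 * DEFAULT_BOUNDS.span)
        rng = np.random.default_rng(5)
        pop = init_population(DEFAULT_BOUNDS, 6, rng)
        state = run_abc(objective, pop, DEFAULT_BOUNDS, ABCConfig(n_iterations=10), rng)
        for source in state.sources:
            assert source.fitness > 0
            assert source.trial >= 0
            assert np.all(source.position >= DEFAULT_BOUNDS.lower)
            assert np.all(source.position <= DEFAULT_BOUNDS.upper)
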