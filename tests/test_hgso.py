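import math

import numpy as np
import pytest

from mafcnn import hgso as hg


def sphere(x):
    return float(np.sum(x * x))


@pytest.fixture
def small_config():
    return hg.HGSOConfig(population_size=8, n_clusters=2, max_iter=10, seed=0)


@pytest.fixture
def unit_bounds():
    return hg.SearchBounds([0.0, 0.0], [1.0, 1.0])


class TestInitialisation:
    def test_positions_in_bounds_and_shared_henry(self, small_config,
                                                  unit_bounds):
        state = hg.initialize_population(unit_bounds, small_config,
                                         np.random.default_rng(0))
        assert state.positions.shape == (8, 2)
        assert np.all((state.positions >= 0) & (state.positions <= 1))
        assert state.henry.size == 2
        # every agent of a cluster shares its H_j
        assert len(np.unique(state.henry[state.cluster_of])) == 2

    def test_degenerate_draws_match_init_constants(self, small_config,
                                                   unit_bounds, stub_rng):
        state = hg.initialize_population(unit_bounds, small_config,
                                         stub_rng(0.5))
        np.testing.assert_allclose(state.henry, 0.025)        # l1/2
        np.testing.assert_allclose(state.cluster_const, 0.005)  # l3/2
        np.testing.assert_allclose(state.pressure, 50.0)      # l2/2

    def test_same_seed_identical(self, small_config, unit_bounds):
        a = hg.initialize_population(unit_bounds, small_config,
                                     np.random.default_rng(3))
        b = hg.initialize_population(unit_bounds, small_config,
                                     np.random.default_rng(3))
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.henry, b.henry)

    def test_indivisible_clustering_rejected(self):
        with pytest.raises(ValueError):
            hg.HGSOConfig(population_size=10, n_clusters=3)


class TestRanking:
    def _state(self, fitness, n_clusters):
        n = len(fitness)
        cfg = hg.HGSOConfig(population_size=n, n_clusters=n_clusters)
        state = hg.initialize_population(
            hg.SearchBounds([0.0], [1.0]), cfg, np.random.default_rng(0))
        state.fitness = np.array(fitness, dtype=float)
        return state

    def test_single_cluster_best_is_global_best(self):
        state = self._state([4.0, 2.0, 3.0, 5.0], 1)
        cluster_best, global_best = hg.rank_and_select_best(state)
        assert cluster_best.tolist() == [1]
        assert global_best == 1

    def test_two_cluster_enumeration(self):
        state = self._state([3.0, 1.0, 2.0, 5.0, 0.0, 9.0], 2)
        cluster_best, global_best = hg.rank_and_select_best(state)
        assert state.fitness[cluster_best[0]] == 1.0
        assert state.fitness[cluster_best[1]] == 0.0
        assert global_best == 4

    def test_ties_break_to_lowest_index(self):
        state = self._state([2.0, 2.0, 2.0, 2.0], 2)
        cluster_best, global_best = hg.rank_and_select_best(state)
        assert cluster_best.tolist() == [0, 2]
        assert global_best == 0


class TestHenryAndSolubility:
    def test_henry_strictly_decreases(self, small_config, unit_bounds):
        state = hg.initialize_population(unit_bounds, small_config,
                                         np.random.default_rng(1))
        for t in range(1, small_config.max_iter + 1):
            before = state.henry.copy()
            hg.update_henry_coefficient(state, t, small_config)
            assert np.all(state.henry < before)

    def test_zero_cluster_constant_keeps_henry(self, small_config,
                                               unit_bounds):
        state = hg.initialize_population(unit_bounds, small_config,
                                         np.random.default_rng(1))
        state.cluster_const = np.zeros_like(state.cluster_const)
        before = state.henry.copy()
        hg.update_henry_coefficient(state, 5, small_config)
        np.testing.assert_array_equal(state.henry, before)

    def test_final_iteration_scalar_oracle(self, unit_bounds, stub_rng):
        cfg = hg.HGSOConfig(population_size=4, n_clusters=1, max_iter=10)
        state = hg.initialize_population(unit_bounds, cfg, stub_rng(0.5))
        hg.update_henry_coefficient(state, cfg.max_iter, cfg)
        expected = 0.025 * math.exp(-0.005 * (math.e - 1.0 / 298.0))
        np.testing.assert_allclose(state.henry, expected, rtol=1e-15)

    def test_iteration_out_of_range(self, small_config, unit_bounds):
        state = hg.initialize_population(unit_bounds, small_config,
                                         np.random.default_rng(0))
        with pytest.raises(ValueError):
            hg.update_henry_coefficient(state, 0, small_config)

    def test_solubility_product_and_linearity(self, unit_bounds, stub_rng):
        cfg = hg.HGSOConfig(population_size=4, n_clusters=1, K=1.0)
        state = hg.initialize_population(unit_bounds, cfg, stub_rng(0.5))
        s = hg.update_solubility(state, cfg)
        np.testing.assert_allclose(s, 1.25)           # 1 * 0.025 * 50
        cfg3 = hg.HGSOConfig(population_size=4, n_clusters=1, K=3.0)
        np.testing.assert_allclose(hg.update_solubility(state, cfg3), 3.75)
        state.pressure[:] = 0.0
        np.testing.assert_allclose(hg.update_solubility(state, cfg), 0.0)


class TestPositionUpdate:
    def test_fixed_point_agent_does_not_move(self, stub_rng):
        cfg = hg.HGSOConfig(population_size=4, n_clusters=1)
        bounds = hg.SearchBounds([-1.0, -1.0], [1.0, 1.0])
        state = hg.initialize_population(bounds, cfg, np.random.default_rng(0))
        best = np.array([0.5, -0.5])
        state.positions[:] = best
        state.fitness[:] = 1.0
        state.solubility[:] = 1.0   # S * x_best == x == cluster best
        new = hg.update_positions(state, np.tile(best, (4, 1)), best, 1.0,
                                  cfg, stub_rng(0.5))
        np.testing.assert_allclose(new, state.positions, atol=1e-15)

    def test_zero_random_draws_freeze_positions(self, stub_rng):
        cfg = hg.HGSOConfig(population_size=4, n_clusters=1)
        bounds = hg.SearchBounds([-1.0, -1.0], [1.0, 1.0])
        state = hg.initialize_population(bounds, cfg, np.random.default_rng(2))
        state.fitness[:] = [1.0, 2.0, 3.0, 4.0]
        state.solubility[:] = 0.3
        new = hg.update_positions(state, state.positions.copy(),
                                  state.positions[0], 1.0, cfg, stub_rng(0.0))
        np.testing.assert_array_equal(new, state.positions)

    def test_single_step_matches_hand_computation(self, stub_rng):
        # one 2-D agent step with every draw stubbed to 0.5 and flag +1
        cfg = hg.HGSOConfig(population_size=4, n_clusters=1, beta=1.0,
                            alpha=1.0, epsilon=0.05)
        bounds = hg.SearchBounds([-2.0, -2.0], [2.0, 2.0])
        state = hg.initialize_population(bounds, cfg, np.random.default_rng(0))
        x = np.array([[0.4, -0.2]] * 4)
        state.positions = x.copy()
        state.fitness = np.array([2.0, 3.0, 4.0, 5.0])
        state.solubility = np.array([0.8, 0.8, 0.8, 0.8])
        cluster_best = np.array([[1.0, 1.0]] * 4)
        global_best = np.array([-1.0, 0.5])
        f_best = 1.0
        new = hg.update_positions(state, cluster_best, global_best, f_best,
                                  cfg, stub_rng(0.5))
        for i in range(4):
            gamma = 1.0 * math.exp(-(f_best + 0.05)
                                   / (state.fitness[i] + 0.05))
            for d in range(2):
                step = (1.0 * 0.5 * gamma * (cluster_best[i, d] - x[i, d])
                        + 1.0 * 0.5 * 1.0 * (0.8 * global_best[d] - x[i, d]))
                assert new[i, d] == pytest.approx(x[i, d] + step, abs=1e-15)


class TestWorstAgents:
    @pytest.mark.parametrize("draw,expected", [(0.5, 4), (0.0, 3), (1.0, 6)])
    def test_count_bounds_and_rounding(self, draw, expected, stub_rng):
        cfg = hg.HGSOConfig(population_size=30, n_clusters=5)
        assert hg.count_worst_agents(30, cfg, stub_rng(draw)) == expected

    def test_count_always_in_fraction_band(self, rng):
        cfg = hg.HGSOConfig(population_size=30, n_clusters=5)
        for _ in range(200):
            nw = hg.count_worst_agents(30, cfg, rng)
            assert 3 <= nw <= 6

    def test_reinitialise_moves_exactly_the_worst(self, unit_bounds):
        cfg = hg.HGSOConfig(population_size=4, n_clusters=1)
        state = hg.initialize_population(unit_bounds, cfg,
                                         np.random.default_rng(0))
        before = state.positions.copy()
        state.fitness = np.array([1.0, 9.0, 3.0, 7.0])
        moved = hg.reinitialize_worst(state, 2, unit_bounds,
                                      np.random.default_rng(1))
        assert sorted(moved.tolist()) == [1, 3]
        np.testing.assert_array_equal(state.positions[[0, 2]], before[[0, 2]])
        assert np.all((state.positions >= 0) & (state.positions <= 1))

    def test_zero_and_full_reinitialisation(self, unit_bounds):
        cfg = hg.HGSOConfig(population_size=4, n_clusters=1)
        state = hg.initialize_population(unit_bounds, cfg,
                                         np.random.default_rng(0))
        before = state.positions.copy()
        state.fitness = np.arange(4.0)
        assert hg.reinitialize_worst(state, 0, unit_bounds,
                                     np.random.default_rng(0)).size == 0
        np.testing.assert_array_equal(state.positions, before)
        hg.reinitialize_worst(state, 4, unit_bounds, np.random.default_rng(0))
        assert np.all((state.positions >= 0) & (state.positions <= 1))
        with pytest.raises(ValueError):
            hg.reinitialize_worst(state, 5, unit_bounds,
                                  np.random.default_rng(0))


class TestMinimise:
    def test_constant_objective_found_immediately(self):
        cfg = hg.HGSOConfig(population_size=4, n_clusters=1, max_iter=3,
                            seed=0)
        res = hg.hgso_minimize(lambda x: 7.5, hg.SearchBounds([0.0], [1.0]),
                               cfg)
        assert res.best_fitness == 7.5
        assert res.history[0] == 7.5

    def test_history_length_and_monotonicity(self):
        cfg = hg.HGSOConfig(population_size=8, n_clusters=2, max_iter=25,
                            seed=1)
        res = hg.hgso_minimize(sphere, hg.SearchBounds([-5, -5], [5, 5]), cfg)
        assert res.history.size == 25
        assert np.all(np.diff(res.history) <= 0)

    def test_sphere_converges(self):
        cfg = hg.HGSOConfig(population_size=30, n_clusters=5, max_iter=200,
                            seed=0)
        res = hg.hgso_minimize(sphere, hg.SearchBounds([-5, -5], [5, 5]), cfg)
        assert res.best_fitness <= 1e-2
        np.testing.assert_allclose(res.best_position, 0.0, atol=0.1)

    def test_deterministic_given_seed(self):
        cfg = hg.HGSOConfig(population_size=8, n_clusters=2, max_iter=20,
                            seed=5)
        a = hg.hgso_minimize(sphere, hg.SearchBounds([-5, -5], [5, 5]), cfg)
        b = hg.hgso_minimize(sphere, hg.SearchBounds([-5, -5], [5, 5]), cfg)
        np.testing.assert_array_equal(a.history, b.history)
        np.testing.assert_array_equal(a.best_position, b.best_position)

    def test_nonfinite_objective_reported_with_context(self):
        cfg = hg.HGSOConfig(population_size=4, n_clusters=1, max_iter=2,
                            seed=0)
        with pytest.raises(ValueError, match="agent"):
            hg.hgso_minimize(lambda x: float("nan"),
                             hg.SearchBounds([0.0], [1.0]), cfg)


class TestHyperparameterSpace:
    def test_integer_dimension_rounds_to_nearest(self):
        dim = hg.Dimension("batch_size", "integer", 2, 64)
        assert dim.decode(4.7) == 5
        assert dim.decode(4.2) == 4

    def test_log_dimension_bounds(self):
        dim = hg.Dimension("lr0", "continuous", 1e-4, 1e-1, log=True)
        lo, hi = dim.bounds
        assert dim.decode(lo) == pytest.approx(1e-4)
        assert dim.decode(hi) == pytest.approx(1e-1)

    def test_round_trip_identity_on_representable_grid(self):
        space = hg.default_hyperparameter_space()
        for lr in (1e-4, 1e-3, 1e-2, 1e-1):
            for batch in (2, 5, 33, 64):
                settings = {"lr0": lr, "batch_size": batch, "epochs": 25,
                            "dropout": 0.5}
                decoded = space.decode(space.encode(settings))
                assert decoded["lr0"] == pytest.approx(lr, rel=1e-12)
                assert decoded["batch_size"] == batch
                assert decoded["epochs"] == 25
                assert decoded["dropout"] == pytest.approx(0.5)

    def test_out_of_bounds_position_rejected(self):
        space = hg.default_hyperparameter_space()
        bad = space.bounds.upper + 1.0
        with pytest.raises(ValueError):
            space.decode(bad)


class TestFitness:
    @pytest.mark.parametrize("wrong,expected", [(0, 0.0), (2, 20.0),
                                                (10, 100.0)])
    def test_misclassification_percentage(self, wrong, expected):
        y_true = np.zeros(10, dtype=int)
        y_pred = np.zeros(10, dtype=int)
        y_pred[:wrong] = 1
        assert hg.misclassification_rate(y_true, y_pred) == expected
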