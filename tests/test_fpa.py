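import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csfpa.fpa import (
    FpaConfig,
    SearchBounds,
    global_pollination_step,
    levy_sample,
    local_pollination_step,
    minimize,
)


class TestLevySample:
    def test_seeded_determinism(self):
        a = levy_sample(1.5, 1000, np.random.default_rng(9))
        b = levy_sample(1.5, 1000, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)

    def test_symmetric_about_zero(self):
        draws = levy_sample(1.5, 10**6, np.random.default_rng(0))
        assert np.mean(draws > 0) == pytest.approx(0.5, abs=0.01)
        assert abs(np.median(draws)) < 0.01

    def test_tail_index(self):
        # P(|X| > s) ~ s^-lambda: fit the log-log slope over a tail decade
        lam = 1.5
        draws = np.abs(levy_sample(lam, 10**6, np.random.default_rng(1)))
        s = np.array([10.0, 100.0])
        frac = np.array([(draws > v).mean() for v in s])
        slope = np.diff(np.log(frac))[0] / np.diff(np.log(s))[0]
        assert slope == pytest.approx(-lam, abs=0.3)

    @pytest.mark.parametrize("lam", [0.5, 1.0, 3.5])
    def test_exponent_out_of_range(self, lam):
        with pytest.raises(ValueError, match="exponent"):
            levy_sample(lam, 10, np.random.default_rng(0))


class TestPollinationSteps:
    def test_global_fixed_point_at_best(self):
        x = np.array([1.0, 2.0, 3.0])
        out = global_pollination_step(x, x, 0.1, 1.5, np.random.default_rng(0))
        np.testing.assert_allclose(out, x)

    def test_global_zero_scale(self):
        rng = np.random.default_rng(0)
        x, g = np.array([1.0, -1.0]), np.array([5.0, 5.0])
        np.testing.assert_allclose(global_pollination_step(x, g, 0.0, 1.5, rng), x)

    def test_global_forced_unit_levy(self):
        out = global_pollination_step(
            np.array([2.0]), np.array([5.0]), 1.0, 1.5,
            np.random.default_rng(0), levy_draws=np.array([1.0]),
        )
        assert out[0] == pytest.approx(5.0)

    def test_global_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension"):
            global_pollination_step(np.zeros(2), np.zeros(3), 0.1, 1.5,
                                    np.random.default_rng(0))

    def test_local_equal_peers_is_identity(self):
        rng = np.random.default_rng(0)
        x, p = np.array([0.5, 0.5]), np.array([1.0, 2.0])
        np.testing.assert_allclose(local_pollination_step(x, p, p, rng), x)

    def test_local_forced_unit_eps(self):
        out = local_pollination_step(
            np.zeros(2), np.ones(2), np.zeros(2), np.random.default_rng(0), eps=1.0
        )
        np.testing.assert_allclose(out, np.ones(2))

    def test_local_stays_on_segment(self):
        x = np.array([1.0, 1.0])
        a, b = np.array([3.0, 0.0]), np.array([1.0, 2.0])
        for seed in range(20):
            out = local_pollination_step(x, a, b, np.random.default_rng(seed))
            t = (out - x) / (a - b)
            assert t[0] == pytest.approx(t[1])
            assert -1e-12 <= t[0] <= 1.0


def _sphere(target):
    return lambda x: float(np.sum((np.asarray(x) - target) ** 2))


class TestMinimize:
    def test_sphere_reaches_tolerance(self):
        target = np.array([1.0, -2.0, 3.0, 0.5, -0.5])
        bounds = SearchBounds(np.full(5, -25.0), np.full(5, 25.0))
        res = minimize(_sphere(target), bounds, FpaConfig(seed=3))
        assert res.best_fitness < 1e-8
        assert res.stop_reason == "tolerance"
        assert res.iterations_run < FpaConfig().max_iterations

    def test_constant_objective_stagnates_at_window(self):
        bounds = SearchBounds(np.array([-1.0]), np.array([1.0]))
        cfg = FpaConfig(seed=0, stagnation_window=50, fitness_tolerance=1e-30)
        res = minimize(lambda x: 1.0, bounds, cfg)
        assert res.stop_reason == "stagnation"
        assert res.iterations_run == 50

    @settings(max_examples=10, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_history_non_increasing(self, seed):
        bounds = SearchBounds(np.full(3, -5.0), np.full(3, 5.0))
        cfg = FpaConfig(seed=seed, max_iterations=60, fitness_tolerance=1e-30)
        res = minimize(lambda x: float(np.sum(np.abs(x)) + np.sin(x[0])), bounds, cfg)
        assert np.all(np.diff(res.fitness_history) <= 0)

    def test_every_evaluation_respects_box(self):
        lower, upper = np.array([-1.0, 0.0]), np.array([2.0, 0.5])
        seen = []

        def objective(x):
            seen.append(x.copy())
            return float(np.sum(x**2))

        minimize(objective, SearchBounds(lower, upper),
                 FpaConfig(seed=5, max_iterations=50, fitness_tolerance=1e-30))
        seen = np.array(seen)
        assert np.all(seen >= lower - 1e-12) and np.all(seen <= upper + 1e-12)

    def test_reproducible(self):
        bounds = SearchBounds(np.full(4, -10.0), np.full(4, 10.0))
        cfg = FpaConfig(seed=11, max_iterations=100)
        obj = _sphere(np.array([1.0, 1.0, -1.0, 0.0]))
        a = minimize(obj, bounds, cfg)
        b = minimize(obj, bounds, cfg)
        np.testing.assert_array_equal(a.best_position, b.best_position)
        assert a.best_fitness == b.best_fitness
        assert a.iterations_run == b.iterations_run

    def test_quadratic_bowl_accuracy(self):
        # anisotropic 2-D bowl: minimizer found to within 1e-3
        target = np.array([0.7, -1.3])
        bounds = SearchBounds(np.full(2, -5.0), np.full(2, 5.0))

        def bowl(x):
            d = x - target
            return float(3 * d[0] ** 2 + 0.5 * d[1] ** 2)

        res = minimize(bowl, bounds, FpaConfig(seed=2))
        np.testing.assert_allclose(res.best_position, target, atol=1e-3)

    def test_nonfinite_objective_treated_as_worst(self):
        bounds = SearchBounds(np.array([-2.0]), np.array([2.0]))

        def holey(x):
            return np.nan if x[0] < 0 else float(x[0] ** 2)

        res = minimize(holey, bounds, FpaConfig(seed=1, max_iterations=300))
        assert np.isfinite(res.best_fitness)
        assert res.best_position[0] >= 0

    def test_vectorized_matches_scalar(self):
        bounds = SearchBounds(np.full(3, -5.0), np.full(3, 5.0))
        cfg = FpaConfig(seed=7, max_iterations=80)
        target = np.array([0.5, -0.5, 1.5])
        a = minimize(_sphere(target), bounds, cfg)
        b = minimize(lambda P: np.sum((P - target) ** 2, axis=1), bounds, cfg,
                     vectorized=True)
        np.testing.assert_array_equal(a.best_position, b.best_position)


class TestConfigValidation:
    def test_switch_probability_range(self):
        with pytest.raises(ValueError, match="switch_probability"):
            FpaConfig(switch_probability=1.5)

    def test_bounds_ordering(self):
        with pytest.raises(ValueError, match="lower"):
            SearchBounds(np.array([1.0]), np.array([0.0]))
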