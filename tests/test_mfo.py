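"""Unit and property tests for the Moth-Flame Optimization core."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mothflame.mfo import (
    FlameArchive,
    MFOConfig,
    MothPopulation,
    SearchSpace,
    construct_flames,
    flame_count,
    init_population,
    optimize,
    spiral_terms,
    update_positions,
)


class FixedRng:
    """Stand-in RNG returning a constant uniform draw."""

    def __init__(self, value):
        self.value = value

    def random(self, size=None):
        if size is None:
            return self.value
        return np.full(size, self.value)


class TestSearchSpace:
    def test_rejects_inverted_and_nonfinite_bounds(self):
        with pytest.raises(ValueError):
            SearchSpace(np.array([1.0]), np.array([0.0]))
        with pytest.raises(ValueError):
            SearchSpace(np.array([np.nan]), np.array([1.0]))
        with pytest.raises(ValueError):
            SearchSpace(np.array([0.0]), np.array([np.inf]))


class TestInitPopulation:
    @pytest.mark.parametrize(
        "lo, hi, draw, expected",
        [(0.0, 1.0, 0.5, 0.5), (-1.0, 1.0, 0.75, 0.5)],
    )
    def test_affine_map(self, lo, hi, draw, expected):
        space = SearchSpace.cube(1, lo, hi)
        pop = init_population(space, 2, FixedRng(draw))
        assert pop.positions == pytest.approx(expected)
        assert pop.fitness is None

    @given(
        seed=st.integers(0, 2**16),
        lo=st.floats(-100, 0),
        width=st.floats(0.1, 100),
    )
    @settings(max_examples=25, deadline=None)
    def test_positions_within_bounds(self, seed, lo, width):
        space = SearchSpace.cube(4, lo, lo + width)
        pop = init_population(space, 5, np.random.default_rng(seed))
        assert (pop.positions >= space.lower).all()
        assert (pop.positions <= space.upper).all()


class TestFlameCount:
    @pytest.mark.parametrize(
        "t, n, t_max, expected",
        [
            (100, 7, 100, 1),     # always 1 at t = T
            (1, 10, 100, 10),     # round(9.91) = 10
            (50, 10, 100, 6),     # round(5.5), half away from zero
        ],
    )
    def test_schedule_values(self, t, n, t_max, expected):
        assert flame_count(t, n, t_max) == expected

    @given(n=st.integers(2, 50), t_max=st.integers(1, 200))
    @settings(max_examples=50, deadline=None)
    def test_nonincreasing_and_endpoints(self, n, t_max):
        counts = [flame_count(t, n, t_max) for t in range(1, t_max + 1)]
        assert all(1 <= r <= n for r in counts)
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert counts[-1] == 1

    def test_out_of_range_iteration(self):
        with pytest.raises(IndexError):
            flame_count(0, 10, 100)
        with pytest.raises(IndexError):
            flame_count(101, 10, 100)


class TestConstructFlames:
    def test_first_iteration_sorts_moths(self):
        pop = MothPopulation(
            positions=np.array([[10.0], [20.0], [30.0]]),
            fitness=np.array([3.0, 1.0, 2.0]),
        )
        flames = construct_flames(None, pop)
        assert flames.fitness.tolist() == [1.0, 2.0, 3.0]
        assert flames.flames[:, 0].tolist() == [20.0, 30.0, 10.0]

    def test_merge_keeps_best_n(self):
        prev = FlameArchive(flames=np.array([[1.0], [3.0]]),
                            fitness=np.array([1.0, 3.0]))
        pop = MothPopulation(positions=np.array([[2.0], [4.0]]),
                             fitness=np.array([2.0, 4.0]))
        flames = construct_flames(prev, pop)
        assert flames.fitness.tolist() == [1.0, 2.0]

    def test_elitism_on_merge(self):
        prev = FlameArchive(flames=np.array([[0.0], [1.0]]),
                            fitness=np.array([0.5, 2.0]))
        pop = MothPopulation(positions=np.array([[5.0], [6.0]]),
                             fitness=np.array([7.0, 8.0]))
        flames = construct_flames(prev, pop)
        assert flames.best_fitness <= 0.5

    def test_nan_fitness_rejected(self):
        pop = MothPopulation(positions=np.zeros((2, 1)),
                             fitness=np.array([np.nan, 1.0]))
        with pytest.raises(ValueError):
            construct_flames(None, pop)


class TestSpiralTerms:
    def test_a_reaches_minus_two_at_final_iteration(self):
        terms = spiral_terms(100, 100, 1.0, FixedRng(0.3))
        assert terms.a == pytest.approx(-2.0)

    @pytest.mark.parametrize("draw, expected_k", [(0.0, 1.0), (1.0, None)])
    def test_k_endpoints(self, draw, expected_k):
        terms = spiral_terms(10, 100, 1.0, FixedRng(draw))
        if expected_k is None:
            expected_k = terms.a
        assert terms.k == pytest.approx(expected_k)
        assert terms.a <= terms.k <= 1.0


class TestUpdatePositions:
    def _setup(self, moth_pos, flame_pos, lo=-100.0, hi=100.0):
        space = SearchSpace.cube(moth_pos.shape[1], lo, hi)
        moths = MothPopulation(positions=moth_pos, fitness=np.zeros(len(moth_pos)))
        flames = FlameArchive(flames=flame_pos,
                              fitness=np.arange(len(flame_pos), dtype=float))
        cfg = MFOConfig(n_moths=len(moth_pos), max_iterations=100)
        return moths, flames, cfg, space

    def test_moth_at_flame_is_fixed_point(self):
        pos = np.array([[2.0, 3.0], [2.0, 3.0]])
        moths, flames, cfg, space = self._setup(pos, pos.copy())
        new = update_positions(moths, flames, 2, 5, cfg, space,
                               np.random.default_rng(0))
        np.testing.assert_allclose(new.positions, pos)

    def test_unit_distance_k_zero_lands_at_flame_plus_one(self):
        # k = 0 requires u = 1/(1-a); at t = T, a = -2 so u = 1/3
        moths, flames, cfg, space = self._setup(
            np.array([[0.0], [0.0]]), np.array([[1.0], [1.0]])
        )
        new = update_positions(moths, flames, 2, 100, cfg, space,
                               FixedRng(1.0 / 3.0))
        np.testing.assert_allclose(new.positions, 2.0)  # F + 1*e^0*cos(0)

    @given(seed=st.integers(0, 2**16), t=st.integers(1, 100))
    @settings(max_examples=25, deadline=None)
    def test_updates_stay_clamped(self, seed, t):
        rng = np.random.default_rng(seed)
        space = SearchSpace.cube(3, -1.0, 1.0)
        moths = MothPopulation(positions=rng.uniform(-1, 1, (6, 3)),
                               fitness=rng.random(6))
        flames = FlameArchive(flames=rng.uniform(-1, 1, (6, 3)),
                              fitness=np.sort(rng.random(6)))
        cfg = MFOConfig(n_moths=6, max_iterations=100)
        new = update_positions(moths, flames, 3, t, cfg, space, rng)
        assert (new.positions >= -1.0).all() and (new.positions <= 1.0).all()

    def test_flame_index_out_of_range(self):
        moths, flames, cfg, space = self._setup(np.zeros((2, 1)), np.ones((2, 1)))
        with pytest.raises(IndexError):
            update_positions(moths, flames, 3, 5, cfg, space,
                             np.random.default_rng(0))


class TestOptimize:
    def _sphere_cfg(self, seed, n=10, t=30):
        return MFOConfig(n_moths=n, max_iterations=t, seed=seed,
                         objective=lambda x: float(np.sum(x**2)))

    def test_trace_nonincreasing_and_final_best(self):
        res = optimize(self._sphere_cfg(0), SearchSpace.cube(3, -5, 5))
        assert (np.diff(res.trace) <= 0).all()
        assert res.best_fitness == res.trace[-1]
        assert len(res.trace) == 30

    def test_single_iteration_trace_is_initial_best(self):
        cfg = MFOConfig(n_moths=2, max_iterations=1, seed=3,
                        objective=lambda x: float(np.sum(x**2)))
        space = SearchSpace.cube(2, -5, 5)
        res = optimize(cfg, space)
        rng = np.random.default_rng(3)
        init = init_population(space, 2, rng)
        expected = min(float(np.sum(x**2)) for x in init.positions)
        assert res.trace.shape == (1,)
        assert res.best_fitness == pytest.approx(expected)

    def test_seeded_determinism(self):
        space = SearchSpace.cube(4, -2, 2)
        r1 = optimize(self._sphere_cfg(42), space)
        r2 = optimize(self._sphere_cfg(42), space)
        np.testing.assert_array_equal(r1.trace, r2.trace)
        np.testing.assert_array_equal(r1.best_position, r2.best_position)

    def test_objective_error_reports_iteration(self):
        def bad(x):
            raise RuntimeError("boom")

        cfg = MFOConfig(n_moths=2, max_iterations=3, objective=bad)
        with pytest.raises(RuntimeError, match="iteration 1"):
            optimize(cfg, SearchSpace.cube(2, 0, 1))

    def test_best_position_within_bounds(self):
        res = optimize(self._sphere_cfg(7), SearchSpace.cube(3, -1, 1))
        assert (np.abs(res.best_position) <= 1.0).all()
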