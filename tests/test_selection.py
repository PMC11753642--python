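"""Tests for the MFO wrapper feature selector and its exhaustive oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mothflame.mfo import MFOConfig
from mothflame.selection import (
    FitnessSpec,
    MFOFeatureSelector,
    SelectionResult,
    binarize,
    combine_fitness,
    exhaustive_oracle,
    select_features,
    selection_fitness,
    validate_features,
)


class TestBinarize:
    @pytest.mark.parametrize(
        "position, expected",
        [
            ([0.9, 0.9], [True, True]),
            ([0.6, 0.4, 0.5], [True, False, False]),   # strict > 0.5
            ([0.1, 0.3, 0.2], [False, True, False]),   # empty-mask repair
        ],
    )
    def test_threshold_and_repair(self, position, expected):
        assert binarize(np.array(position)).tolist() == expected

    def test_repair_tie_takes_lowest_index(self):
        assert binarize(np.array([0.3, 0.3, 0.1])).tolist() == [True, False, False]

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            binarize(np.array([0.2, np.inf]))

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_mask_never_empty(self, position):
        assert binarize(np.array(position)).any()


class TestFitness:
    def test_penalty_arithmetic(self):
        assert combine_fitness(0.1, 5, 10, 0.99) == pytest.approx(0.104)
        assert combine_fitness(0.2, 3, 10, 1.0) == pytest.approx(0.2)

    def test_monotone_in_error(self):
        f = [combine_fitness(e, 4, 10, 0.99) for e in (0.1, 0.2, 0.3)]
        assert f == sorted(f)

    def test_deterministic_given_seed(self, small_features):
        X, y, _ = small_features
        mask = np.array([True, False, True, True, False, False])
        spec = FitnessSpec(seed=9)
        assert selection_fitness(mask, X, y, spec) == selection_fitness(mask, X, y, spec)

    def test_stratification_error_on_tiny_class(self):
        X = np.vstack([np.zeros((2, 3)), np.ones((10, 3))])
        y = np.array([1] * 2 + [2] * 10)
        with pytest.raises(ValueError, match="stratification"):
            selection_fitness(np.array([True, True, True]), X, y,
                              FitnessSpec(cv_folds=5))

    def test_validate_rejects_nan_and_singleton_class(self):
        with pytest.raises(ValueError):
            validate_features(np.array([[np.nan, 1.0], [0.0, 1.0]]), [1, 2])
        with pytest.raises(ValueError):
            validate_features(np.ones((3, 2)), [1, 1, 2])


class TestExhaustiveOracle:
    def test_single_feature_is_only_candidate(self):
        rng = np.random.default_rng(0)
        X = np.hstack([rng.normal(size=(20, 1))])
        y = np.array([1] * 10 + [2] * 10)
        mask, _ = exhaustive_oracle(X, y, FitnessSpec(seed=0))
        assert mask.tolist() == [True]

    def test_refuses_large_d(self):
        X = np.random.default_rng(0).normal(size=(10, 16))
        y = np.array([1] * 5 + [2] * 5)
        with pytest.raises(ValueError, match="refused"):
            exhaustive_oracle(X, y)

    def test_oracle_dominates_mfo(self, small_features):
        X, y, _ = small_features
        spec = FitnessSpec(seed=1)
        _, oracle_fit = exhaustive_oracle(X, y, spec)
        result = select_features(X, y, MFOConfig(n_moths=10, max_iterations=10,
                                                 seed=1), spec)
        assert oracle_fit <= result.fitness + 1e-12


class TestSelectFeatures:
    def test_perfectly_separating_feature_is_selected(self):
        # column 0 separates the classes exactly; columns 1-3 are noise
        rng = np.random.default_rng(4)
        n = 30
        y = np.array([1] * n + [2] * n)
        sep = np.concatenate([rng.normal(-10, 0.1, n), rng.normal(10, 0.1, n)])
        X = np.column_stack([sep] + [rng.normal(size=2 * n) for _ in range(3)])
        result = select_features(X, y, MFOConfig(n_moths=10, max_iterations=15,
                                                 seed=0), FitnessSpec(seed=0))
        assert result.mask[0]
        assert result.cv_error == pytest.approx(0.0)

    def test_determinism_and_audit_record(self, small_features):
        X, y, _ = small_features
        cfg = MFOConfig(n_moths=8, max_iterations=8, seed=5)
        spec = FitnessSpec(seed=5)
        r1 = select_features(X, y, cfg, spec)
        r2 = select_features(X, y, cfg, spec)
        assert r1.mask.tolist() == r2.mask.tolist()
        assert r1.fitness == r2.fitness
        # fitness recomputable from its parts
        assert r1.fitness == pytest.approx(
            combine_fitness(r1.cv_error, r1.n_selected, X.shape[1], spec.alpha)
        )
        assert r1.n_selected == int(r1.mask.sum()) >= 1
        assert (np.diff(r1.trace) <= 0).all()

    def test_json_round_trip(self, small_features):
        X, y, _ = small_features
        r = select_features(X, y, MFOConfig(n_moths=6, max_iterations=5, seed=2),
                            FitnessSpec(seed=2))
        back = SelectionResult.from_json(r.to_json())
        assert back.mask.tolist() == r.mask.tolist()
        assert back.fitness == pytest.approx(r.fitness)


class TestSklearnEstimator:
    def test_fit_transform_and_params(self, small_features):
        X, y, _ = small_features
        sel = MFOFeatureSelector(n_moths=8, max_iterations=8, random_state=3)
        assert sel.get_params()["alpha"] == 0.99
        sel.set_params(alpha=0.95)
        Xt = sel.fit(X, y).transform(X)
        assert Xt.shape == (X.shape[0], sel.n_selected_)
        assert sel.support_.sum() == sel.n_selected_
        np.testing.assert_array_equal(Xt, X[:, sel.support_])

    def test_clone_compatible(self, small_features):
        from sklearn.base import clone

        X, y, _ = small_features
        sel = MFOFeatureSelector(n_moths=6, max_iterations=5, random_state=1)
        c = clone(sel)
        assert c.get_params() == sel.get_params()
        assert c.fit(X, y).support_.tolist() == sel.fit(X, y).support_.tolist()
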