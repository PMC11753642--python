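"""Binary wrapper feature selection driven by Moth-Flame Optimization.

Moths fly in the continuous unit cube [0, 1]^d; a position is thresholded
into a boolean column mask (coordinate > 0.5) and scored by the
cross-validated error of an inner classifier on the masked columns plus a
small subset-size penalty:

    fitness(mask) = alpha * cv_error(mask) + (1 - alpha) * |mask| / d

with alpha = 0.99 by default, so accuracy dominates and the penalty only
breaks ties toward smaller subsets.  Fitness is minimized.  An all-false
mask is repaired by selecting the coordinate with the largest position
(lowest index on ties) so the search space stays closed.

`exhaustive_oracle` enumerates every nonempty mask (d <= 15) and is the
ground-truth reference the selector is tested against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Tuple

import numpy as np
from sklearn.base import BaseEstimator, clone
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_X_y, check_is_fitted

from .evaluation import make_classifier
from .mfo import MFOConfig, SearchSpace, optimize

__all__ = [
    "FitnessSpec",
    "SelectionResult",
    "validate_features",
    "binarize",
    "combine_fitness",
    "selection_fitness",
    "select_features",
    "exhaustive_oracle",
    "MFOFeatureSelector",
]


@dataclass
class FitnessSpec:
    """Wrapper-fitness parameters.

    alpha
        Weight on classification error, in (0, 1]; the complement weights
        the selected-fraction penalty.
    inner_classifier
        Preset id from the classifier registry (default "F-KNN", i.e. 1-NN:
        fast and parameter-free).
    cv_folds
        Stratified folds for the inner error estimate.
    seed
        Fixes the fold assignment, making fitness a pure function of
        (mask, data, spec).
    """

    alpha: float = 0.99
    inner_classifier: str = "F-KNN"
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")


@dataclass
class SelectionResult:
    """Chosen mask plus the audit trail needed to reproduce it."""

    mask: np.ndarray
    fitness: float
    cv_error: float
    n_selected: int
    trace: np.ndarray
    config_echo: dict = field(default_factory=dict)

    @property
    def selected_indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask)

    def to_json(self) -> str:
        return json.dumps(
            {
                "selected_indices": self.selected_indices.tolist(),
                "n_features": int(self.mask.size),
                "fitness": self.fitness,
                "cv_error": self.cv_error,
                "n_selected": self.n_selected,
                "trace": np.asarray(self.trace).tolist(),
                "config_echo": self.config_echo,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SelectionResult":
        obj = json.loads(text)
        mask = np.zeros(obj["n_features"], dtype=bool)
        mask[obj["selected_indices"]] = True
        return cls(
            mask=mask,
            fitness=obj["fitness"],
            cv_error=obj["cv_error"],
            n_selected=obj["n_selected"],
            trace=np.asarray(obj["trace"]),
            config_echo=obj.get("config_echo", {}),
        )


def validate_features(X, y) -> Tuple[np.ndarray, np.ndarray]:
    """Check the labeled feature table: finite values, every class with at
    least two samples (required for stratified CV)."""
    X, y = check_X_y(np.asarray(X, dtype=float), np.asarray(y))
    if np.isnan(X).any():
        raise ValueError("feature matrix contains NaN")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < 2 or len(counts) < 2:
        raise ValueError("every class needs at least 2 samples, and K >= 2")
    return X, y


def binarize(position: np.ndarray) -> np.ndarray:
    """Threshold a continuous position into a mask; repair an empty mask by
    selecting argmax(position) (lowest index on ties)."""
    position = np.asarray(position, dtype=float)
    if not np.isfinite(position).all():
        raise ValueError("position contains non-finite values")
    mask = position > 0.5
    if not mask.any():
        mask = mask.copy()
        mask[int(np.argmax(position))] = True
    return mask


def combine_fitness(cv_error: float, n_selected: int, d: int, alpha: float) -> float:
    """alpha * error + (1 - alpha) * selected fraction."""
    return alpha * cv_error + (1.0 - alpha) * n_selected / d


def _cv_error(mask: np.ndarray, X: np.ndarray, y: np.ndarray,
              spec: FitnessSpec, folds) -> float:
    Xm = X[:, mask]
    errors = 0
    base = make_classifier(spec.inner_classifier, seed=spec.seed)
    for tr, te in folds:
        clf = clone(base)
        clf.fit(Xm[tr], y[tr])
        errors += int(np.sum(clf.predict(Xm[te]) != y[te]))
    return errors / len(y)


def _make_folds(X, y, spec: FitnessSpec):
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < spec.cv_folds:
        raise ValueError(
            f"stratification error: smallest class has {counts.min()} samples, "
            f"fewer than cv_folds={spec.cv_folds}"
        )
    skf = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True,
                          random_state=spec.seed)
    return list(skf.split(X, y))


def selection_fitness(mask, X, y, spec: FitnessSpec = FitnessSpec()) -> float:
    """Wrapper fitness of one mask; deterministic given (mask, data, spec)."""
    X, y = validate_features(X, y)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (X.shape[1],) or not mask.any():
        raise ValueError("mask must be a nonempty boolean vector of length d")
    folds = _make_folds(X, y, spec)
    err = _cv_error(mask, X, y, spec, folds)
    return combine_fitness(err, int(mask.sum()), X.shape[1], spec.alpha)


def select_features(
    X,
    y,
    mfo_cfg: Optional[MFOConfig] = None,
    spec: FitnessSpec = FitnessSpec(),
) -> SelectionResult:
    """Run MFO over [0, 1]^d with the wrapper fitness as objective.

    Fitness values are memoized per mask (many continuous positions map to
    the same mask), which makes the wrapped search dramatically cheaper
    without changing any result.  Same seed, data and spec give the same
    mask.
    """
    X, y = validate_features(X, y)
    d = X.shape[1]
    if d < 2:
        raise ValueError("feature selection needs at least 2 columns")
    if mfo_cfg is None:
        mfo_cfg = MFOConfig(n_moths=20, max_iterations=50)

    folds = _make_folds(X, y, spec)
    cache: dict = {}

    def objective(position: np.ndarray) -> float:
        mask = binarize(position)
        key = mask.tobytes()
        if key not in cache:
            err = _cv_error(mask, X, y, spec, folds)
            cache[key] = (combine_fitness(err, int(mask.sum()), d, spec.alpha), err)
        return cache[key][0]

    cfg = MFOConfig(
        n_moths=mfo_cfg.n_moths,
        max_iterations=mfo_cfg.max_iterations,
        spiral_b=mfo_cfg.spiral_b,
        seed=mfo_cfg.seed,
        objective=objective,
    )
    space = SearchSpace.cube(d, 0.0, 1.0)
    result = optimize(cfg, space)

    mask = binarize(result.best_position)
    fitness, cv_error = cache[mask.tobytes()]
    return SelectionResult(
        mask=mask,
        fitness=fitness,
        cv_error=cv_error,
        n_selected=int(mask.sum()),
        trace=result.trace,
        config_echo={
            "n_moths": cfg.n_moths,
            "max_iterations": cfg.max_iterations,
            "spiral_b": cfg.spiral_b,
            "seed": cfg.seed,
            "fitness": asdict(spec),
            "n_features": d,
        },
    )


def exhaustive_oracle(X, y, spec: FitnessSpec = FitnessSpec()) -> Tuple[np.ndarray, float]:
    """Global optimum by enumerating all 2^d - 1 nonempty masks (d <= 15).

    Ties resolve to the lowest-index mask in enumeration order (mask bits
    little-endian in the column index).
    """
    X, y = validate_features(X, y)
    d = X.shape[1]
    if d > 15:
        raise ValueError(f"exhaustive search refused for d={d} > 15")
    folds = _make_folds(X, y, spec)
    best_mask, best_fit = None, np.inf
    for code in range(1, 2**d):
        mask = np.array([(code >> j) & 1 for j in range(d)], dtype=bool)
        err = _cv_error(mask, X, y, spec, folds)
        fit = combine_fitness(err, int(mask.sum()), d, spec.alpha)
        if fit < best_fit:
            best_mask, best_fit = mask, fit
    assert best_mask is not None
    return best_mask, float(best_fit)


class MFOFeatureSelector(SelectorMixin, BaseEstimator):
    """sklearn-compatible feature selector wrapping the MFO search.

    Parameters
    ----------
    n_moths, max_iterations, spiral_b : MFO search budget and spiral shape.
    alpha : weight on CV error in the fitness (complement penalizes subset
        size).
    inner_classifier : preset id scoring candidate subsets (default 1-NN).
    cv_folds : stratified folds for the inner error estimate.
    random_state : seeds both the MFO stream and the CV fold assignment.

    Attributes
    ----------
    support_ : boolean mask of selected columns.
    fitness_, cv_error_, n_selected_, trace_ : audit record of the search.
    result_ : the full :class:`SelectionResult`.
    """

    def __init__(self, n_moths=20, max_iterations=50, spiral_b=1.0,
                 alpha=0.99, inner_classifier="F-KNN", cv_folds=5,
                 random_state=0):
        self.n_moths = n_moths
        self.max_iterations = max_iterations
        self.spiral_b = spiral_b
        self.alpha = alpha
        self.inner_classifier = inner_classifier
        self.cv_folds = cv_folds
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_features(X, y)
        cfg = MFOConfig(
            n_moths=self.n_moths,
            max_iterations=self.max_iterations,
            spiral_b=self.spiral_b,
            seed=self.random_state,
        )
        spec = FitnessSpec(
            alpha=self.alpha,
            inner_classifier=self.inner_classifier,
            cv_folds=self.cv_folds,
            seed=self.random_state,
        )
        result = select_features(X, y, cfg, spec)
        self.result_ = result
        self.support_ = result.mask
        self.fitness_ = result.fitness
        self.cv_error_ = result.cv_error
        self.n_selected_ = result.n_selected
        self.trace_ = result.trace
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_
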