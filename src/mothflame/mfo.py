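"""Continuous Moth-Flame Optimization (MFO).

MFO is a population metaheuristic modelled on the transverse orientation of
nocturnal moths: each search agent ("moth") spirals around an elite
best-known position ("flame") on a logarithmic spiral, while the number of
active flames shrinks linearly from N to 1 over the run so that exploration
collapses into exploitation.

The update for moth ``i`` at iteration ``t`` is

    x_i(t+1) = D_i * exp(b*k) * cos(2*pi*k) + f

where ``f`` is moth i's own flame for ``i <= R`` (the current flame count)
and the R-th flame otherwise, ``D_i = |f - x_i|`` coordinate-wise, ``b`` is
the spiral shape constant and ``k`` is drawn uniformly in ``[a, 1]`` with
``a = -1 - t/T`` decreasing from about -1 to -2 over the run.

Flames are the elitist memory: at every iteration the previous flames and
the current moths are pooled, sorted by fitness (ascending — everything here
MINIMIZES) and the best N retained, so the best solution found is never lost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "SearchSpace",
    "MothPopulation",
    "FlameArchive",
    "SpiralTerms",
    "MFOConfig",
    "MFOResult",
    "init_population",
    "flame_count",
    "construct_flames",
    "spiral_terms",
    "update_positions",
    "optimize",
    "MothFlameOptimizer",
]


@dataclass(frozen=True)
class SearchSpace:
    """Box-constrained search domain: lower/upper bound per dimension."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        if lo.ndim != 1 or hi.shape != lo.shape or lo.size < 1:
            raise ValueError("bounds must be 1-D arrays of equal, positive length")
        if not (np.isfinite(lo).all() and np.isfinite(hi).all()):
            raise ValueError("bounds must be finite")
        if not (lo < hi).all():
            raise ValueError("every lower bound must be strictly below its upper bound")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    @property
    def dims(self) -> int:
        return self.lower.size

    @classmethod
    def cube(cls, dims: int, lower: float, upper: float) -> "SearchSpace":
        return cls(np.full(dims, float(lower)), np.full(dims, float(upper)))

    def clip(self, positions: np.ndarray) -> np.ndarray:
        return np.clip(positions, self.lower, self.upper)


@dataclass
class MothPopulation:
    """Moth positions and (optionally evaluated) fitness values."""

    positions: np.ndarray  # (n, d)
    fitness: Optional[np.ndarray] = None  # (n,) or None until evaluated

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def evaluated(self) -> bool:
        return self.fitness is not None


@dataclass
class FlameArchive:
    """Elite memory: flame positions sorted ascending by fitness (best first)."""

    flames: np.ndarray  # (n, d)
    fitness: np.ndarray  # (n,), sorted ascending

    @property
    def best_position(self) -> np.ndarray:
        return self.flames[0]

    @property
    def best_fitness(self) -> float:
        return float(self.fitness[0])


@dataclass(frozen=True)
class SpiralTerms:
    """One draw of the spiral parameters: k ~ U[a, 1], a in [-2, -1]."""

    a: float
    k: float
    b: float


@dataclass
class MFOConfig:
    """Run parameters; ``objective`` maps a position vector to a finite real
    to minimize."""

    n_moths: int = 30
    max_iterations: int = 100
    spiral_b: float = 1.0
    seed: int = 0
    objective: Optional[Callable[[np.ndarray], float]] = None

    def __post_init__(self):
        if self.n_moths < 2:
            raise ValueError("n_moths must be at least 2")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be at least 1")


@dataclass
class MFOResult:
    best_position: np.ndarray
    best_fitness: float
    trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_evaluations: int = 0


def init_population(space: SearchSpace, n: int, rng: np.random.Generator) -> MothPopulation:
    """Scatter ``n`` moths uniformly in the box: x = u * (ub - lb) + lb.

    Draw order is moth-major then dimension, so a run is reproducible from
    the seed alone.
    """
    if n < 2:
        raise ValueError("population size must be at least 2")
    u = rng.random((n, space.dims))
    positions = u * (space.upper - space.lower) + space.lower
    return MothPopulation(positions=positions, fitness=None)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def flame_count(t: int, n: int, t_max: int) -> int:
    """Linearly shrinking flame count round(N - t*(N-1)/T), clamped to [1, N].

    Non-increasing in t; equals N at t=1 (for T > N-1) and exactly 1 at t=T.
    Ties at .5 round half away from zero.
    """
    if not 1 <= t <= t_max:
        raise IndexError(f"iteration index {t} outside [1, {t_max}]")
    if n < 2:
        raise ValueError("n must be at least 2")
    r = _round_half_away(n - t * (n - 1) / t_max)
    return max(1, min(n, r))


def construct_flames(prev: Optional[FlameArchive], moths: MothPopulation) -> FlameArchive:
    """Elitist flame construction.

    First iteration (``prev`` is None): flames are the moths sorted ascending
    by fitness.  Later iterations: pool previous flames with the current
    moths, sort ascending, keep the best N.  Sorting is stable, so equal
    fitness preserves first-seen order (flames before moths).
    """
    if not moths.evaluated:
        raise ValueError("moth population must be evaluated before flame construction")
    fit = np.asarray(moths.fitness, dtype=float)
    if np.isnan(fit).any():
        raise ValueError("moth fitness contains NaN")
    n = moths.n
    if prev is None:
        pool_pos, pool_fit = moths.positions, fit
    else:
        pool_pos = np.vstack([prev.flames, moths.positions])
        pool_fit = np.concatenate([prev.fitness, fit])
    order = np.argsort(pool_fit, kind="stable")[:n]
    return FlameArchive(flames=pool_pos[order].copy(), fitness=pool_fit[order].copy())


def spiral_terms(t: int, t_max: int, b: float, rng: np.random.Generator) -> SpiralTerms:
    """One spiral draw: a = -1 - t/T, k = (a - 1) * u + 1 with u ~ U[0, 1]."""
    if not 1 <= t <= t_max:
        raise IndexError(f"iteration index {t} outside [1, {t_max}]")
    a = _adaptive_a(t, t_max)
    k = (a - 1.0) * float(rng.random()) + 1.0
    return SpiralTerms(a=a, k=k, b=b)


def _adaptive_a(t: int, t_max: int) -> float:
    return -1.0 + t * (-1.0 / t_max)


def update_positions(
    moths: MothPopulation,
    flames: FlameArchive,
    r: int,
    t: int,
    cfg: MFOConfig,
    space: SearchSpace,
    rng: np.random.Generator,
) -> MothPopulation:
    """Logarithmic-spiral position update, coordinate-wise, then clamp.

    Moth i <= r spirals around its own flame F_i; moth i > r around flame
    F_r.  One k is drawn per moth per dimension (moth-major order).  The new
    population is unevaluated.
    """
    n, d = moths.positions.shape
    if not 1 <= r <= flames.flames.shape[0]:
        raise IndexError(f"flame count {r} outside [1, {flames.flames.shape[0]}]")
    a = _adaptive_a(t, cfg.max_iterations)
    k = (a - 1.0) * rng.random((n, d)) + 1.0
    # target flame per moth: own flame up to r, then the r-th flame
    idx = np.minimum(np.arange(n), r - 1)
    target = flames.flames[idx]
    dist = np.abs(target - moths.positions)
    new_pos = dist * np.exp(cfg.spiral_b * k) * np.cos(2.0 * np.pi * k) + target
    return MothPopulation(positions=space.clip(new_pos), fitness=None)


def _evaluate(pop: MothPopulation, objective: Callable[[np.ndarray], float], t: int) -> None:
    try:
        fit = np.array([float(objective(x)) for x in pop.positions])
    except Exception as exc:  # add iteration context, keep the original cause
        raise RuntimeError(f"objective evaluation failed at iteration {t}") from exc
    if not np.isfinite(fit).all():
        raise ValueError(f"objective returned non-finite fitness at iteration {t}")
    pop.fitness = fit


def optimize(cfg: MFOConfig, space: SearchSpace) -> MFOResult:
    """Run the full MFO loop: evaluate -> construct flames -> shrink flame
    count -> spiral update, for ``cfg.max_iterations`` iterations.

    Returns the best flame and a per-iteration trace of the best flame
    fitness, which is non-increasing by elitism.  Identical (config, space,
    seed) triples give bit-identical results.
    """
    if cfg.objective is None:
        raise ValueError("cfg.objective must be set")
    rng = np.random.default_rng(cfg.seed)
    pop = init_population(space, cfg.n_moths, rng)
    flames: Optional[FlameArchive] = None
    t_max = cfg.max_iterations
    trace = np.empty(t_max)
    n_eval = 0
    for t in range(1, t_max + 1):
        _evaluate(pop, cfg.objective, t)
        n_eval += pop.n
        flames = construct_flames(flames, pop)
        r = flame_count(t, cfg.n_moths, t_max)
        trace[t - 1] = flames.best_fitness
        pop = update_positions(pop, flames, r, t, cfg, space, rng)
    assert flames is not None
    return MFOResult(
        best_position=flames.best_position.copy(),
        best_fitness=flames.best_fitness,
        trace=trace,
        n_evaluations=n_eval,
    )


class MothFlameOptimizer:
    """Convenience front end over :func:`optimize`.

    Parameters mirror :class:`MFOConfig`; call :meth:`minimize` with an
    objective and box bounds.
    """

    def __init__(self, n_moths: int = 30, max_iterations: int = 100,
                 spiral_b: float = 1.0, seed: int = 0):
        self.n_moths = n_moths
        self.max_iterations = max_iterations
        self.spiral_b = spiral_b
        self.seed = seed

    def minimize(
        self,
        objective: Callable[[np.ndarray], float],
        lower: Sequence[float] | float,
        upper: Sequence[float] | float,
        dims: Optional[int] = None,
    ) -> MFOResult:
        if np.isscalar(lower):
            if dims is None:
                raise ValueError("dims is required with scalar bounds")
            space = SearchSpace.cube(dims, float(lower), float(upper))  # type: ignore[arg-type]
        else:
            space = SearchSpace(np.asarray(lower, float), np.asarray(upper, float))
        cfg = MFOConfig(
            n_moths=self.n_moths,
            max_iterations=self.max_iterations,
            spiral_b=self.spiral_b,
            seed=self.seed,
            objective=objective,
        )
        return optimize(cfg, space)
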