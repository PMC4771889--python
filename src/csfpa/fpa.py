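"""Flower Pollination Algorithm: a bound-constrained continuous minimizer.

A population of candidate solutions ("flowers") evolves by two moves.  A
*global pollination* step pulls a flower toward the best solution found so
far, scaled per dimension by a heavy-tailed Levy draw:

    x <- x + gamma * L * (g_best - x)

A *local pollination* step walks along the difference of two random peers,
scaled by a single uniform draw:

    x <- x + eps * (x_j - x_k),   eps ~ Uniform[0, 1]

Each update, a flower takes the local step with probability ``p`` (the
switch probability, biased toward local search) and the global step
otherwise.  Moves are accepted greedily (never worsening that flower), so
the best-so-far fitness is non-increasing.  Levy steps use Mantegna's
construction for a stable tail index ``lambda``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import gamma as _gamma_fn
from typing import Callable

import numpy as np

__all__ = [
    "FpaConfig",
    "SearchBounds",
    "OptimizationResult",
    "levy_sample",
    "global_pollination_step",
    "local_pollination_step",
    "minimize",
]


@dataclass
class FpaConfig:
    """Settings for :func:`minimize`.

    ``switch_probability`` is the probability of a *local* pollination step.
    Stopping: fitness below ``fitness_tolerance``, or improvement over the
    last ``stagnation_window`` iterations below ``stagnation_tolerance``,
    or ``max_iterations``.
    """

    population_size: int = 25
    switch_probability: float = 0.8
    levy_exponent: float = 1.5
    step_scale: float = 0.1
    max_iterations: int = 3000
    fitness_tolerance: float = 1e-8
    stagnation_window: int = 200
    stagnation_tolerance: float = 1e-10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.switch_probability <= 1.0:
            raise ValueError("switch_probability must lie in [0, 1]")
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")
        if self.step_scale <= 0:
            raise ValueError("step_scale must be positive")


@dataclass
class SearchBounds:
    """Per-dimension box constraints (lower <= upper elementwise)."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if self.lower.shape != self.upper.shape:
            raise ValueError("lower and upper must have the same shape")
        if np.any(self.lower > self.upper):
            raise ValueError("lower must not exceed upper")

    @property
    def dim(self) -> int:
        return self.lower.shape[0]

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)


@dataclass
class OptimizationResult:
    best_position: np.ndarray
    best_fitness: float
    iterations_run: int
    stop_reason: str  # "tolerance" | "stagnation" | "max_iterations"
    fitness_history: np.ndarray = field(default_factory=lambda: np.empty(0))


def levy_sample(lam: float, size, rng: np.random.Generator) -> np.ndarray:
    """Symmetric heavy-tailed step draws with tail index ``lam``.

    Mantegna's construction: ``u / |v|**(1/lam)`` with ``u ~ N(0, sigma_u^2)``,
    ``v ~ N(0, 1)`` and

        sigma_u = [ Gamma(1+lam) sin(pi lam / 2)
                    / (Gamma((1+lam)/2) lam 2^((lam-1)/2)) ]^(1/lam)
    """
    if not 1.0 < lam <= 3.0:
        raise ValueError(f"levy exponent must lie in (1, 3], got {lam}")
    sigma_u = (
        _gamma_fn(1.0 + lam)
        * np.sin(np.pi * lam / 2.0)
        / (_gamma_fn((1.0 + lam) / 2.0) * lam * 2.0 ** ((lam - 1.0) / 2.0))
    ) ** (1.0 / lam)
    u = rng.normal(0.0, sigma_u, size=size)
    v = rng.normal(0.0, 1.0, size=size)
    return u / np.abs(v) ** (1.0 / lam)


def global_pollination_step(
    current: np.ndarray,
    global_best: np.ndarray,
    gamma: float,
    lam: float,
    rng: np.random.Generator,
    levy_draws: np.ndarray | None = None,
) -> np.ndarray:
    """Move toward the global best, scaled per dimension by a Levy draw.

    ``current`` may be a single vector or a (pop, dim) array (``global_best``
    broadcasts).  ``levy_draws`` lets callers inject pre-drawn steps.
    """
    current = np.asarray(current, dtype=float)
    global_best = np.asarray(global_best, dtype=float)
    if current.shape[-1] != global_best.shape[-1]:
        raise ValueError("current and global_best dimensions differ")
    if levy_draws is None:
        levy_draws = levy_sample(lam, current.shape, rng)
    return current + gamma * levy_draws * (global_best - current)


def local_pollination_step(
    current: np.ndarray,
    peer_a: np.ndarray,
    peer_b: np.ndarray,
    rng: np.random.Generator,
    eps: float | np.ndarray | None = None,
) -> np.ndarray:
    """Random walk along the difference of two peers, eps ~ Uniform[0, 1].

    A single scalar eps scales the whole difference vector (one draw per
    flower for array inputs).
    """
    current = np.asarray(current, dtype=float)
    peer_a = np.asarray(peer_a, dtype=float)
    peer_b = np.asarray(peer_b, dtype=float)
    if not (current.shape == peer_a.shape == peer_b.shape):
        raise ValueError("current and peers must share a shape")
    if eps is None:
        eps = rng.uniform(0.0, 1.0, size=current.shape[:-1] + (1,)) if current.ndim > 1 \
            else rng.uniform(0.0, 1.0)
    return current + eps * (peer_a - peer_b)


def _evaluate(
    objective: Callable, positions: np.ndarray, vectorized: bool
) -> np.ndarray:
    if vectorized:
        values = np.asarray(objective(positions), dtype=float)
    else:
        values = np.array([float(objective(x)) for x in positions], dtype=float)
    # non-finite objective values are treated as +inf (worst possible)
    return np.where(np.isfinite(values), values, np.inf)


def minimize(
    objective: Callable,
    bounds: SearchBounds,
    config: FpaConfig,
    vectorized: bool = False,
) -> OptimizationResult:
    """Minimize ``objective`` over the box by flower pollination.

    With ``vectorized=True`` the objective receives a (pop, dim) array and
    must return a length-pop vector; otherwise it is called per vector.
    Reproducible: identical config, seed and objective give identical
    results.
    """
    rng = np.random.default_rng(config.seed)
    n, d = config.population_size, bounds.dim

    pop = bounds.lower + rng.uniform(size=(n, d)) * (bounds.upper - bounds.lower)
    fit = _evaluate(objective, pop, vectorized)

    best_idx = int(np.argmin(fit))
    best_pos = pop[best_idx].copy()
    best_fit = float(fit[best_idx])
    history = [best_fit]

    stop_reason = "max_iterations"
    iterations = 0
    if best_fit < config.fitness_tolerance:
        stop_reason = "tolerance"
        return OptimizationResult(best_pos, best_fit, 0, stop_reason, np.asarray(history))
    for t in range(1, config.max_iterations + 1):
        iterations = t
        # Draw every random quantity for the iteration up front so the
        # stream is independent of which branch each flower takes.
        take_local = rng.uniform(size=n) < config.switch_probability
        levy = levy_sample(config.levy_exponent, (n, d), rng)
        eps = rng.uniform(size=(n, 1))
        peers = rng.integers(0, n, size=(n, 2))

        prop_global = global_pollination_step(
            pop, best_pos, config.step_scale, config.levy_exponent, rng, levy_draws=levy
        )
        prop_local = local_pollination_step(pop, pop[peers[:, 0]], pop[peers[:, 1]], rng, eps=eps)
        proposals = bounds.clip(np.where(take_local[:, None], prop_local, prop_global))

        new_fit = _evaluate(objective, proposals, vectorized)
        accept = new_fit <= fit  # greedy: never worsen a flower
        pop[accept] = proposals[accept]
        fit[accept] = new_fit[accept]

        idx = int(np.argmin(fit))
        if fit[idx] < best_fit:
            best_fit = float(fit[idx])
            best_pos = pop[idx].copy()
        history.append(best_fit)

        if best_fit < config.fitness_tolerance:
            stop_reason = "tolerance"
            break
        if (
            t >= config.stagnation_window
            and history[t - config.stagnation_window] - best_fit < config.stagnation_tolerance
        ):
            stop_reason = "stagnation"
            break

    return OptimizationResult(
        best_position=best_pos,
        best_fitness=best_fit,
        iterations_run=iterations,
        stop_reason=stop_reason,
        fitness_history=np.asarray(history),
    )
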