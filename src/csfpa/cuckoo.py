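"""Cuckoo Search over candidate regulator subsets.

The outer, combinatorial half of the inference method: each *nest* holds a
fixed-size combination of ``i_max`` candidate regulator genes for one target
gene.  Nest quality is the training error of the decoupled RNN restricted
to those regulators, minimized by the flower pollination optimizer.  New
candidates are proposed by a discrete analogue of a Levy flight (the Levy
magnitude sets how many slots of the combination are replaced: mostly one,
occasionally all), poor nests are abandoned and rebuilt at random with
probability ``p_a``, and the best nest is elitist.

Gene indices in nests are 1-based, matching the convention used in all
user-facing output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .benchmark import ExpressionDataset
from .fpa import FpaConfig, SearchBounds, levy_sample

__all__ = [
    "CsConfig",
    "RegulatorNest",
    "initialize_nests",
    "levy_move",
    "abandon_worst",
    "search_regulators",
]


@dataclass
class CsConfig:
    """Settings for the regulator-subset search.

    ``i_max`` caps the number of candidate regulators per target gene
    (default 3, the sparsity assumption); ``abandon_probability`` is the
    fraction of worst nests rebuilt each generation.
    """

    n_nests: int = 10
    abandon_probability: float = 0.25
    levy_exponent: float = 1.5
    step_scale: float = 1.0
    n_generations: int = 30
    i_max: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.abandon_probability <= 1.0:
            raise ValueError("abandon_probability must lie in [0, 1]")
        if self.i_max < 1:
            raise ValueError("i_max must be at least 1")
        if self.n_nests < 1:
            raise ValueError("n_nests must be at least 1")


@dataclass
class RegulatorNest:
    """One candidate solution: a combination of regulator genes (1-based).

    ``best_params`` holds the fitted (i_max weights, bias, tau) vector once
    the nest has been evaluated; ``fitness`` is the training error (lower is
    better, +inf before evaluation).
    """

    regulators: tuple[int, ...]
    best_params: np.ndarray | None = None
    fitness: float = math.inf

    def __post_init__(self) -> None:
        regs = tuple(int(g) for g in self.regulators)
        if len(set(regs)) != len(regs):
            raise ValueError(f"regulator indices must be distinct: {regs}")
        if any(g < 1 for g in regs):
            raise ValueError(f"gene indices are 1-based: {regs}")
        self.regulators = regs


def _random_combination(
    n_genes: int, i_max: int, rng: np.random.Generator
) -> tuple[int, ...]:
    genes = rng.choice(n_genes, size=i_max, replace=False) + 1
    return tuple(sorted(int(g) for g in genes))


def initialize_nests(n_genes: int, config: CsConfig, rng=None) -> list[RegulatorNest]:
    """Deterministic partition initialization, then random fill.

    Nest k holds the consecutive block (k*i_max - i_max + 1, ..., k*i_max)
    while whole blocks of gene indices remain — for 30 genes and i_max = 3
    this is (1,2,3), (4,5,6), ..., (28,29,30), covering every gene exactly
    once.  Any remaining nests get seeded random distinct combinations.
    """
    if n_genes < config.i_max:
        raise ValueError(f"need at least i_max={config.i_max} genes, got {n_genes}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    nests: list[RegulatorNest] = []
    n_blocks = min(config.n_nests, n_genes // config.i_max)
    for k in range(n_blocks):
        start = k * config.i_max + 1
        nests.append(RegulatorNest(tuple(range(start, start + config.i_max))))
    while len(nests) < config.n_nests:
        nests.append(RegulatorNest(_random_combination(n_genes, config.i_max, rng)))
    return nests


def levy_move(
    nest: RegulatorNest, n_genes: int, config: CsConfig, rng: np.random.Generator
) -> RegulatorNest:
    """Propose a new combination by a discrete Levy flight.

    The number of slots replaced is k = min(i_max, max(1, round(|alpha*L|)))
    for a Levy draw L, so small changes dominate with occasional full
    rebuilds.  Replacement genes are drawn uniformly from genes not already
    in the nest.
    """
    L = levy_sample(config.levy_exponent, None, rng)
    k = int(min(config.i_max, max(1, round(abs(config.step_scale * float(L))))))
    current = list(nest.regulators)
    outside = np.setdiff1d(np.arange(1, n_genes + 1), current)
    k = min(k, len(outside))
    if k == 0:
        return RegulatorNest(tuple(sorted(current)))
    slots = rng.choice(config.i_max, size=k, replace=False)
    new_genes = rng.choice(outside, size=k, replace=False)
    for slot, g in zip(slots, new_genes):
        current[slot] = int(g)
    return RegulatorNest(tuple(sorted(current)))


def abandon_worst(
    nests: list[RegulatorNest], n_genes: int, config: CsConfig, rng: np.random.Generator
) -> list[RegulatorNest]:
    """Replace the worst ceil(p_a * n) nests with fresh random combinations.

    The single best nest is never abandoned.  Fresh nests are returned
    unevaluated (fitness = +inf).
    """
    n = len(nests)
    n_replace = min(math.ceil(config.abandon_probability * n), n - 1)
    if n_replace <= 0:
        return list(nests)
    order = np.argsort([nest.fitness for nest in nests], kind="stable")
    worst = set(int(i) for i in order[n - n_replace:])
    out = list(nests)
    for i in range(n):
        if i in worst:
            out[i] = RegulatorNest(_random_combination(n_genes, config.i_max, rng))
    return out


def search_regulators(
    target_gene: int,
    dataset: ExpressionDataset,
    cs_config: CsConfig,
    fpa_config: FpaConfig,
    bounds: SearchBounds,
    evaluator: Callable[[tuple[int, ...]], tuple[np.ndarray, float]] | None = None,
) -> RegulatorNest:
    """Find the best regulator combination (and fitted parameters) for one gene.

    Runs generations of (Levy move -> FPA training -> greedy replacement ->
    abandonment).  ``evaluator`` maps a combination to (fitted params,
    fitness); by default it trains the decoupled one-step-ahead objective
    with the flower pollination optimizer, seeding each combination's run
    from (fpa seed, target gene, combination) so results are independent of
    visit order.  Fitness per combination is memoized.  The search stops as
    soon as any nest's fitness falls below ``fpa_config.fitness_tolerance``.
    """
    n_genes = dataset.n_genes
    if not 1 <= target_gene <= n_genes:
        raise ValueError(f"target_gene must be in 1..{n_genes}")
    if evaluator is None:
        from .inference import make_combination_evaluator

        evaluator = make_combination_evaluator(
            target_gene, dataset, fpa_config, bounds, i_max=cs_config.i_max
        )

    cache: dict[tuple[int, ...], tuple[np.ndarray, float]] = {}

    def evaluate(nest: RegulatorNest) -> RegulatorNest:
        key = tuple(sorted(nest.regulators))
        if key not in cache:
            cache[key] = evaluator(key)
        params, fitness = cache[key]
        nest.best_params = np.asarray(params, dtype=float)
        nest.fitness = float(fitness)
        return nest

    def copy_of(nest: RegulatorNest) -> RegulatorNest:
        return RegulatorNest(
            nest.regulators,
            None if nest.best_params is None else nest.best_params.copy(),
            nest.fitness,
        )

    rng = np.random.default_rng(cs_config.seed)
    nests = initialize_nests(n_genes, cs_config, rng)
    best: RegulatorNest | None = None
    for nest in nests:
        evaluate(nest)
        if best is None or nest.fitness < best.fitness:
            best = copy_of(nest)
        if best.fitness < fpa_config.fitness_tolerance:
            return best

    for _ in range(cs_config.n_generations):
        for i, nest in enumerate(nests):
            candidate = evaluate(levy_move(nest, n_genes, cs_config, rng))
            if candidate.fitness <= nest.fitness:
                nests[i] = candidate
            if candidate.fitness < best.fitness:
                best = copy_of(candidate)
            if best.fitness < fpa_config.fitness_tolerance:
                return best
        nests = abandon_worst(nests, n_genes, cs_config, rng)
        for i, nest in enumerate(nests):
            if nest.best_params is None:
                evaluate(nest)
                if nest.fitness < best.fitness:
                    best = copy_of(nest)
                if best.fitness < fpa_config.fitness_tolerance:
                    return best
    return best
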