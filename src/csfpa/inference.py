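"""Decoupled RNN network inference driven by cuckoo search + flower pollination.

The whole-network training problem — N(N+2) parameters for N genes — is
decoupled into N independent per-gene subproblems.  For each target gene a
cuckoo search proposes combinations of at most ``i_max`` candidate
regulators; each combination is scored by fitting the (i_max + 2)-parameter
restricted RNN (i_max weights, one bias, one time constant) with the flower
pollination optimizer against one-step-ahead prediction error.  Training
uses teacher forcing: the prediction for time t+1 is computed from the
*observed* regulator expression at time t, so per-transition errors are
independent.  Fitted rows are assembled into a weight matrix and edges are
called by thresholding weight magnitude and taking the sign.

:class:`CSFPANetworkInference` wraps the pipeline as a scikit-learn style
estimator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator

from .benchmark import ExpressionDataset, SignedNetwork
from .cuckoo import CsConfig, RegulatorNest, search_regulators
from .dynamics import RnnNetworkModel, _clamp_tau
from .fpa import FpaConfig, SearchBounds, minimize

__all__ = [
    "BOUNDS_PRESETS",
    "DecoupledObjectiveSpec",
    "InferredNetwork",
    "parameter_bounds",
    "decoupled_fitness",
    "coupled_fitness",
    "make_combination_evaluator",
    "infer_gene",
    "infer_network",
    "call_edges",
    "CSFPANetworkInference",
]

#: Search boxes per parameter kind: (|w| limit, |bias| limit, (tau_lo, tau_hi)).
#: "artificial" is the 30-gene benchmark box; "ecoli" the SOS-network box.
BOUNDS_PRESETS: dict[str, tuple[float, float, tuple[float, float]]] = {
    "artificial": (25.0, 10.0, (0.0, 15.0)),
    "ecoli": (10.0, 10.0, (0.0, 10.0)),
}


def parameter_bounds(i_max: int, preset: str = "artificial") -> SearchBounds:
    """Box constraints for one gene's (i_max weights, bias, tau) vector."""
    if preset not in BOUNDS_PRESETS:
        raise ValueError(f"unknown bounds preset {preset!r}; choose from {sorted(BOUNDS_PRESETS)}")
    w_lim, b_lim, (t_lo, t_hi) = BOUNDS_PRESETS[preset]
    lower = np.array([-w_lim] * i_max + [-b_lim, t_lo])
    upper = np.array([w_lim] * i_max + [b_lim, t_hi])
    return SearchBounds(lower, upper)


@dataclass
class DecoupledObjectiveSpec:
    """One per-gene subproblem: target gene, candidate regulators, data.

    Gene indices are 1-based.  Self-regulation (target among regulators) is
    permitted by the formalism.
    """

    target_gene: int
    regulator_genes: tuple[int, ...]
    dataset: ExpressionDataset
    delta_t: float = 1.0

    def __post_init__(self) -> None:
        regs = tuple(int(g) for g in self.regulator_genes)
        if len(set(regs)) != len(regs):
            raise ValueError("regulator genes must be distinct")
        n = self.dataset.n_genes
        if not 1 <= self.target_gene <= n:
            raise ValueError(f"target_gene out of range 1..{n}")
        if any(not 1 <= g <= n for g in regs):
            raise ValueError(f"regulator gene out of range 1..{n}")
        self.regulator_genes = regs


def _transition_arrays(spec: DecoupledObjectiveSpec):
    """Stack the (t -> t+1) training pairs of every series.

    Returns (R, e_own, y): regulator expression at t, the target's own
    expression at t, and the target's observed expression at t+1.
    """
    ti = spec.target_gene - 1
    ri = [g - 1 for g in spec.regulator_genes]
    R = np.vstack([s[:-1][:, ri] for s in spec.dataset.series])
    e_own = np.concatenate([s[:-1, ti] for s in spec.dataset.series])
    y = np.concatenate([s[1:, ti] for s in spec.dataset.series])
    return R, e_own, y


def _batch_objective(spec: DecoupledObjectiveSpec):
    """Vectorized objective: (m, i_max+2) parameter rows -> m fitness values."""
    R, e_own, y = _transition_arrays(spec)
    k = len(spec.regulator_genes)
    dt = spec.delta_t

    def objective(P: np.ndarray) -> np.ndarray:
        P = np.atleast_2d(np.asarray(P, dtype=float))
        W, beta, tau = P[:, :k], P[:, k], P[:, k + 1]
        bad = ~np.all(np.isfinite(P), axis=1)
        tau = _clamp_tau(np.where(bad, 1.0, tau), dt)
        r = dt / tau
        pred = r * expit(R @ W.T + beta) + (1.0 - r) * e_own[:, None]
        res = pred - y[:, None]
        out = np.einsum("tm,tm->m", res, res)
        out[bad] = np.inf
        return out

    return objective


def decoupled_fitness(spec: DecoupledObjectiveSpec, params: np.ndarray) -> float:
    """One-step-ahead squared prediction error of the restricted gene model.

    ``params`` is (w_1..w_k, bias, tau).  Every transition t -> t+1 within
    each series contributes the squared difference between the predicted and
    observed target expression at t+1, with predictions computed from
    observed regulator values at t (teacher forcing).  Non-finite parameters
    yield +inf.
    """
    params = np.asarray(params, dtype=float)
    if params.shape != (len(spec.regulator_genes) + 2,):
        raise ValueError("params must be (weights..., bias, tau)")
    value = float(_batch_objective(spec)(params[None, :])[0])
    return value


def coupled_fitness(network: RnnNetworkModel, dataset: ExpressionDataset) -> float:
    """Whole-network one-step-ahead squared error, summed over all genes.

    The coupled counterpart of the per-gene objective: decoupling is exact
    in the sense that the sum of per-gene errors at the same parameters
    equals this quantity.
    """
    W, beta = network.weight_matrix, network.biases
    r = network.delta_t / _clamp_tau(network.taus, network.delta_t)
    total = 0.0
    for s in dataset.series:
        pred = r * expit(s[:-1] @ W.T + beta) + (1.0 - r) * s[:-1]
        total += float(np.sum((pred - s[1:]) ** 2))
    return total


def _derived_seed(master: int, *key: int) -> int:
    """Stable sub-stream seed below 2^31 from a master seed and an index key."""
    ss = np.random.SeedSequence(entropy=int(master), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def make_combination_evaluator(
    target_gene: int,
    dataset: ExpressionDataset,
    fpa_config: FpaConfig,
    bounds: SearchBounds,
    i_max: int,
):
    """Build the nest evaluator: combination -> (fitted params, fitness).

    Each combination's FPA run is seeded from (fpa seed, target gene,
    combination), so a combination's fitness does not depend on when the
    search proposes it — brute-force enumeration with the same budget gives
    identical per-combination results.
    """
    if bounds.dim != i_max + 2:
        raise ValueError(f"bounds must have dimension i_max+2 = {i_max + 2}")

    def evaluate(combo: tuple[int, ...]):
        spec = DecoupledObjectiveSpec(target_gene, tuple(combo), dataset)
        cfg = FpaConfig(
            population_size=fpa_config.population_size,
            switch_probability=fpa_config.switch_probability,
            levy_exponent=fpa_config.levy_exponent,
            step_scale=fpa_config.step_scale,
            max_iterations=fpa_config.max_iterations,
            fitness_tolerance=fpa_config.fitness_tolerance,
            stagnation_window=fpa_config.stagnation_window,
            stagnation_tolerance=fpa_config.stagnation_tolerance,
            seed=_derived_seed(fpa_config.seed, target_gene, *sorted(combo)),
        )
        result = minimize(_batch_objective(spec), bounds, cfg, vectorized=True)
        return result.best_position, result.best_fitness

    return evaluate


def infer_gene(
    target_gene: int,
    dataset: ExpressionDataset,
    cs_config: CsConfig,
    fpa_config: FpaConfig,
    bounds: SearchBounds | None = None,
) -> RegulatorNest:
    """Infer one gene's regulators and parameters (one row of the model).

    The cuckoo search's own randomness is seeded from (cs seed, target gene)
    so genes can be processed in any order with identical results.
    """
    if bounds is None:
        bounds = parameter_bounds(cs_config.i_max)
    gene_cs = CsConfig(
        n_nests=cs_config.n_nests,
        abandon_probability=cs_config.abandon_probability,
        levy_exponent=cs_config.levy_exponent,
        step_scale=cs_config.step_scale,
        n_generations=cs_config.n_generations,
        i_max=cs_config.i_max,
        seed=_derived_seed(cs_config.seed, target_gene),
    )
    evaluator = make_combination_evaluator(
        target_gene, dataset, fpa_config, bounds, i_max=cs_config.i_max
    )
    return search_regulators(target_gene, dataset, gene_cs, fpa_config, bounds, evaluator)


@dataclass
class InferredNetwork:
    """Assembled inference output: fitted parameters for every gene.

    ``weight_matrix[i, j]`` is the fitted effect of gene j+1 on gene i+1
    (zero outside that gene's selected regulators); each row has at most
    ``i_max`` nonzero entries.
    """

    weight_matrix: np.ndarray
    biases: np.ndarray
    taus: np.ndarray
    per_gene_fitness: np.ndarray
    regulators: list[tuple[int, ...]]
    edge_threshold: float = 0.1

    @property
    def n_genes(self) -> int:
        return self.weight_matrix.shape[0]


def call_edges(inferred: InferredNetwork) -> SignedNetwork:
    """Threshold fitted weights into a signed network.

    Entry (i, j) becomes sign(w_ij) when |w_ij| exceeds the edge threshold,
    else 0 (small fitted weights mean no regulation).
    """
    W = inferred.weight_matrix
    signs = np.where(np.abs(W) > inferred.edge_threshold, np.sign(W), 0.0)
    return SignedNetwork(signs)


def infer_network(
    dataset: ExpressionDataset,
    cs_config: CsConfig | None = None,
    fpa_config: FpaConfig | None = None,
    bounds: SearchBounds | None = None,
    edge_threshold: float = 0.1,
    checkpoint_dir: str | Path | None = None,
    progress: bool = False,
) -> InferredNetwork:
    """Infer the full network: run the per-gene search for every gene.

    The per-gene subproblems are independent.  With ``checkpoint_dir`` each
    finished gene is persisted as JSON and reloaded on rerun, so a long run
    can resume.
    """
    cs_config = cs_config or CsConfig()
    fpa_config = fpa_config or FpaConfig()
    if bounds is None:
        bounds = parameter_bounds(cs_config.i_max)
    n = dataset.n_genes
    W = np.zeros((n, n))
    biases = np.zeros(n)
    taus = np.zeros(n)
    fitness = np.zeros(n)
    regulators: list[tuple[int, ...]] = []

    ckpt = Path(checkpoint_dir) if checkpoint_dir else None
    if ckpt:
        ckpt.mkdir(parents=True, exist_ok=True)

    for gene in range(1, n + 1):
        record = None
        if ckpt:
            f = ckpt / f"gene_{gene:03d}.json"
            if f.exists():
                record = json.loads(f.read_text())
        if record is None:
            nest = infer_gene(gene, dataset, cs_config, fpa_config, bounds)
            record = {
                "gene": gene,
                "regulators": list(nest.regulators),
                "params": [float(v) for v in nest.best_params],
                "fitness": nest.fitness,
            }
            if ckpt:
                (ckpt / f"gene_{gene:03d}.json").write_text(json.dumps(record))
        regs = tuple(record["regulators"])
        params = np.asarray(record["params"], dtype=float)
        for slot, g in enumerate(regs):
            W[gene - 1, g - 1] = params[slot]
        biases[gene - 1] = params[len(regs)]
        taus[gene - 1] = params[len(regs) + 1]
        fitness[gene - 1] = record["fitness"]
        regulators.append(regs)
        if progress:
            print(
                f"gene {gene}/{n}: regulators={regs} fitness={record['fitness']:.3e}",
                flush=True,
            )

    return InferredNetwork(W, biases, taus, fitness, regulators, edge_threshold)


class CSFPANetworkInference(BaseEstimator):
    """Gene regulatory network inference as a scikit-learn estimator.

    Fits a sparse signed network to replicate time-series expression data
    (values expected in [0, 1]): for each gene, a cuckoo search selects at
    most ``i_max`` candidate regulators and a flower pollination optimizer
    fits the restricted RNN gene model against one-step-ahead prediction
    error.

    Parameters
    ----------
    i_max : int
        Maximum number of regulators per target gene.
    n_nests, n_generations, abandon_probability, cs_step_scale
        Cuckoo-search settings (population of regulator combinations).
    population_size, switch_probability, step_scale, max_iterations,
    fitness_tolerance, stagnation_window, stagnation_tolerance, levy_exponent
        Flower-pollination settings for each per-combination parameter fit.
    bounds : str or SearchBounds
        Parameter search box: preset name ("artificial" or "ecoli") or an
        explicit :class:`SearchBounds` of dimension ``i_max + 2``.
    edge_threshold : float
        Minimum |weight| for a fitted weight to be called as an edge.
    random_state : int
        Master seed; all per-gene and per-combination streams derive from it.

    Attributes
    ----------
    weight_matrix_ : ndarray of shape (N, N)
        Fitted weights; entry (i, j) is the effect of gene j+1 on gene i+1.
    biases_, taus_, fitness_ : ndarray of shape (N,)
        Fitted per-gene bias, time constant and training error.
    regulators_ : list of tuple
        Selected regulator combination per gene (1-based indices).
    network_ : SignedNetwork
        Called signed edges.

    Examples
    --------
    >>> from csfpa.benchmark import build_toy_network, generate_dataset
    >>> data = generate_dataset(build_toy_network(), n_series=3, n_timepoints=30)
    >>> est = CSFPANetworkInference(random_state=0).fit(data)
    >>> est.network_.n_edges <= data.n_genes * est.i_max
    True
    """

    def __init__(
        self,
        i_max: int = 3,
        n_nests: int = 10,
        n_generations: int = 30,
        abandon_probability: float = 0.25,
        cs_step_scale: float = 1.0,
        population_size: int = 25,
        switch_probability: float = 0.8,
        step_scale: float = 0.1,
        max_iterations: int = 500,
        fitness_tolerance: float = 1e-8,
        stagnation_window: int = 200,
        stagnation_tolerance: float = 1e-10,
        levy_exponent: float = 1.5,
        bounds: str | SearchBounds = "artificial",
        edge_threshold: float = 0.1,
        random_state: int = 0,
    ):
        self.i_max = i_max
        self.n_nests = n_nests
        self.n_generations = n_generations
        self.abandon_probability = abandon_probability
        self.cs_step_scale = cs_step_scale
        self.population_size = population_size
        self.switch_probability = switch_probability
        self.step_scale = step_scale
        self.max_iterations = max_iterations
        self.fitness_tolerance = fitness_tolerance
        self.stagnation_window = stagnation_window
        self.stagnation_tolerance = stagnation_tolerance
        self.levy_exponent = levy_exponent
        self.bounds = bounds
        self.edge_threshold = edge_threshold
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------
    @staticmethod
    def _as_dataset(X) -> ExpressionDataset:
        if isinstance(X, ExpressionDataset):
            return X
        if isinstance(X, (list, tuple)):
            return ExpressionDataset([np.asarray(s, dtype=float) for s in X])
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a (time, genes) matrix, a list of them, "
                             "or an ExpressionDataset")
        return ExpressionDataset([X])

    def _configs(self):
        cs = CsConfig(
            n_nests=self.n_nests,
            abandon_probability=self.abandon_probability,
            levy_exponent=self.levy_exponent,
            step_scale=self.cs_step_scale,
            n_generations=self.n_generations,
            i_max=self.i_max,
            seed=int(self.random_state),
        )
        fpa = FpaConfig(
            population_size=self.population_size,
            switch_probability=self.switch_probability,
            levy_exponent=self.levy_exponent,
            step_scale=self.step_scale,
            max_iterations=self.max_iterations,
            fitness_tolerance=self.fitness_tolerance,
            stagnation_window=self.stagnation_window,
            stagnation_tolerance=self.stagnation_tolerance,
            seed=int(self.random_state),
        )
        if isinstance(self.bounds, SearchBounds):
            box = self.bounds
        else:
            box = parameter_bounds(self.i_max, self.bounds)
        return cs, fpa, box

    # -- sklearn API -------------------------------------------------------
    def fit(self, X, y=None, checkpoint_dir=None, progress: bool = False):
        """Infer the network from time-series expression data ``X``."""
        data = self._as_dataset(X)
        if data.n_timepoints < 2:
            raise ValueError("need at least 2 time points per series")
        cs, fpa, box = self._configs()
        result = infer_network(
            data, cs, fpa, box,
            edge_threshold=self.edge_threshold,
            checkpoint_dir=checkpoint_dir,
            progress=progress,
        )
        self.n_features_in_ = data.n_genes
        self.gene_names_ = list(data.gene_names)
        self.result_ = result
        self.weight_matrix_ = result.weight_matrix
        self.biases_ = result.biases
        self.taus_ = result.taus
        self.fitness_ = result.per_gene_fitness
        self.regulators_ = result.regulators
        self.network_ = call_edges(result)
        return self

    def _fitted_model(self) -> RnnNetworkModel:
        return RnnNetworkModel.from_arrays(self.weight_matrix_, self.biases_, self.taus_)

    def predict(self, X) -> np.ndarray:
        """One-step-ahead predictions from observed states.

        For a (T, N) series returns the (T-1, N) matrix of predicted
        expression at times 2..T given the observed rows 1..T-1.
        """
        if not hasattr(self, "weight_matrix_"):
            raise AttributeError("estimator is not fitted yet; call fit first")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(f"X must be (time, {self.n_features_in_})")
        model = self._fitted_model()
        r = model.delta_t / _clamp_tau(model.taus, model.delta_t)
        return r * expit(X[:-1] @ model.weight_matrix.T + model.biases) + (1.0 - r) * X[:-1]

    def score(self, X, y=None) -> float:
        """Negative mean squared one-step-ahead prediction error."""
        X = np.asarray(X, dtype=float)
        pred = self.predict(X)
        return -float(np.mean((pred - X[1:]) ** 2))
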