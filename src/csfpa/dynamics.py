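"""Discrete-time recurrent neural network (RNN) model of gene expression.

Each gene's expression at the next time step is a convex blend of a sigmoid
response to the weighted expression of all genes and its own current level:

    e_i(t + dt) = (dt / tau_i) * f( sum_j w_ij * e_j(t) + beta_i )
                  + (1 - dt / tau_i) * e_i(t)

where ``f(z) = 1 / (1 + exp(-z))``, ``w_ij`` is the signed regulatory
strength of gene j on gene i, ``beta_i`` a basal (bias) level and ``tau_i``
a time constant controlling how fast gene i responds.  With ``tau_i >= dt``
and an initial state in [0, 1]^N every trajectory stays in [0, 1]^N.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "TAU_MIN_FACTOR",
    "RnnGeneModel",
    "RnnNetworkModel",
    "sigmoid",
    "step",
    "simulate",
]

#: Effective time constants are clamped to ``delta_t * TAU_MIN_FACTOR`` so the
#: update stays defined at the tau = 0 boundary of the search range.
TAU_MIN_FACTOR = 1e-3


def sigmoid(z):
    """Logistic function ``1 / (1 + exp(-z))``, numerically stable via expit."""
    return expit(z)


def _clamp_tau(tau: float | np.ndarray, delta_t: float):
    return np.maximum(tau, delta_t * TAU_MIN_FACTOR)


@dataclass
class RnnGeneModel:
    """Parameters governing a single gene's update rule.

    Parameters
    ----------
    weights
        Length-N vector of signed regulatory strengths; zero means no
        regulation by that gene.
    bias
        Basal expression term inside the sigmoid.
    tau
        Time constant (> 0); larger values mean slower dynamics.
    delta_t
        Time increment of the discrete update (default 1).
    index
        0-based position of this gene in the network's state vector; the
        update blends against ``expression[index]``.
    """

    weights: np.ndarray
    bias: float
    tau: float
    delta_t: float = 1.0
    index: int = 0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1:
            raise ValueError("weights must be a 1-D vector")
        if not np.isfinite(self.tau) or self.tau <= 0:
            raise ValueError(f"tau must be positive and finite, got {self.tau}")


@dataclass
class RnnNetworkModel:
    """A full network: one :class:`RnnGeneModel` per gene, shared delta_t."""

    gene_models: list[RnnGeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.gene_models)
        for i, gm in enumerate(self.gene_models):
            if gm.weights.shape != (n,):
                raise ValueError(
                    f"gene {i}: weight vector length {gm.weights.shape[0]} != n_genes {n}"
                )
            if gm.delta_t != self.gene_models[0].delta_t:
                raise ValueError("all gene models must share the same delta_t")
            gm.index = i

    @classmethod
    def from_arrays(
        cls,
        weights: np.ndarray,
        biases: np.ndarray,
        taus: np.ndarray,
        delta_t: float = 1.0,
    ) -> "RnnNetworkModel":
        """Build a network from an (N, N) weight matrix and length-N biases/taus.

        Row i of ``weights`` holds the regulatory inputs of gene i, i.e.
        ``weights[i, j]`` is the effect of gene j on gene i.
        """
        weights = np.asarray(weights, dtype=float)
        biases = np.asarray(biases, dtype=float)
        taus = np.asarray(taus, dtype=float)
        n = weights.shape[0]
        if weights.shape != (n, n):
            raise ValueError("weight matrix must be square")
        if biases.shape != (n,) or taus.shape != (n,):
            raise ValueError("biases and taus must have one entry per gene")
        models = [
            RnnGeneModel(weights[i].copy(), float(biases[i]), float(taus[i]), delta_t, i)
            for i in range(n)
        ]
        return cls(models)

    @property
    def n_genes(self) -> int:
        return len(self.gene_models)

    @property
    def delta_t(self) -> float:
        return self.gene_models[0].delta_t

    @property
    def weight_matrix(self) -> np.ndarray:
        return np.vstack([gm.weights for gm in self.gene_models])

    @property
    def biases(self) -> np.ndarray:
        return np.array([gm.bias for gm in self.gene_models])

    @property
    def taus(self) -> np.ndarray:
        return np.array([gm.tau for gm in self.gene_models])


def step(model: RnnGeneModel, expression_now: np.ndarray) -> float:
    """One update of a single gene given the current expression of all genes."""
    e = np.asarray(expression_now, dtype=float)
    if e.shape != model.weights.shape:
        raise ValueError(
            f"expression vector length {e.shape} does not match weights {model.weights.shape}"
        )
    tau = _clamp_tau(model.tau, model.delta_t)
    r = model.delta_t / tau
    return float(r * expit(model.weights @ e + model.bias) + (1.0 - r) * e[model.index])


def simulate(
    network: RnnNetworkModel, initial_expression: np.ndarray, n_steps: int
) -> np.ndarray:
    """Simulate the network for ``n_steps`` synchronous updates.

    Returns an ``(n_steps + 1, N)`` trajectory whose first row is the initial
    state.  All genes advance from the same previous row.
    """
    e0 = np.asarray(initial_expression, dtype=float)
    if e0.shape != (network.n_genes,):
        raise ValueError("initial_expression must have one entry per gene")
    if not np.all(np.isfinite(e0)):
        raise ValueError("initial_expression must be finite")
    if n_steps < 0:
        raise ValueError("n_steps must be non-negative")

    W = network.weight_matrix
    beta = network.biases
    r = network.delta_t / _clamp_tau(network.taus, network.delta_t)

    traj = np.empty((n_steps + 1, network.n_genes), dtype=float)
    traj[0] = e0
    for t in range(n_steps):
        e = traj[t]
        traj[t + 1] = r * expit(W @ e + beta) + (1.0 - r) * e
    return traj
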