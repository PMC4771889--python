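"""Synthetic gene-regulatory-network benchmarks and training-data generation.

Provides the standard sparse 30-gene artificial network (36 regulations,
all time constants 10, a handful of nonzero biases), replicate time-series
generation from the RNN dynamics, optional noise injection, and small toy
networks for fast end-to-end tests.

Gene indices in all user-facing structures are 1-based (``w[1,14]`` is the
effect of gene 14 on gene 1); arrays are indexed 0-based internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import RnnNetworkModel, simulate

__all__ = [
    "SignedNetwork",
    "ExpressionDataset",
    "build_table1_network",
    "build_toy_network",
    "generate_dataset",
    "add_noise",
    "extract_gold_standard",
]

# The 36 regulations of the 30-gene benchmark, keyed (target, regulator),
# 1-based: entry (i, j) = w_ij, the signed effect of gene j on gene i.
BENCHMARK_30_WEIGHTS: dict[tuple[int, int], float] = {
    (1, 14): -15, (5, 1): 10, (6, 1): -20, (7, 2): 15, (7, 3): 10,
    (8, 4): 20, (9, 5): -20, (9, 6): 10, (9, 17): 10, (10, 7): -10,
    (11, 4): -15, (11, 7): 15, (11, 22): -15, (12, 23): 10, (13, 8): 20,
    (14, 9): 15, (15, 10): -10, (16, 11): 15, (16, 12): -15, (17, 13): -20,
    (19, 14): -15, (20, 15): 10, (21, 16): -20, (23, 17): -10, (24, 15): -15,
    (24, 18): -20, (24, 19): 15, (25, 20): -10, (26, 11): 20, (26, 28): 20,
    (27, 24): -15, (27, 25): 10, (27, 30): 15, (28, 25): -15, (29, 26): 10,
    (30, 27): 15,
}
BENCHMARK_30_POSITIVE_BIAS = (2, 5, 6, 10, 16, 24, 28)   # beta_i = +5
BENCHMARK_30_NEGATIVE_BIAS = (15, 17, 27)                # beta_i = -5


@dataclass
class SignedNetwork:
    """Signed adjacency: entry (i, j) is the effect of gene j on gene i.

    The biologically meaningful content is the sign pattern: +1 activation,
    -1 inhibition, 0 no regulation.
    """

    adjacency: np.ndarray

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        n = self.adjacency.shape[0]
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency must be square")

    @property
    def n_genes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def signs(self) -> np.ndarray:
        """Integer {-1, 0, +1} sign matrix."""
        return np.sign(self.adjacency).astype(int)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.adjacency))

    def edges(self) -> list[tuple[int, int, int]]:
        """Edge list of (regulator, target, sign), 1-based gene indices."""
        out = []
        tgt, reg = np.nonzero(self.adjacency)
        for i, j in zip(tgt, reg):
            out.append((int(j) + 1, int(i) + 1, int(np.sign(self.adjacency[i, j]))))
        return out


@dataclass
class ExpressionDataset:
    """Replicate time-series expression data: M series of (T, N) matrices."""

    series: list[np.ndarray]
    gene_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.series = [np.asarray(s, dtype=float) for s in self.series]
        if not self.series:
            raise ValueError("dataset needs at least one series")
        n = self.series[0].shape[1]
        for k, s in enumerate(self.series):
            if s.ndim != 2 or s.shape[1] != n:
                raise ValueError(f"series {k} has inconsistent gene dimension")
            if not np.all(np.isfinite(s)):
                raise ValueError(f"series {k} contains non-finite values")
        if not self.gene_names:
            self.gene_names = [f"G{i + 1}" for i in range(n)]
        if len(self.gene_names) != n:
            raise ValueError("gene_names length must match the number of genes")

    @property
    def n_genes(self) -> int:
        return self.series[0].shape[1]

    @property
    def n_series(self) -> int:
        return len(self.series)

    @property
    def n_timepoints(self) -> int:
        return self.series[0].shape[0]


def build_table1_network() -> RnnNetworkModel:
    """The 30-gene artificial benchmark network.

    36 signed weights of magnitude 10-20, biases +/-5 on ten genes, all time
    constants 10, time step 1.
    """
    n = 30
    W = np.zeros((n, n))
    for (i, j), w in BENCHMARK_30_WEIGHTS.items():
        W[i - 1, j - 1] = w
    beta = np.zeros(n)
    beta[[i - 1 for i in BENCHMARK_30_POSITIVE_BIAS]] = 5.0
    beta[[i - 1 for i in BENCHMARK_30_NEGATIVE_BIAS]] = -5.0
    tau = np.full(n, 10.0)
    return RnnNetworkModel.from_arrays(W, beta, tau, delta_t=1.0)


def build_toy_network() -> RnnNetworkModel:
    """A 5-gene sparse test network with at most two regulators per gene.

    Genes 2, 5 and 3 form a negative feedback loop (2 -> 5 -> 3 -| 2), which
    keeps trajectories away from saturated fixed points so every regulation
    is identifiable from the dynamics; genes 1 and 4 hang off the loop.
    All weight magnitudes are >= 10 and biases roughly center each gene's
    sigmoid input so expression explores the full [0, 1] range.
    """
    W = np.zeros((5, 5))
    W[0, 1] = 10.0    # gene 2 activates gene 1
    W[0, 4] = -15.0   # gene 5 inhibits gene 1
    W[1, 2] = -12.0   # gene 3 inhibits gene 2
    W[2, 4] = 12.0    # gene 5 activates gene 3
    W[3, 2] = 10.0    # gene 3 activates gene 4
    W[4, 1] = 15.0    # gene 2 activates gene 5
    beta = np.array([2.5, 6.0, -6.0, -5.0, -7.5])
    tau = np.full(5, 10.0)
    return RnnNetworkModel.from_arrays(W, beta, tau, delta_t=1.0)


def generate_dataset(
    network: RnnNetworkModel,
    n_series: int = 5,
    n_timepoints: int = 50,
    seed: int = 0,
) -> ExpressionDataset:
    """Generate replicate training series by simulating the network.

    Each series starts from an independent uniform-random initial state in
    [0, 1]^N and runs ``n_timepoints - 1`` synchronous updates, giving a
    (n_timepoints, N) matrix per series.  The defaults (5 series of 50 time
    points) match the benchmark protocol.
    """
    if n_timepoints < 2:
        raise ValueError("n_timepoints must be at least 2")
    rng = np.random.default_rng(seed)
    series = []
    for _ in range(n_series):
        e0 = rng.uniform(0.0, 1.0, size=network.n_genes)
        series.append(simulate(network, e0, n_timepoints - 1))
    return ExpressionDataset(series)


def add_noise(
    dataset: ExpressionDataset,
    noise_level: float,
    seed: int = 0,
    kind: str = "multiplicative",
) -> ExpressionDataset:
    """Return a noisy copy of the dataset, clipped to [0, 1].

    ``kind="multiplicative"`` (default): each value x becomes
    x * (1 + eps), eps ~ Normal(0, noise_level^2) — the conventional reading
    of "x% noise" on expression data.  ``kind="additive"``: x + eps with
    eps ~ Normal(0, noise_level^2).
    """
    if noise_level < 0:
        raise ValueError("noise_level must be non-negative")
    if kind not in ("multiplicative", "additive"):
        raise ValueError(f"unknown noise kind: {kind!r}")
    if noise_level == 0:
        return ExpressionDataset([s.copy() for s in dataset.series], list(dataset.gene_names))
    rng = np.random.default_rng(seed)
    out = []
    for s in dataset.series:
        eps = rng.normal(0.0, noise_level, size=s.shape)
        noisy = s * (1.0 + eps) if kind == "multiplicative" else s + eps
        out.append(np.clip(noisy, 0.0, 1.0))
    return ExpressionDataset(out, list(dataset.gene_names))


def extract_gold_standard(network: RnnNetworkModel) -> SignedNetwork:
    """Signed adjacency of the generating weights (the gold standard)."""
    return SignedNetwork(np.sign(network.weight_matrix))
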