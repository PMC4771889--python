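import math

import numpy as np
import pytest
from sklearn.base import clone

from csfpa.benchmark import ExpressionDataset, generate_dataset
from csfpa.cuckoo import CsConfig
from csfpa.fpa import FpaConfig, SearchBounds
from csfpa.inference import (
    CSFPANetworkInference,
    DecoupledObjectiveSpec,
    InferredNetwork,
    call_edges,
    coupled_fitness,
    decoupled_fitness,
    infer_gene,
    infer_network,
    parameter_bounds,
)


def _generating_params(network, gene, regulators):
    """(w..., bias, tau) of the generating network restricted to `regulators`."""
    w = [network.weight_matrix[gene - 1, g - 1] for g in regulators]
    return np.array(w + [network.biases[gene - 1], network.taus[gene - 1]])


class TestDecoupledFitness:
    def test_two_point_fixture_matches_hand_arithmetic(self):
        # 1 series, T=2: single transition; regulator gene 2, target gene 1
        data = ExpressionDataset([np.array([[0.2, 0.4], [0.6, 0.9]])])
        spec = DecoupledObjectiveSpec(1, (2,), data)
        w, beta, tau = 2.0, 0.5, 5.0
        pred = (1 / tau) / (1 + math.exp(-(w * 0.4 + beta))) + (1 - 1 / tau) * 0.2
        expected = (pred - 0.6) ** 2
        assert decoupled_fitness(spec, np.array([w, beta, tau])) == pytest.approx(
            expected, rel=1e-14
        )

    def test_generating_parameters_give_machine_zero(self, toy_network, toy_dataset):
        for gene in range(1, 6):
            regs = tuple(
                int(j) + 1 for j in np.nonzero(toy_network.weight_matrix[gene - 1])[0]
            ) or (gene,)
            spec = DecoupledObjectiveSpec(gene, regs, toy_dataset)
            fit = decoupled_fitness(spec, _generating_params(toy_network, gene, regs))
            assert fit < 1e-20

    def test_non_negative(self, toy_dataset):
        spec = DecoupledObjectiveSpec(1, (2, 3), toy_dataset)
        rng = np.random.default_rng(0)
        for _ in range(30):
            params = rng.uniform(-20, 20, size=4)
            params[3] = abs(params[3]) + 0.5
            assert decoupled_fitness(spec, params) >= 0.0

    def test_nonfinite_params_give_infinity(self, toy_dataset):
        spec = DecoupledObjectiveSpec(1, (2,), toy_dataset)
        assert decoupled_fitness(spec, np.array([np.nan, 0.0, 5.0])) == np.inf

    def test_wrong_param_length(self, toy_dataset):
        spec = DecoupledObjectiveSpec(1, (2, 3), toy_dataset)
        with pytest.raises(ValueError, match="params"):
            decoupled_fitness(spec, np.zeros(3))

    def test_duplicate_regulators_rejected(self, toy_dataset):
        with pytest.raises(ValueError, match="distinct"):
            DecoupledObjectiveSpec(1, (2, 2), toy_dataset)


class TestDecouplingEquivalence:
    def test_sum_of_per_gene_errors_equals_coupled_objective(self, toy_network, toy_dataset):
        # at arbitrary (not just generating) parameters, with every gene as
        # its own regulator set, the decoupled errors must sum to the coupled one
        rng = np.random.default_rng(4)
        n = toy_network.n_genes
        W = rng.uniform(-10, 10, size=(n, n))
        beta = rng.uniform(-5, 5, size=n)
        tau = rng.uniform(2, 15, size=n)
        from csfpa.dynamics import RnnNetworkModel

        net = RnnNetworkModel.from_arrays(W, beta, tau)
        total = 0.0
        all_genes = tuple(range(1, n + 1))
        for gene in all_genes:
            spec = DecoupledObjectiveSpec(gene, all_genes, toy_dataset)
            params = np.concatenate([W[gene - 1], [beta[gene - 1], tau[gene - 1]]])
            total += decoupled_fitness(spec, params)
        assert total == pytest.approx(coupled_fitness(net, toy_dataset), rel=1e-12)


class TestCallEdges:
    def _inferred(self, W, threshold=0.5):
        n = W.shape[0]
        return InferredNetwork(W, np.zeros(n), np.full(n, 10.0), np.zeros(n),
                               [()] * n, edge_threshold=threshold)

    def test_thresholding(self):
        W = np.array([[0.0, 0.3], [-15.0, 0.0]])
        net = call_edges(self._inferred(W, threshold=0.5))
        assert net.signs[0, 1] == 0      # below threshold: no edge
        assert net.signs[1, 0] == -1     # strong negative weight: inhibition
        assert net.n_edges == 1

    def test_zero_matrix(self):
        assert call_edges(self._inferred(np.zeros((3, 3)))).n_edges == 0


class TestInferGene:
    def test_true_regulator_recovered_with_sign(self, chain4_network):
        data = generate_dataset(chain4_network, 5, 50, seed=3)
        cs = CsConfig(n_nests=4, n_generations=10, seed=0)
        fpa = FpaConfig(max_iterations=400, seed=0)
        nest = infer_gene(1, data, cs, fpa)
        assert 3 in nest.regulators
        assert nest.best_params[nest.regulators.index(3)] > 1.0

    def test_order_independent_seeding(self, chain4_network):
        # per-gene derived seeds: inferring gene 2 alone equals inferring it
        # after other genes (no shared random state)
        data = generate_dataset(chain4_network, 3, 30, seed=5)
        cs = CsConfig(n_nests=4, n_generations=5, seed=1)
        fpa = FpaConfig(max_iterations=150, seed=1)
        alone = infer_gene(2, data, cs, fpa)
        infer_gene(1, data, cs, fpa)
        again = infer_gene(2, data, cs, fpa)
        assert alone.regulators == again.regulators
        assert alone.fitness == again.fitness


@pytest.fixture(scope="module")
def small_run(chain4_network):
    data = generate_dataset(chain4_network, 5, 50, seed=3)
    cs = CsConfig(n_nests=4, n_generations=8, seed=0)
    fpa = FpaConfig(max_iterations=300, seed=0)
    return infer_network(data, cs, fpa), data


class TestInferNetwork:
    def test_row_sparsity(self, small_run):
        inferred, _ = small_run
        for row in inferred.weight_matrix:
            assert np.count_nonzero(row) <= 3

    def test_called_edges_bounded_by_sparsity_cap(self, small_run):
        inferred, data = small_run
        assert call_edges(inferred).n_edges <= data.n_genes * 3

    def test_checkpoint_resume_reproduces_result(self, chain4_network, tmp_path):
        data = generate_dataset(chain4_network, 3, 30, seed=5)
        cs = CsConfig(n_nests=4, n_generations=3, seed=2)
        fpa = FpaConfig(max_iterations=100, seed=2)
        first = infer_network(data, cs, fpa, checkpoint_dir=tmp_path)
        assert len(list(tmp_path.glob("gene_*.json"))) == 4
        resumed = infer_network(data, cs, fpa, checkpoint_dir=tmp_path)
        np.testing.assert_array_equal(first.weight_matrix, resumed.weight_matrix)
        np.testing.assert_array_equal(first.per_gene_fitness, resumed.per_gene_fitness)


class TestEstimator:
    def test_sklearn_params_round_trip(self):
        est = CSFPANetworkInference(i_max=2, random_state=3)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        cloned.set_params(edge_threshold=0.2)
        assert cloned.edge_threshold == 0.2

    def test_fit_predict_score(self, chain4_network):
        data = generate_dataset(chain4_network, 3, 25, seed=5)
        est = CSFPANetworkInference(
            n_nests=4, n_generations=3, max_iterations=100, random_state=0
        ).fit(data)
        assert est.n_features_in_ == 4
        assert est.weight_matrix_.shape == (4, 4)
        X = data.series[0]
        pred = est.predict(X)
        assert pred.shape == (X.shape[0] - 1, 4)
        assert est.score(X) <= 0.0

    def test_accepts_plain_matrix_and_list(self, chain4_network):
        data = generate_dataset(chain4_network, 2, 20, seed=5)
        est = CSFPANetworkInference(
            n_nests=2, n_generations=1, max_iterations=50, random_state=0
        )
        est.fit(data.series[0])           # single (T, N) matrix
        assert est.n_features_in_ == 4
        est.fit(list(data.series))        # list of matrices
        assert est.n_features_in_ == 4

    def test_predict_before_fit_raises(self):
        with pytest.raises(AttributeError, match="not fitted"):
            CSFPANetworkInference().predict(np.zeros((3, 4)))

    def test_unknown_bounds_preset(self, chain4_network):
        data = generate_dataset(chain4_network, 1, 5, seed=0)
        with pytest.raises(ValueError, match="preset"):
            CSFPANetworkInference(bounds="nonsense").fit(data)

    def test_explicit_bounds_accepted(self, chain4_network):
        data = generate_dataset(chain4_network, 2, 15, seed=5)
        box = SearchBounds(np.array([-5.0] * 2 + [-5.0, 0.1]),
                           np.array([5.0] * 2 + [5.0, 12.0]))
        est = CSFPANetworkInference(
            i_max=2, n_nests=2, n_generations=1, max_iterations=50,
            bounds=box, random_state=0,
        ).fit(data)
        assert np.all(np.abs(est.weight_matrix_) <= 5.0)


class TestBoundsPresets:
    def test_artificial_box(self):
        b = parameter_bounds(3, "artificial")
        np.testing.assert_array_equal(b.lower, [-25, -25, -25, -10, 0])
        np.testing.assert_array_equal(b.upper, [25, 25, 25, 10, 15])

    def test_ecoli_box(self):
        b = parameter_bounds(3, "ecoli")
        np.testing.assert_array_equal(b.lower, [-10, -10, -10, -10, 0])
        np.testing.assert_array_equal(b.upper, [10, 10, 10, 10, 10])
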