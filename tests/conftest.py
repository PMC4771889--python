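import numpy as np
import pytest

from csfpa.benchmark import (
    build_table1_network,
    build_toy_network,
    extract_gold_standard,
    generate_dataset,
)


@pytest.fixture(scope="session")
def table1_network():
    return build_table1_network()


@pytest.fixture(scope="session")
def table1_dataset(table1_network):
    """The benchmark training protocol: 5 replicate series of 50 time points."""
    return generate_dataset(table1_network, n_series=5, n_timepoints=50, seed=1)


@pytest.fixture(scope="session")
def toy_network():
    return build_toy_network()


@pytest.fixture(scope="session")
def toy_gold(toy_network):
    return extract_gold_standard(toy_network)


@pytest.fixture(scope="session")
def toy_dataset(toy_network):
    return generate_dataset(toy_network, n_series=5, n_timepoints=50, seed=7)


@pytest.fixture(scope="session")
def chain4_network():
    """4-gene network where gene 1 is regulated only by gene 3."""
    from csfpa.dynamics import RnnNetworkModel

    W = np.zeros((4, 4))
    W[0, 2] = 12.0   # gene 3 activates gene 1
    W[2, 1] = -10.0  # gene 2 inhibits gene 3 (keeps gene 3 moving)
    W[1, 0] = 10.0   # gene 1 activates gene 2
    beta = np.array([-6.0, -5.0, 5.0, 0.0])
    return RnnNetworkModel.from_arrays(W, beta, np.full(4, 10.0))
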