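import numpy as np
import pytest

import graphuq as gq


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_graph(rng, n=6, d=4, edge_prob=0.4, label=None):
    """A random valid attributed graph for property tests."""
    upper = np.triu(rng.random((n, n)) < edge_prob, k=1)
    adjacency = (upper | upper.T).astype(np.int8)
    features = rng.normal(size=(n, d))
    return gq.AttributedGraph(features=features, adjacency=adjacency, label=label)


@pytest.fixture
def path3():
    """3-node path 0-1-2 with distinct single-channel features."""
    adjacency = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=np.int8)
    features = np.array([[1.0], [2.0], [3.0]])
    return gq.AttributedGraph(features=features, adjacency=adjacency, label=0)


@pytest.fixture
def triangle():
    adjacency = np.ones((3, 3), dtype=np.int8) - np.eye(3, dtype=np.int8)
    features = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
    return gq.AttributedGraph(features=features, adjacency=adjacency, label=1)


@pytest.fixture(scope="session")
def tiny_spec():
    return gq.GNNSpec(input_dim=4, hidden_dims=(5, 6), class_count=2)


@pytest.fixture(scope="session")
def tiny_decoder(tiny_spec):
    return gq.init_decoder(tiny_spec, latent_dim=3, hidden=(8, 8, 8), seed=7)


@pytest.fixture(scope="session")
def tiny_omega(tiny_spec, tiny_decoder):
    return gq.decode_parameters(tiny_decoder, np.array([0.3, -0.2, 0.1]))


@pytest.fixture(scope="session")
def motif_dataset():
    """Small planted-motif dataset shared across tests (read-only)."""
    ds = gq.generate_motif_dataset(gq.SyntheticConfig(n_graphs=60, seed=11))
    gq.split_dataset(ds, mode="random", seed=11)
    return ds


@pytest.fixture(scope="session")
def benchmark_results():
    """One full end-to-end benchmark run, reused by the acceptance checks."""
    from graphuq.benchmark import run_motif_benchmark

    return run_motif_benchmark(seed=1)
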