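import numpy as np
import pytest

from fcgraph.cohort import SyntheticConfig, coupling_matrix, simulate_subject
from fcgraph.connectivity import ConnectivityGraph


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Small grid, four planted clusters, low noise."""
    return SyntheticConfig(
        grid_shape=(6, 6, 3), n_latent_clusters=4, noise_sd=0.1, seed=42
    )


@pytest.fixture(scope="session")
def subject(small_config):
    return simulate_subject(small_config, "C", seed=7)


@pytest.fixture(scope="session")
def two_block_subject():
    """Two planted blocks with uncorrelated latent signals, minimal noise."""
    config = SyntheticConfig(
        grid_shape=(6, 4, 2),
        n_latent_clusters=2,
        coupling={c: coupling_matrix(2, 0.0) for c in ("C", "MCI", "AD")},
        noise_sd=0.01,
        seed=3,
    )
    return simulate_subject(config, "C", seed=5)


def make_graph(weights, directed=False) -> ConnectivityGraph:
    weights = np.asarray(weights, dtype=float)
    return ConnectivityGraph(
        weights=weights, directed=directed, node_ids=list(range(1, len(weights) + 1))
    )


@pytest.fixture
def graph_factory():
    return make_graph


def random_graph(rng, n, density=0.6, directed=False) -> ConnectivityGraph:
    w = rng.uniform(0.05, 1.0, size=(n, n))
    w *= rng.random((n, n)) < density
    np.fill_diagonal(w, 0.0)
    if not directed:
        w = np.triu(w, 1)
        w = w + w.T
    return make_graph(w, directed=directed)
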