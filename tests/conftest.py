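import numpy as np
import pytest

from hypergraphmt import Hypergraph, PlantedConfig, planted_state, sample_hypergraph


def random_instance(rng, n_max=12, d_max=4, k_max=3, density=0.4):
    """Random (u, w, hypergraph) triple at oracle-checkable scale."""
    N = int(rng.integers(4, n_max + 1))
    K = int(rng.integers(1, k_max + 1))
    D = int(rng.integers(2, d_max + 1))
    u = rng.uniform(size=(N, K))
    u[rng.uniform(size=(N, K)) < 0.2] = 0.0  # exercise exact zeros
    w = rng.uniform(size=(D - 1, K))
    edges = []
    seen = set()
    for _ in range(int(rng.integers(3, 2 * N))):
        d = int(rng.integers(2, D + 1))
        e = tuple(sorted(rng.choice(N, size=d, replace=False).tolist()))
        if e not in seen:
            seen.add(e)
            edges.append((e, int(rng.integers(1, 4))))
    h = Hypergraph([f"n{i}" for i in range(N)], edges)
    return u, w, h


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def tiny_hypergraph():
    """Three nodes, one pair and one triangle hyperedge."""
    return Hypergraph(["a", "b", "c"], [((0, 1), 2), ((0, 1, 2), 1)])


@pytest.fixture(scope="session")
def planted_small():
    """Two-block benchmark at reduced size, with its ground truth."""
    cfg = PlantedConfig(N=50, K=2, D_max=3, w=(0.1, 0.01), overlap=0.0, seed=7)
    state = planted_state(cfg)
    h = sample_hypergraph(state, seed=7)
    return cfg, state, h
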