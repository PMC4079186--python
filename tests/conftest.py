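import numpy as np
import pytest

from cohub import WeightedNetwork, generate_random_network


@pytest.fixture
def path3():
    """Path A-B (0.3), B-C (0.7)."""
    return WeightedNetwork.from_edges(
        [("A", "B", 0.3), ("B", "C", 0.7)], nodes=["A", "B", "C"]
    )


@pytest.fixture
def k4_distinct():
    """Complete graph on 4 nodes with 6 distinct weights."""
    nodes = ["A", "B", "C", "D"]
    weights = [0.05, 0.15, 0.35, 0.55, 0.75, 0.95]
    edges = []
    k = 0
    for i in range(4):
        for j in range(i + 1, 4):
            edges.append((nodes[i], nodes[j], weights[k]))
            k += 1
    return WeightedNetwork.from_edges(edges, nodes=nodes)


@pytest.fixture
def uniform_net():
    """Complete 6-node network, all weights equal (the P = 1 fixture)."""
    return generate_random_network(6, ("constant", {"value": 0.4}), seed=0)


def random_weighted_network(rng, n_nodes=None, complete=True):
    """Seeded helper for property tests."""
    if n_nodes is None:
        n_nodes = int(rng.integers(2, 9))
    if complete:
        return generate_random_network(n_nodes, ("uniform", {}), seed=int(rng.integers(2**31)))
    u, v = np.triu_indices(n_nodes, k=1)
    keep = rng.random(len(u)) < 0.6
    if not keep.any():
        keep[0] = True
    nodes = [f"n{i}" for i in range(n_nodes)]
    edges = [
        (nodes[a], nodes[b], float(rng.random()))
        for a, b in zip(u[keep], v[keep])
    ]
    return WeightedNetwork.from_edges(edges, nodes=nodes)
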