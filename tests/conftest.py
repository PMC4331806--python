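import numpy as np
import pytest

from ishc.network_model import PPINetwork


@pytest.fixture
def triangle_net() -> PPINetwork:
    """Unit-weight triangle a-b-c."""
    return PPINetwork(
        nodes=["a", "b", "c"],
        weights={("a", "b"): 1.0, ("b", "c"): 1.0, ("a", "c"): 1.0},
    )


@pytest.fixture
def two_blob_coords() -> np.ndarray:
    """Two tight 5-point blobs separated by ~10x their internal spread."""
    rng = np.random.default_rng(42)
    blob1 = rng.normal(0.0, 0.01, size=(5, 3))
    blob2 = rng.normal(0.0, 0.01, size=(5, 3)) + np.array([1.0, 0.0, 0.0])
    return np.vstack([blob1, blob2])


def random_network(rng: np.random.Generator, n: int, p: float = 0.5, weighted: bool = True) -> PPINetwork:
    """Erdos-Renyi-style random network helper for oracle comparisons."""
    nodes = [f"v{i}" for i in range(n)]
    weights = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.uniform() < p:
                w = float(rng.uniform(0.5, 2.0)) if weighted else 1.0
                weights[(nodes[i], nodes[j])] = w
    return PPINetwork(nodes=nodes, weights=weights)
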