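import numpy as np
import pytest

from swpnet.synth import BackboneSpec, WeightedGraph, generate_toy_graph


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def triangle_graph():
    w = np.array([[0.0, 0.2, 0.4], [0.2, 0.0, 0.8], [0.4, 0.8, 0.0]])
    return WeightedGraph(weights=w)


@pytest.fixture
def path3_graph():
    w = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
    return WeightedGraph(weights=w)


@pytest.fixture
def random_graph6(rng):
    spec = BackboneSpec(kind="erdos_renyi", n=6, k=3, weight_low=0.1, weight_high=1.0)
    return generate_toy_graph(spec, seed=7)


def random_weighted_matrix(rng, n, density=0.5):
    """Random symmetric nonnegative test matrix with zero diagonal."""
    w = np.triu(rng.uniform(0.1, 1.0, size=(n, n)), 1)
    w *= np.triu(rng.random((n, n)) < density, 1)
    return w + w.T
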