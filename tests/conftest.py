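import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cliquecav as cc

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def net_from_edges(n, weighted_edges):
    """WeightedNetwork from {(i, j): w}."""
    w = np.zeros((n, n))
    for (a, b), wt in weighted_edges.items():
        w[a, b] = w[b, a] = wt
    return cc.WeightedNetwork(w)


def random_er_network(n, p, rng):
    """Erdos-Renyi graph with i.i.d. uniform (distinct a.s.) weights."""
    mask = np.triu(rng.random((n, n)) < p, 1)
    w = np.triu(rng.random((n, n)), 1) * mask
    return cc.WeightedNetwork(w + w.T)


@pytest.fixture
def square():
    net, gt = cc.planted_cavity_network(cc.square_cavity_spec())
    return net, gt


@pytest.fixture
def octahedron():
    net, gt = cc.planted_cavity_network(cc.octahedron_cavity_spec())
    return net, gt


@pytest.fixture
def triangle_pendant():
    """Triangle {0,1,2} plus pendant edge (2,3)."""
    return net_from_edges(4, {(0, 1): 4, (1, 2): 3, (0, 2): 2, (2, 3): 1})
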