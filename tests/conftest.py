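import numpy as np
import pytest

from mpxwalk import GeneSet, NetworkLayer, make_multiplex_from_layers
from mpxwalk.fixtures import er_layers, tau_toy, three_layer_toy


@pytest.fixture
def toy3():
    """Three layers over union {a,b,c,d}; node b absent from layer 3."""
    return three_layer_toy()


@pytest.fixture
def tau_mpx():
    """Layer 1 = path A-B, layer 2 = clique ABCD."""
    return tau_toy()


@pytest.fixture
def two_layer_pair():
    """Two identical single-edge layers A-B (simplest coupled multiplex)."""
    layers = [
        NetworkLayer("l1", [("A", "B", 1.0)]),
        NetworkLayer("l2", [("A", "B", 1.0)]),
    ]
    return make_multiplex_from_layers(layers, delta=0.5)


@pytest.fixture
def er_mpx():
    """Small seeded ER multiplex (3 layers, 20 nodes)."""
    return make_multiplex_from_layers(er_layers(20, 3, p=0.2, rng_seed=7))


def random_multiplex(rng: np.random.Generator, max_supra: int = 200):
    """A random small multiplex with n*L <= max_supra (oracle-sized)."""
    L = int(rng.integers(1, 4))
    n = int(rng.integers(3, max(4, max_supra // L + 1)))
    n = min(n, max_supra // L)
    layers = []
    names = [f"g{i:03d}" for i in range(n)]
    for l in range(L):
        # each layer spans a random subset of the universe
        k = int(rng.integers(2, n + 1))
        sub = sorted(rng.choice(n, size=k, replace=False))
        edges = set()
        # random spanning chain keeps the layer non-empty and connected-ish
        for a, b in zip(sub[:-1], sub[1:]):
            edges.add((names[a], names[b]))
        extra = int(rng.integers(0, max(1, k)))
        for _ in range(extra):
            a, b = rng.choice(sub, size=2, replace=False)
            u, v = names[min(a, b)], names[max(a, b)]
            edges.add((u, v))
        w = rng.uniform(0.5, 2.0, size=len(edges))
        layers.append(
            NetworkLayer(
                f"L{l}", [(u, v, float(x)) for (u, v), x in zip(sorted(edges), w)]
            )
        )
    delta = float(rng.uniform(0.0, 1.0))
    mode = "presence" if rng.random() < 0.7 else "union"
    return make_multiplex_from_layers(layers, delta=delta, coupling_mode=mode)


def random_seed_set(rng: np.random.Generator, mpx) -> GeneSet:
    k = int(rng.integers(1, min(4, mpx.n_nodes) + 1))
    members = sorted(rng.choice(mpx.nodes, size=k, replace=False))
    return GeneSet("rand", list(members))
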