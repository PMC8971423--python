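import random

import networkx as nx
import pytest

from entroloc import ContactNetwork, InfectionSnapshot


@pytest.fixture
def three_path():
    """Path a–b–c, everyone infected: the smallest worked entropy example."""
    net = ContactNetwork.from_edges([("a", "b"), ("b", "c")])
    snap = InfectionSnapshot(network=net, infected=frozenset("abc"))
    return net, snap


@pytest.fixture
def star_factory():
    """Star with a named center and L leaves."""

    def make(leaves: int, center: str = "c") -> ContactNetwork:
        return ContactNetwork.from_edges(
            [(center, f"l{k}") for k in range(leaves)]
        )

    return make


def random_infected_instance(seed: int, n_max: int = 50):
    """A random ER graph with a random non-empty infected subset."""
    rng = random.Random(seed)
    n = rng.randint(4, n_max)
    p = rng.uniform(0.08, 0.3)
    g = nx.gnp_random_graph(n, p, seed=seed)
    g = nx.relabel_nodes(g, {v: str(v) for v in g.nodes})
    nodes = sorted(g.nodes)
    k = rng.randint(1, n)
    infected = frozenset(rng.sample(nodes, k))
    net = ContactNetwork(g)
    return net, InfectionSnapshot(network=net, infected=infected)


@pytest.fixture
def random_instance_factory():
    return random_infected_instance
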