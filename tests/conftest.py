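import random

import pytest

from netpharm.data import (
    fig4_crosstalk_path,
    table1_compounds_path,
    table2_docking_path,
)
from netpharm.model import TypedNetwork


@pytest.fixture(scope="session")
def table1_path():
    return table1_compounds_path()


@pytest.fixture(scope="session")
def table2_path():
    return table2_docking_path()


@pytest.fixture(scope="session")
def crosstalk_path():
    return fig4_crosstalk_path()


def make_network(nodes, edges, allowed_pairs=None):
    """Build a TypedNetwork from (id, class) pairs and (u, v) edges."""
    net = TypedNetwork(allowed_pairs=allowed_pairs)
    for node_id, node_class in nodes:
        net.add_node(node_id, node_class)
    for u, v in edges:
        net.add_edge(u, v)
    return net


def path_graph(*ids):
    nodes = [(i, "target") for i in ids]
    edges = list(zip(ids, ids[1:]))
    return make_network(nodes, edges)


def random_network(rng: random.Random, n: int, p: float = 0.4) -> TypedNetwork:
    """Random graph with random node classes; may be disconnected."""
    classes = ["compound", "target", "pathway"]
    ids = [f"n{i:03d}" for i in range(n)]
    net = TypedNetwork()
    for i in ids:
        net.add_node(i, rng.choice(classes))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                net.add_edge(ids[i], ids[j])
    return net
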