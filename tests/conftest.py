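import networkx as nx
import pytest

import agewalk as aw


@pytest.fixture
def triangle():
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("a", "c"), ("b", "c")])
    return g


@pytest.fixture
def path4():
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("c", "d")])
    return g


def make_weighted_snapshot(edges, age="s0"):
    """edges: iterable of (u, v, w)."""
    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=float(w))
    return aw.Snapshot(age_label=age, graph=g)


@pytest.fixture
def toy_weighted_dynamic():
    """Two snapshots over one triangle edge set (differential-style weights)."""
    s0 = make_weighted_snapshot(
        [("a", "b", 10.0), ("a", "c", 50.0), ("b", "c", 10.0)], age="s0"
    )
    s1 = make_weighted_snapshot(
        [("a", "b", 50.0), ("a", "c", -20.0), ("b", "c", 10.0)], age="s1"
    )
    return aw.DynamicNetwork(snapshots=[s0, s1], weighted=True)


def random_connected_graph(rng, n, p=0.08):
    """Seeded Erdos-Renyi graph, regenerated until connected."""
    while True:
        seed = int(rng.integers(0, 2**31 - 1))
        g = nx.gnp_random_graph(n, p, seed=seed)
        if g.number_of_nodes() and nx.is_connected(g):
            return nx.relabel_nodes(g, {i: f"n{i:03d}" for i in g.nodes})


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic study shared by integration tests."""
    return aw.generate_dataset(
        aw.SyntheticConfig(n_genes=60, n_ages=4, n_aging_genes=8, seed=11)
    )


@pytest.fixture(scope="session")
def small_suite(small_dataset):
    ds = small_dataset
    return aw.build_suite(ds.network, ds.expression)
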