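import networkx as nx
import numpy as np
import pytest

from acunet import (
    AcupointNetwork,
    CommunityMap,
    GeneratorConfig,
    build_adn,
    fixture_graphs,
    generate_prescriptions,
)


@pytest.fixture(scope="session")
def fixtures():
    return fixture_graphs()


@pytest.fixture(scope="session")
def star4(fixtures):
    return fixtures["star4"]


@pytest.fixture(scope="session")
def path3(fixtures):
    return fixtures["path3"]


@pytest.fixture(scope="session")
def k4(fixtures):
    return fixtures["k4"]


@pytest.fixture(scope="session")
def gprime(fixtures):
    return fixtures["gprime"]


@pytest.fixture(scope="session")
def two_clique(fixtures):
    return fixtures["two_clique"]


@pytest.fixture(scope="session")
def small_config():
    # reduced study shape so the end-to-end suite stays fast
    return GeneratorConfig(
        n_conditions=16,
        n_entities=48,
        n_communities=6,
        prescription_size=6,
        seed=7,
        community_size_profile="balanced",
        min_community_nodes=2,
    )


@pytest.fixture(scope="session")
def small_synthetic(small_config):
    table, communities = generate_prescriptions(small_config)
    return build_adn(table, communities)


def random_connected_weighted_net(rng: np.random.Generator, n: int, max_weight: int = 5):
    """Random connected weighted network: spanning tree plus extra edges."""
    nodes = [f"n{i:02d}" for i in range(n)]
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    order = rng.permutation(n)
    for i in range(1, n):
        u = nodes[order[i]]
        v = nodes[order[rng.integers(0, i)]]
        graph.add_edge(u, v, weight=int(rng.integers(1, max_weight + 1)))
    n_extra = int(rng.integers(0, n))
    for _ in range(n_extra):
        u, v = rng.choice(nodes, size=2, replace=False)
        if not graph.has_edge(u, v):
            graph.add_edge(u, v, weight=int(rng.integers(1, max_weight + 1)))
    communities = CommunityMap(assignment={node: "M01" for node in nodes})
    return AcupointNetwork(graph, communities)
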