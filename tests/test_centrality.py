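"""Centrality scores against hand computations and independent oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest

from acunet import (
    AcupointNetwork,
    CommunityMap,
    DisconnectedNetworkError,
    PrescriptionTable,
    betweenness_centrality,
    build_adn,
    cld_centrality,
    closeness_centrality,
    compute_centrality,
    degree_centrality,
    eigenvector_centrality,
    graph_diameter,
    influence_profile,
    k_shell,
    key_node_score,
    star_network,
    weighted_degree,
)
from conftest import random_connected_weighted_net


def brute_force_walk_weight(net, source, target, length):
    """Sum over all length-k walks source→target of the edge-weight product."""
    total = 0.0
    frontier = [(source, 1.0)]
    for _ in range(length):
        nxt = []
        for node, product in frontier:
            for neighbor in net.graph.neighbors(node):
                nxt.append((neighbor, product * net.weight(node, neighbor)))
        frontier = nxt
    for node, product in frontier:
        if node == target:
            total += product
    return total


class TestDiameter:
    def test_path_and_complete(self, path3, k4):
        assert graph_diameter(path3) == 2
        assert graph_diameter(k4) == 1

    def test_weighted_fixture_uses_hops(self, gprime):
        # weights are ignored for distances: the 4-node weighted fixture has
        # hop diameter 2
        assert graph_diameter(gprime) == 2

    def test_disconnected_rejected(self):
        table = PrescriptionTable.from_dict({"d1": ["a", "b"], "d2": ["c", "d"]})
        communities = CommunityMap(assignment={e: "M01" for e in "abcd"})
        net = build_adn(table, communities)
        with pytest.raises(DisconnectedNetworkError):
            graph_diameter(net)


class TestInfluenceProfile:
    def test_single_edge(self):
        communities = CommunityMap(assignment={"a": "M01", "b": "M01"})
        graph = nx.Graph()
        graph.add_edge("a", "b", weight=1)
        profile = influence_profile(AcupointNetwork(graph, communities))
        assert profile.diameter == 1
        assert profile.theta("a", 1) == profile.theta("b", 1) == 1
        assert profile.total(1) == 1

    def test_path3_hand_matrix_power(self, path3):
        # A^2 = [[1,0,1],[0,2,0],[1,0,1]] for the unit path
        profile = influence_profile(path3)
        a, b, c = path3.nodes
        assert profile.theta(a, 1) == 1 and profile.theta(b, 1) == 2
        assert profile.total(1) == 2
        assert profile.theta(a, 2) == 1
        assert profile.theta(b, 2) == 0
        assert profile.theta(c, 2) == 1
        assert profile.total(2) == 1

    def test_triangle(self):
        communities = CommunityMap(assignment={e: "M01" for e in "abc"})
        graph = nx.Graph()
        for u, v in itertools.combinations("abc", 2):
            graph.add_edge(u, v, weight=1)
        profile = influence_profile(AcupointNetwork(graph, communities))
        assert profile.diameter == 1
        assert all(profile.theta(e, 1) == 2 for e in "abc")
        assert profile.total(1) == 3

    def test_theta1_is_weighted_degree(self, gprime, small_synthetic):
        for net in (gprime, small_synthetic):
            profile = influence_profile(net)
            strength = weighted_degree(net)
            for node in net.nodes:
                assert profile.theta(node, 1) == pytest.approx(strength[node])

    def test_pair_counting_identity(self, small_synthetic):
        # sum_i theta_i^k = 2 theta^k: each unordered pair counted once
        profile = influence_profile(small_synthetic)
        for k in range(1, profile.diameter + 1):
            total = sum(profile.theta(n, k) for n in small_synthetic.nodes)
            assert total == pytest.approx(2 * profile.total(k), rel=1e-12)

    def test_matrix_power_matches_walk_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            net = random_connected_weighted_net(rng, int(rng.integers(3, 7)))
            A = net.adjacency_matrix()
            nodes = net.nodes
            for k in (1, 2, 3):
                Ak = np.linalg.matrix_power(A, k)
                for i, j in itertools.product(range(len(nodes)), repeat=2):
                    expected = brute_force_walk_weight(net, nodes[i], nodes[j], k)
                    assert Ak[i, j] == pytest.approx(expected)


class TestKeyNode:
    def test_triangle_scores(self):
        communities = CommunityMap(assignment={e: "M01" for e in "abc"})
        graph = nx.Graph()
        for u, v in itertools.combinations("abc", 2):
            graph.add_edge(u, v, weight=1)
        scores = key_node_score(AcupointNetwork(graph, communities))
        assert all(scores[e] == pytest.approx(2 / 3) for e in "abc")

    def test_path3_scores(self, path3):
        scores = key_node_score(path3)
        a, b, c = path3.nodes
        assert scores[a] == pytest.approx(1.5)
        assert scores[b] == pytest.approx(1.0)
        assert scores[c] == pytest.approx(1.5)

    def test_sum_identity_random_graphs(self):
        # sum_i Key_node(v_i) = 2 D on every connected weighted graph
        rng = np.random.default_rng(5)
        for _ in range(25):
            net = random_connected_weighted_net(rng, int(rng.integers(3, 30)))
            scores = key_node_score(net)
            diameter = graph_diameter(net)
            assert sum(scores.scores.values()) == pytest.approx(
                2 * diameter, rel=1e-9
            )


class TestBaselines:
    def test_closeness_hand_values(self, path3, k4):
        scores = closeness_centrality(path3)
        a, b, c = path3.nodes
        assert scores[b] == pytest.approx(1.0)
        assert scores[a] == scores[c] == pytest.approx(2 / 3)
        assert all(v == pytest.approx(1.0) for v in closeness_centrality(k4).scores.values())

    def test_closeness_star_leaf(self):
        scores = closeness_centrality(star_network(4))
        leaf = [n for n in scores if n != "c"][0]
        assert scores[leaf] == pytest.approx(0.6)

    def test_closeness_error_names_components(self):
        table = PrescriptionTable.from_dict({"d1": ["a", "b"], "d2": ["c", "d"]})
        communities = CommunityMap(assignment={e: "M01" for e in "abcd"})
        net = build_adn(table, communities)
        with pytest.raises(DisconnectedNetworkError, match="components"):
            closeness_centrality(net)

    def test_degree_and_strength(self, two_clique):
        assert degree_centrality(star_network(4))["c"] == 3
        assert weighted_degree(two_clique)["b"] == 4  # 1 + 2 + 1

    def test_betweenness(self, path3, k4):
        scores = betweenness_centrality(path3)
        _, b, _ = path3.nodes
        assert scores[b] == pytest.approx(1.0)  # the single a–c geodesic
        assert all(v == 0 for v in betweenness_centrality(k4).scores.values())
        star5 = star_network(5)
        assert betweenness_centrality(star5)["c"] == pytest.approx(1.0)

    def test_eigenvector_symmetry_and_center(self, k4, path3):
        ev = eigenvector_centrality(k4)
        values = list(ev.scores.values())
        assert np.allclose(values, values[0])
        ev_path = eigenvector_centrality(path3)
        a, b, c = path3.nodes
        assert ev_path[b] > ev_path[a] and ev_path[b] > ev_path[c]

    def test_eigenvector_scale_invariance(self, gprime):
        doubled = nx.Graph()
        for u, v, data in gprime.graph.edges(data=True):
            doubled.add_edge(u, v, weight=2 * data["weight"])
        net2 = AcupointNetwork(doubled, gprime.communities)
        ev1 = eigenvector_centrality(gprime)
        ev2 = eigenvector_centrality(net2)
        for node in gprime.nodes:
            assert ev1[node] == pytest.approx(ev2[node], abs=1e-8)

    def test_eigenvector_matches_numpy_eig(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            net = random_connected_weighted_net(rng, int(rng.integers(3, 20)))
            ev = eigenvector_centrality(net)
            A = net.adjacency_matrix()
            eigvals, eigvecs = np.linalg.eigh(A)
            principal = np.abs(eigvecs[:, np.argmax(eigvals)])
            for node, expected in zip(net.nodes, principal):
                assert ev[node] == pytest.approx(expected, abs=1e-6)

    def test_k_shell_hand_values(self, k4, fixtures):
        assert all(v == 3 for v in k_shell(k4).scores.values())
        shells = k_shell(fixtures["triangle_pendant"])
        assert shells["t4"] == 1
        assert shells["t1"] == shells["t2"] == shells["t3"] == 2
        assert all(v == 1 for v in k_shell(star_network(6)).scores.values())

    def test_k_shell_matches_manual_pruning(self):
        # oracle: repeatedly strip nodes of degree <= s, recording shells
        rng = np.random.default_rng(9)
        for _ in range(10):
            net = random_connected_weighted_net(rng, int(rng.integers(4, 25)))
            graph = net.graph.copy()
            expected = {}
            shell = 0
            while graph:
                shell += 1
                while True:
                    to_remove = [n for n, d in graph.degree() if d <= shell]
                    if not to_remove:
                        break
                    for node in to_remove:
                        expected[node] = shell
                    graph.remove_nodes_from(to_remove)
            scores = k_shell(net)
            assert {n: int(v) for n, v in scores.items()} == expected

    def test_cld_hand_values(self, k4):
        pair = star_network(2)
        assert cld_centrality(pair)["c"] == pytest.approx(1.0)
        assert cld_centrality(star_network(4))["c"] == pytest.approx(3.0)
        assert all(v == pytest.approx(9 / 2) for v in cld_centrality(k4).scores.values())

    def test_cld_formula_is_pluggable(self, k4):
        scores = cld_centrality(k4, formula=lambda g, n: float(g.degree(n)))
        assert all(v == 3.0 for v in scores.scores.values())

    def test_closeness_betweenness_match_bfs_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            net = random_connected_weighted_net(rng, int(rng.integers(3, 12)))
            nodes = net.nodes
            dist = dict(nx.all_pairs_shortest_path_length(net.graph))
            closeness = closeness_centrality(net)
            for node in nodes:
                expected = (len(nodes) - 1) / sum(
                    dist[node][other] for other in nodes if other != node
                )
                assert closeness[node] == pytest.approx(expected)
            # betweenness oracle: enumerate geodesics among all simple paths
            betweenness = betweenness_centrality(net)
            n = len(nodes)
            expected_b = dict.fromkeys(nodes, 0.0)
            for s, t in itertools.combinations(nodes, 2):
                geodesics = [
                    p
                    for p in nx.all_simple_paths(net.graph, s, t, cutoff=dist[s][t])
                    if len(p) - 1 == dist[s][t]
                ]
                for path in geodesics:
                    for inner in path[1:-1]:
                        expected_b[inner] += 1.0 / len(geodesics)
            scale = 2.0 / ((n - 1) * (n - 2)) if n > 2 else 1.0
            for node in nodes:
                assert betweenness[node] == pytest.approx(expected_b[node] * scale)


def test_permutation_equivariance():
    """Relabeling nodes permutes every centrality identically."""
    rng = np.random.default_rng(23)
    net = random_connected_weighted_net(rng, 12)
    relabel = {n: f"z{i:02d}" for i, n in enumerate(reversed(net.nodes))}
    graph2 = nx.relabel_nodes(net.graph, relabel)
    communities2 = CommunityMap(assignment={n: "M01" for n in graph2.nodes})
    net2 = AcupointNetwork(graph2, communities2)
    for method in ["key_node", "degree", "closeness", "betweenness",
                   "eigenvector", "k_shell", "cld"]:
        s1 = compute_centrality(net, method)
        s2 = compute_centrality(net2, method)
        for node in net.nodes:
            assert s1[node] == pytest.approx(s2[relabel[node]], abs=1e-8)


def test_unknown_method_lists_available():
    with pytest.raises(ValueError, match="available"):
        compute_centrality(star_network(3), "pagerank")
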