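"""Node-importance scores on weighted undirected co-occurrence networks.

The central quantity is the *Key_node* influence index: for a connected
network with weighted adjacency matrix ``A`` and (unweighted hop) diameter
``D``, a node's influence at walk length ``k`` is

    theta_i^k = sum_{m != i} A^k[i, m]

(the off-diagonal row sum of the k-th matrix power — the weight-product
accumulation of all length-k walks leaving the node), and the network total
is ``theta^k = (1/2) sum_{n != m} A^k[n, m]``.  The index is the node's share
of total walk influence, summed over lengths 1..D:

    Key_node(v_i) = sum_{k=1}^{D} theta_i^k / theta^k

Length-1 influence is exactly the weighted degree; longer walks credit nodes
whose heavy edges sit on many indirect routes.  Since the off-diagonal row
sums of a symmetric matrix add up to twice the half-sum, the scores obey the
identity ``sum_i Key_node(v_i) = 2 D`` on every connected network.

Six classical baselines used in the comparison experiments are provided as
well: degree, closeness, betweenness, eigenvector, k-shell and clustered
local degree (CLD).  Distances everywhere are unweighted hop counts; only
the matrix powers and the weighted degree use edge weights.
"""

from __future__ import annotations

from collections.abc import Callable, Mapping
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .network import AcupointNetwork

__all__ = [
    "ScoreVector",
    "InfluenceProfile",
    "graph_diameter",
    "influence_profile",
    "key_node_score",
    "closeness_centrality",
    "degree_centrality",
    "weighted_degree",
    "betweenness_centrality",
    "eigenvector_centrality",
    "k_shell",
    "cld_centrality",
    "CENTRALITY_METHODS",
    "compute_centrality",
]


@dataclass(frozen=True)
class ScoreVector:
    """Named node → score mapping produced by one ranking method."""

    method: str
    scores: Mapping[str, float]

    def __getitem__(self, node: str) -> float:
        return self.scores[node]

    def __len__(self) -> int:
        return len(self.scores)

    def __iter__(self):
        return iter(self.scores)

    def items(self):
        return self.scores.items()

    def as_series(self) -> pd.Series:
        return pd.Series(dict(self.scores), name=self.method).sort_index()

    def to_frame(self) -> pd.DataFrame:
        df = self.as_series().rename("score").rename_axis("entity_id").reset_index()
        df.insert(1, "method", self.method)
        return df


@dataclass(frozen=True)
class InfluenceProfile:
    """Per-node, per-walk-length weighted influence and network totals.

    ``theta_node[i, k-1]`` is theta_i^k for node ``nodes[i]``;
    ``theta_total[k-1]`` is theta^k; ``diameter`` is D.
    """

    nodes: tuple[str, ...]
    diameter: int
    theta_node: np.ndarray
    theta_total: np.ndarray

    def theta(self, node: str, k: int) -> float:
        return float(self.theta_node[self.nodes.index(node), k - 1])

    def total(self, k: int) -> float:
        return float(self.theta_total[k - 1])


def graph_diameter(net: AcupointNetwork) -> int:
    """Maximum unweighted shortest-path hop count over all node pairs."""
    net.require_connected("graph_diameter")
    if net.n_nodes < 2:
        raise ValueError("diameter requires at least two nodes")
    return nx.diameter(net.graph)


def influence_profile(net: AcupointNetwork) -> InfluenceProfile:
    """Walk-influence profile theta_i^k, theta^k for k = 1..D.

    ``A^k`` is formed by repeated multiplication of the weighted adjacency
    matrix, so entries accumulate the product of edge weights along every
    length-k walk (walks may revisit nodes).
    """
    net.require_connected("influence_profile")
    diameter = graph_diameter(net)
    A = net.adjacency_matrix()
    n = A.shape[0]
    theta_node = np.empty((n, diameter))
    theta_total = np.empty(diameter)
    power = np.eye(n)
    for k in range(diameter):
        power = power @ A
        off_diag_rows = power.sum(axis=1) - np.diag(power)
        theta_node[:, k] = off_diag_rows
        theta_total[k] = (power.sum() - np.trace(power)) / 2.0
    return InfluenceProfile(
        nodes=tuple(net.nodes),
        diameter=diameter,
        theta_node=theta_node,
        theta_total=theta_total,
    )


def key_node_score(net: AcupointNetwork) -> ScoreVector:
    """Key_node influence index: sum over k = 1..D of theta_i^k / theta^k.

    Raw scores; multiply by 100 for the percentage form used in reports.
    """
    profile = influence_profile(net)
    if np.any(profile.theta_total <= 0):
        bad = int(np.argmin(profile.theta_total)) + 1
        raise ValueError(f"total walk influence theta^{bad} is not positive")
    shares = profile.theta_node / profile.theta_total[np.newaxis, :]
    scores = shares.sum(axis=1)
    return ScoreVector("key_node", dict(zip(profile.nodes, map(float, scores))))


def closeness_centrality(net: AcupointNetwork) -> ScoreVector:
    """Classical closeness (N-1) / sum_j d_ij on unweighted hop distances."""
    net.require_connected("closeness_centrality")
    scores = nx.closeness_centrality(net.graph)
    return ScoreVector("closeness", {n: float(scores[n]) for n in net.nodes})


def degree_centrality(net: AcupointNetwork) -> ScoreVector:
    """Unweighted neighbor count."""
    return ScoreVector("degree", {n: float(d) for n, d in net.graph.degree()})


def weighted_degree(net: AcupointNetwork) -> ScoreVector:
    """Node strength s_i = sum_j w_ij."""
    return ScoreVector(
        "weighted_degree", {n: float(d) for n, d in net.graph.degree(weight="weight")}
    )


def betweenness_centrality(net: AcupointNetwork) -> ScoreVector:
    """Shortest-path betweenness on unweighted hops, pair-normalized."""
    scores = nx.betweenness_centrality(net.graph, normalized=True, weight=None)
    return ScoreVector("betweenness", {n: float(scores[n]) for n in net.nodes})


def eigenvector_centrality(
    net: AcupointNetwork, tol: float = 1e-10, max_iter: int = 10_000
) -> ScoreVector:
    """Principal eigenvector of the weighted adjacency matrix.

    Power iteration with L2 normalization and nonnegative orientation; on a
    connected network with positive weights the Perron vector is unique and
    strictly positive.  Iteration runs on A + I: the shift leaves the
    eigenvectors unchanged but makes the leading eigenvalue strictly
    dominant even on bipartite networks, where plain power iteration
    oscillates between +/- the smallest eigenvalue's direction.
    """
    net.require_connected("eigenvector_centrality")
    A = net.adjacency_matrix()
    n = A.shape[0]
    shifted = A + np.eye(n)
    x = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        y = shifted @ x
        norm = np.linalg.norm(y)
        if norm == 0:
            raise ValueError("power iteration collapsed to the zero vector")
        y /= norm
        if np.linalg.norm(y - x) < tol:
            x = y
            break
        x = y
    else:
        raise ValueError(f"power iteration did not converge in {max_iter} iterations")
    if x.sum() < 0:
        x = -x
    x = np.abs(x)  # roundoff can leave tiny negative entries
    return ScoreVector("eigenvector", dict(zip(net.nodes, map(float, x))))


def k_shell(net: AcupointNetwork) -> ScoreVector:
    """Classic unweighted k-shell (core-number) decomposition."""
    shells = nx.core_number(net.graph)
    return ScoreVector("k_shell", {n: float(shells[n]) for n in net.nodes})


def _cld_default(graph: nx.Graph, node: str) -> float:
    neighbor_degree_sum = sum(graph.degree(j) for j in graph.neighbors(node))
    clustering = nx.clustering(graph, node)
    return neighbor_degree_sum / (1.0 + clustering)


def cld_centrality(
    net: AcupointNetwork,
    formula: Callable[[nx.Graph, str], float] | None = None,
) -> ScoreVector:
    """Clustered local degree: neighbor degrees tempered by clustering.

    Default formula: CLD(i) = (sum of unweighted neighbor degrees) /
    (1 + local clustering coefficient).  The formula is pluggable so an
    alternative definition can be substituted without touching callers.
    """
    score_of = formula or _cld_default
    return ScoreVector("cld", {n: float(score_of(net.graph, n)) for n in net.nodes})


CENTRALITY_METHODS: dict[str, Callable[[AcupointNetwork], ScoreVector]] = {
    "key_node": key_node_score,
    "degree": degree_centrality,
    "closeness": closeness_centrality,
    "betweenness": betweenness_centrality,
    "eigenvector": eigenvector_centrality,
    "k_shell": k_shell,
    "cld": cld_centrality,
}


def compute_centrality(net: AcupointNetwork, method: str) -> ScoreVector:
    """Dispatch a centrality by name; raises listing the available methods."""
    try:
        fn = CENTRALITY_METHODS[method]
    except KeyError:
        raise ValueError(
            f"unknown method {method!r}; available: {sorted(CENTRALITY_METHODS)}"
        ) from None
    return fn(net)
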