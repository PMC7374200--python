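"""Ranking-quality metrics: resolution, node-deletion loss, benchmark accuracy.

Three complementary views of how good a node ranking is:

*Resolution* measures granularity.  Scores are grouped into R equal-value
classes of sizes N_1..N_R over n nodes and

    f = 1 - (sum_i N_i^2) / (R * n^2),

so a constant ranking (R = 1) scores f = 0 and an all-distinct ranking
approaches 1 as n grows.  The complementary index Delta = 1 - f is reported
in comparison tables (smaller is better).

*Node-deletion loss* quantifies what connectivity a node (or node set) holds
up.  Direct loss sums reciprocal original hop distances from the deleted
node(s) to everything else; indirect loss adds reciprocal distances for
surviving pairs that removal disconnects.  Total loss is normalized by the
star-network center — the worst case for a given size — giving
C = 4*TLOS / ((N-1)(N+2)) in [0, 1].

*Benchmark accuracy* compares a ranking against the weight-reduction
reference score W(v) = s_v / l_v, where s_v is original weighted degree and
l_v the network's mean shortest-path length after setting every edge length
to 2 except the edges incident to v, which become 1.  Agreement is measured
with the tie-aware Kendall tau-b coefficient.
"""

from __future__ import annotations

import math
from collections.abc import Iterable
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra
from scipy.stats import kendalltau

from .centrality import ScoreVector, compute_centrality, weighted_degree
from .mining import comparison_key_sets
from .network import AcupointNetwork

__all__ = [
    "RankingResult",
    "ResolutionResult",
    "LossReport",
    "BenchmarkScore",
    "resolution",
    "cdf_curve",
    "node_deletion_loss",
    "set_deletion_loss",
    "weight_reduction_benchmark",
    "kendall_tau",
    "evaluate_all",
]


@dataclass(frozen=True)
class RankingResult:
    """Distinct-score classes of a ranking, ordered by descending score."""

    method: str
    classes: tuple[tuple[float, tuple[str, ...]], ...]

    @property
    def granularity(self) -> int:
        return len(self.classes)

    @property
    def class_sizes(self) -> tuple[int, ...]:
        return tuple(len(members) for _, members in self.classes)


@dataclass(frozen=True)
class ResolutionResult:
    f: float
    delta: float
    ranking: RankingResult


@dataclass(frozen=True)
class LossReport:
    """Connectivity loss from deleting a node or node set."""

    target: str | tuple[str, ...]
    dlos: float
    ilos: float
    tlos: float
    c: float


@dataclass(frozen=True)
class BenchmarkScore:
    """Weight-reduction reference scores W(v) = s_v / l_v."""

    w: dict[str, float]
    strength: dict[str, float]
    mean_distance: dict[str, float]

    def as_score_vector(self) -> ScoreVector:
        return ScoreVector("benchmark", dict(self.w))


def _round_significant(x: float, digits: int = 10) -> float:
    if x == 0 or not math.isfinite(x):
        return float(x)
    return round(x, digits - 1 - int(math.floor(math.log10(abs(x)))))


def resolution(scores: ScoreVector, n: int | None = None) -> ResolutionResult:
    """Granularity-based resolution f and its complement Delta = 1 - f.

    Scores are compared after rounding to 10 significant digits so that
    analytically tied floating-point centralities land in one class.
    """
    if n is None:
        n = len(scores)
    if n == 0:
        raise ValueError("resolution is undefined for an empty ranking")
    if len(scores) != n:
        raise ValueError(f"scores cover {len(scores)} nodes, expected {n}")
    groups: dict[float, list[str]] = {}
    for node, score in scores.items():
        groups.setdefault(_round_significant(float(score)), []).append(node)
    classes = tuple(
        (value, tuple(sorted(members)))
        for value, members in sorted(groups.items(), key=lambda kv: -kv[0])
    )
    ranking = RankingResult(method=scores.method, classes=classes)
    R = ranking.granularity
    f = 1.0 - sum(size * size for size in ranking.class_sizes) / (R * n * n)
    return ResolutionResult(f=f, delta=1.0 - f, ranking=ranking)


def cdf_curve(ranking: RankingResult) -> list[tuple[int, float]]:
    """Cumulative node fraction per score class, descending score order."""
    n = sum(ranking.class_sizes)
    points: list[tuple[int, float]] = []
    cumulative = 0
    for index, size in enumerate(ranking.class_sizes, start=1):
        cumulative += size
        points.append((index, cumulative / n))
    return points


def _all_pairs_hops(graph: nx.Graph) -> dict[str, dict[str, int]]:
    return dict(nx.all_pairs_shortest_path_length(graph))


def _loss_report(
    net: AcupointNetwork, targets: set[str], label: str | tuple[str, ...]
) -> LossReport:
    graph = net.graph
    n = net.n_nodes
    dist = _all_pairs_hops(graph)

    # Direct loss: every unordered pair with at least one deleted endpoint,
    # counted once, at original hop distance.
    nodes = net.nodes
    dlos = 0.0
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            if u in targets or v in targets:
                dlos += 1.0 / dist[u][v]

    # Indirect loss: surviving pairs disconnected by the removal, at their
    # original (pre-deletion) distances.
    remaining = graph.subgraph(set(nodes) - targets)
    component_of: dict[str, int] = {}
    for idx, component in enumerate(nx.connected_components(remaining)):
        for node in component:
            component_of[node] = idx
    survivors = sorted(component_of)
    ilos = 0.0
    for i, u in enumerate(survivors):
        for v in survivors[i + 1 :]:
            if component_of[u] != component_of[v]:
                ilos += 1.0 / dist[u][v]

    tlos = dlos + ilos
    c = 4.0 * tlos / ((n - 1) * (n + 2))
    return LossReport(target=label, dlos=dlos, ilos=ilos, tlos=tlos, c=c)


def node_deletion_loss(net: AcupointNetwork, target: str) -> LossReport:
    """Direct/indirect/total connectivity loss from deleting one node.

    C is normalized by the loss of a same-size star's center, the maximum:
    4*TLOS / ((N-1)(N+2)).
    """
    net.require_connected("node_deletion_loss")
    if target not in net.graph:
        raise ValueError(f"unknown target entity {target!r}")
    return _loss_report(net, {target}, target)


def set_deletion_loss(net: AcupointNetwork, targets: Iterable[str]) -> LossReport:
    """Connectivity loss from deleting a node set simultaneously.

    Deleted-deleted pairs are counted once in the direct loss; the
    normalizer is kept at the single-node star maximum so set losses are
    comparable across methods on the same network.
    """
    net.require_connected("set_deletion_loss")
    target_set = set(targets)
    if not target_set:
        raise ValueError("target set is empty")
    unknown = sorted(target_set - set(net.nodes))
    if unknown:
        raise ValueError(f"unknown target entities: {unknown}")
    if len(target_set) >= net.n_nodes:
        raise ValueError("cannot delete every node of the network")
    return _loss_report(net, target_set, tuple(sorted(target_set)))


def weight_reduction_benchmark(net: AcupointNetwork) -> BenchmarkScore:
    """Reference scores W(v) = s_v / l_v via the weight-reduction procedure.

    For each node v the network is re-weighted: every edge gets length 2,
    then all edges incident to v get length 1; l_v is the mean shortest-path
    length over all unordered node pairs in that copy, and s_v is the
    weighted degree in the original network.
    """
    net.require_connected("weight_reduction_benchmark")
    nodes = net.nodes
    n = len(nodes)
    if n < 2:
        raise ValueError("benchmark requires at least two nodes")
    index = {node: i for i, node in enumerate(nodes)}
    base = np.zeros((n, n))
    for u, v in net.graph.edges:
        base[index[u], index[v]] = 2.0
        base[index[v], index[u]] = 2.0
    strength = weighted_degree(net)
    n_pairs = n * (n - 1) / 2.0
    w: dict[str, float] = {}
    mean_distance: dict[str, float] = {}
    for node in nodes:
        i = index[node]
        lengths = base.copy()
        incident = lengths[i] > 0
        lengths[i, incident] = 1.0
        lengths[incident, i] = 1.0
        dist = dijkstra(sp.csr_matrix(lengths), directed=False)
        l_v = float(np.triu(dist, k=1).sum() / n_pairs)
        mean_distance[node] = l_v
        w[node] = strength[node] / l_v
    return BenchmarkScore(
        w=w, strength={m: strength[m] for m in nodes}, mean_distance=mean_distance
    )


def kendall_tau(a: ScoreVector, b: ScoreVector) -> float:
    """Tie-aware Kendall tau-b between two score vectors on the same nodes."""
    if set(a.scores) != set(b.scores):
        raise ValueError(
            f"node sets differ between {a.method!r} and {b.method!r}"
        )
    nodes = sorted(a.scores)
    x = [a[node] for node in nodes]
    y = [b[node] for node in nodes]
    tau = kendalltau(x, y, variant="b").statistic
    return float(tau)


def evaluate_all(
    net: AcupointNetwork,
    methods: list[str] | None = None,
    per_community: int = 2,
    per_community_candidates: int = 4,
) -> pd.DataFrame:
    """Full comparison table: Delta, key-set loss C(U) and benchmark tau.

    One row per method.  Delta and tau are computed on each method's
    full-network score vector (the proposed index also scores all nodes);
    C(U) is the simultaneous-deletion loss of that method's same-dimension
    key set.
    """
    if methods is None:
        methods = ["key_node", "degree", "closeness", "betweenness",
                   "eigenvector", "k_shell", "cld"]
    net.require_connected("evaluate_all")
    benchmark = weight_reduction_benchmark(net).as_score_vector()
    key_sets = comparison_key_sets(
        net, methods, per_community=per_community,
        per_community_candidates=per_community_candidates,
    )
    rows = []
    for method in methods:
        scores = compute_centrality(net, method)
        res = resolution(scores)
        loss = set_deletion_loss(net, key_sets[method].entities)
        tau = kendall_tau(scores, benchmark)
        rows.append(
            {
                "method": method,
                "delta": res.delta,
                "granularity": res.ranking.granularity,
                "c_set": loss.c,
                "tau": tau,
                "key_set_size": len(key_sets[method]),
            }
        )
    return pd.DataFrame(rows).set_index("method")
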