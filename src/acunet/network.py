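"""Construction and serialization of weighted acupoint co-occurrence networks.

An acupoint-disease network (ADN) is built from a *prescription table*: for
every condition (disease) the table lists the set of acupoints prescribed for
it.  Each condition induces a clique over its acupoints, and the weight of an
edge counts how many conditions both endpoints co-treat.  Nodes additionally
carry a fixed *community* label (the meridian the acupoint lies on, or the
"extraordinary points" group); community detection is deliberately out of
scope — the partition is an input.
"""

from __future__ import annotations

import csv
import itertools
import warnings
from collections import Counter
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "NetworkError",
    "DisconnectedNetworkError",
    "PrescriptionTable",
    "CommunityMap",
    "AcupointNetwork",
    "build_adn",
    "connected_check",
    "read_prescriptions",
    "read_communities",
    "read_network",
    "write_network",
    "read_graphml",
]


class NetworkError(ValueError):
    """Invalid input to a network construction or IO routine."""


class DisconnectedNetworkError(NetworkError):
    """Raised by operations that are only defined on connected networks."""


@dataclass(frozen=True)
class PrescriptionTable:
    """Conditions mapped to the ordered set of entities prescribed for them.

    Parameters
    ----------
    records
        Sequence of ``(condition_id, entities)`` pairs.  Entity order within a
        record is preserved but carries no meaning for network construction.
    max_size
        Maximum number of entities per condition.  The source data keeps the
        10 most frequently used acupoints per disease, hence the default.
    """

    records: tuple[tuple[str, tuple[str, ...]], ...]
    max_size: int = 10

    def __post_init__(self) -> None:
        seen_conditions: set[str] = set()
        for condition, entities in self.records:
            if condition in seen_conditions:
                raise NetworkError(f"duplicate condition id {condition!r}")
            seen_conditions.add(condition)
            if len(entities) == 0:
                raise NetworkError(f"condition {condition!r} has an empty entity set")
            if len(set(entities)) != len(entities):
                raise NetworkError(f"condition {condition!r} lists a duplicate entity")
            if len(entities) > self.max_size:
                raise NetworkError(
                    f"condition {condition!r} has {len(entities)} entities, "
                    f"exceeding the maximum of {self.max_size}"
                )

    @classmethod
    def from_dict(cls, mapping: Mapping[str, Iterable[str]], max_size: int = 10) -> "PrescriptionTable":
        records = tuple((c, tuple(es)) for c, es in mapping.items())
        return cls(records=records, max_size=max_size)

    @property
    def n_conditions(self) -> int:
        return len(self.records)

    @property
    def entities(self) -> tuple[str, ...]:
        """Sorted union of all entities appearing in any prescription."""
        out: set[str] = set()
        for _, es in self.records:
            out.update(es)
        return tuple(sorted(out))

    def to_frame(self) -> pd.DataFrame:
        rows = [(c, e) for c, es in self.records for e in es]
        return pd.DataFrame(rows, columns=["condition_id", "entity_id"])


@dataclass(frozen=True)
class CommunityMap:
    """Total assignment of entities to communities.

    ``communities`` fixes the community order used everywhere downstream
    (candidate/key tables iterate communities in this order).
    """

    assignment: Mapping[str, str]
    communities: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        labels = tuple(dict.fromkeys(self.assignment.values()))
        if not self.communities:
            object.__setattr__(self, "communities", labels)
        else:
            missing = set(labels) - set(self.communities)
            if missing:
                raise NetworkError(
                    f"assignment references communities missing from the "
                    f"community list: {sorted(missing)}"
                )

    def __getitem__(self, entity: str) -> str:
        return self.assignment[entity]

    def __contains__(self, entity: str) -> bool:
        return entity in self.assignment

    def members(self, community: str) -> tuple[str, ...]:
        return tuple(sorted(e for e, c in self.assignment.items() if c == community))


class AcupointNetwork:
    """Weighted undirected co-occurrence network with community labels.

    Thin wrapper over a :class:`networkx.Graph` that fixes a deterministic
    (lexicographic) node order, so adjacency matrices are reproducible, and
    keeps the community partition alongside the topology.  Edge weights are
    positive integers (number of co-treated conditions); self-loops are
    forbidden.
    """

    def __init__(self, graph: nx.Graph, communities: CommunityMap) -> None:
        for node in graph.nodes:
            if node not in communities:
                raise NetworkError(f"entity {node!r} has no community assignment")
        for u, v, data in graph.edges(data=True):
            if u == v:
                raise NetworkError(f"self-loop on {u!r}")
            w = data.get("weight")
            if w is None or w <= 0:
                raise NetworkError(f"edge ({u!r}, {v!r}) must have positive weight, got {w!r}")
        self._graph = nx.Graph()
        self._graph.add_nodes_from(sorted(graph.nodes))
        for u, v, data in graph.edges(data=True):
            self._graph.add_edge(u, v, weight=int(data["weight"]))
        for node in self._graph.nodes:
            self._graph.nodes[node]["community"] = communities[node]
        self.communities = communities

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    @property
    def nodes(self) -> list[str]:
        return list(self._graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self._graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def weight(self, u: str, v: str) -> int:
        """Edge weight between ``u`` and ``v`` (0 if not adjacent)."""
        if self._graph.has_edge(u, v):
            return self._graph[u][v]["weight"]
        return 0

    def adjacency_matrix(self) -> np.ndarray:
        """Dense weighted adjacency matrix in lexicographic node order."""
        return nx.to_numpy_array(self._graph, nodelist=self.nodes, weight="weight")

    def community_of(self, node: str) -> str:
        return self.communities[node]

    def community_members(self) -> dict[str, list[str]]:
        """Network nodes grouped by community, in the fixed community order.

        Communities with no network node map to an empty list.
        """
        out: dict[str, list[str]] = {c: [] for c in self.communities.communities}
        for node in self.nodes:
            out[self.communities[node]].append(node)
        return out

    def is_connected(self) -> bool:
        return self.n_nodes > 0 and nx.is_connected(self._graph)

    def require_connected(self, operation: str = "this operation") -> None:
        ok, components = connected_check(self)
        if not ok:
            raise DisconnectedNetworkError(
                f"{operation} requires a connected network; found "
                f"{len(components)} components: {components}"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AcupointNetwork):
            return NotImplemented
        if self.nodes != other.nodes:
            return False
        mine = {frozenset(e): d["weight"] for *e, d in self._graph.edges(data=True)}
        theirs = {frozenset(e): d["weight"] for *e, d in other._graph.edges(data=True)}
        if mine != theirs:
            return False
        return all(self.community_of(n) == other.community_of(n) for n in self.nodes)

    def __repr__(self) -> str:  # pragma: no cover
        return f"AcupointNetwork(N={self.n_nodes}, M={self.n_edges})"


def build_adn(
    prescriptions: PrescriptionTable,
    communities: CommunityMap,
    exclude: Iterable[str] = (),
) -> AcupointNetwork:
    """Build the weighted co-occurrence network from a prescription table.

    The weight of edge (i, j) is the number of conditions whose prescription
    contains both i and j; every within-condition pair is therefore connected
    (each condition induces a clique).  Entities present only in the community
    map are excluded — the node set is exactly the union of prescription
    entities.

    ``exclude`` removes entities up-front (manual curation: acupoints whose
    use conflicts with reference sources can be dropped without editing the
    table); conditions left empty by the exclusion are skipped.
    """
    excluded = set(exclude)
    effective: list[tuple[str, tuple[str, ...]]] = []
    for condition, entities in prescriptions.records:
        kept = tuple(e for e in entities if e not in excluded)
        if kept:
            effective.append((condition, kept))
    if not effective:
        raise NetworkError("prescription table is empty (or fully excluded)")

    node_set: set[str] = set()
    for _, entities in effective:
        node_set.update(entities)
    missing = sorted(e for e in node_set if e not in communities)
    if missing:
        raise NetworkError(f"entities without community assignment: {missing}")

    weights: Counter[tuple[str, str]] = Counter()
    for _, entities in effective:
        for u, v in itertools.combinations(sorted(set(entities)), 2):
            weights[(u, v)] += 1

    graph = nx.Graph()
    graph.add_nodes_from(sorted(node_set))
    for (u, v), w in weights.items():
        graph.add_edge(u, v, weight=w)
    return AcupointNetwork(graph, communities)


def connected_check(net: AcupointNetwork) -> tuple[bool, list[list[str]]]:
    """Return connectivity flag and the sorted list of components."""
    components = [sorted(c) for c in nx.connected_components(net.graph)]
    components.sort(key=lambda c: c[0])
    return len(components) <= 1, components


# ---------------------------------------------------------------------------
# Delimited-text IO


def _detect_sep(path: Path) -> str:
    if path.suffix.lower() in {".tsv", ".tab"}:
        return "\t"
    return ","


def read_prescriptions(path: str | Path, max_size: int = 10) -> PrescriptionTable:
    """Read a two-column (condition_id, entity_id) delimited file.

    Header required; CSV by default, TSV for ``.tsv``/``.tab`` suffixes.
    Duplicated (condition, entity) rows are deduplicated with a warning — a
    pair co-occurring in one condition contributes exactly 1 to its weight
    regardless of row multiplicity.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), dtype=str)
    required = {"condition_id", "entity_id"}
    if not required.issubset(df.columns):
        raise NetworkError(
            f"{path}: expected columns {sorted(required)}, found {list(df.columns)}"
        )
    bad = df.index[df["condition_id"].isna() | df["entity_id"].isna()]
    if len(bad):
        # +2: header line plus 1-based numbering
        lines = ", ".join(str(i + 2) for i in bad[:5])
        raise NetworkError(f"{path}: malformed rows at lines {lines}")
    dup = df.duplicated(subset=["condition_id", "entity_id"])
    if dup.any():
        warnings.warn(
            f"{path}: {int(dup.sum())} duplicated (condition, entity) rows "
            "deduplicated",
            stacklevel=2,
        )
        df = df[~dup]
    grouped: dict[str, list[str]] = {}
    for condition, entity in df.itertuples(index=False):
        grouped.setdefault(condition, []).append(entity)
    records = tuple((c, tuple(es)) for c, es in grouped.items())
    return PrescriptionTable(records=records, max_size=max_size)


def read_communities(path: str | Path) -> CommunityMap:
    """Read a node-attribute table (entity_id, community_id)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), dtype=str)
    required = {"entity_id", "community_id"}
    if not required.issubset(df.columns):
        raise NetworkError(
            f"{path}: expected columns {sorted(required)}, found {list(df.columns)}"
        )
    bad = df.index[df["entity_id"].isna() | df["community_id"].isna()]
    if len(bad):
        lines = ", ".join(str(i + 2) for i in bad[:5])
        raise NetworkError(f"{path}: malformed rows at lines {lines}")
    if df["entity_id"].duplicated().any():
        dupes = sorted(df.loc[df["entity_id"].duplicated(), "entity_id"])
        raise NetworkError(f"{path}: entities assigned more than once: {dupes[:5]}")
    assignment = dict(zip(df["entity_id"], df["community_id"]))
    communities = tuple(dict.fromkeys(df["community_id"]))
    return CommunityMap(assignment=assignment, communities=communities)


def write_network(
    net: AcupointNetwork,
    edge_path: str | Path,
    node_path: str | Path | None = None,
    graphml_path: str | Path | None = None,
) -> None:
    """Serialize the network as a weighted edge list plus node attributes.

    Edges are written ``source,target,weight`` with source < target in
    lexicographic order; the node table is ``entity_id,community_id``.  An
    optional GraphML export carries ``weight`` edge and ``community`` node
    attributes.
    """
    edge_path = Path(edge_path)
    with edge_path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source", "target", "weight"])
        for u, v in sorted(tuple(sorted(e)) for e in net.graph.edges):
            writer.writerow([u, v, net.weight(u, v)])
    if node_path is not None:
        with Path(node_path).open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["entity_id", "community_id"])
            for node in net.nodes:
                writer.writerow([node, net.community_of(node)])
    if graphml_path is not None:
        nx.write_graphml(net.graph, graphml_path)


def read_network(edge_path: str | Path, node_path: str | Path) -> AcupointNetwork:
    """Read a network from an edge-list CSV and a node-attribute CSV."""
    edge_path = Path(edge_path)
    df = pd.read_csv(edge_path, sep=_detect_sep(edge_path), dtype=str)
    required = {"source", "target", "weight"}
    if not required.issubset(df.columns):
        raise NetworkError(
            f"{edge_path}: expected columns {sorted(required)}, found {list(df.columns)}"
        )
    communities = read_communities(node_path)
    graph = nx.Graph()
    graph.add_nodes_from(communities.assignment)
    seen: dict[frozenset[str], tuple[int, int]] = {}
    for i, (u, v, w) in enumerate(df.itertuples(index=False)):
        line = i + 2
        try:
            weight = int(w)
        except (TypeError, ValueError):
            raise NetworkError(f"{edge_path}: non-integer weight {w!r} at line {line}") from None
        if weight <= 0:
            raise NetworkError(f"{edge_path}: non-positive weight at line {line}")
        if u == v:
            raise NetworkError(f"{edge_path}: self-loop at line {line}")
        for node in (u, v):
            if node not in communities:
                raise NetworkError(
                    f"{edge_path}: entity {node!r} at line {line} missing from node table"
                )
        key = frozenset((u, v))
        if key in seen:
            prev_line, prev_weight = seen[key]
            if prev_weight != weight:
                raise NetworkError(
                    f"{edge_path}: duplicate edge ({u!r}, {v!r}) with conflicting "
                    f"weights at lines {prev_line} and {line}"
                )
            continue
        seen[key] = (line, weight)
        graph.add_edge(u, v, weight=weight)
    # Node table entries that touch no edge are still nodes only if they are
    # isolated network nodes; by convention the node table lists exactly the
    # network's nodes, so keep them all.
    return AcupointNetwork(graph, communities)


def read_graphml(path: str | Path) -> AcupointNetwork:
    """Read a network from a GraphML file written by :func:`write_network`."""
    graph = nx.read_graphml(path)
    assignment = {}
    for node, data in graph.nodes(data=True):
        if "community" not in data:
            raise NetworkError(f"{path}: node {node!r} lacks a community attribute")
        assignment[node] = data["community"]
    communities = CommunityMap(assignment=assignment)
    return AcupointNetwork(graph, communities)
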