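"""Synthetic prescription tables and hand-checked fixture networks.

The generator emulates the structure of the frequency summaries that
co-occurrence acupoint networks are built from: ~50 conditions, each
prescribing up to 10 of ~135 entities that are partitioned into 15 fixed
communities.  Entity popularity is Zipf-skewed (a few workhorse entities
appear in many prescriptions), which gives the induced network the
heavy-tailed weighted-degree profile of the real data.  It does not attempt
to reproduce the real network's exact degree sequence or scores — the
published edge list is not available — only its shape.

Sampling design:

* Entities are split into communities by a fixed size profile; ``"auto"``
  mimics the meridian system's spread with two small communities (2 and 3
  entities) and the rest roughly balanced, ``"balanced"`` splits evenly.
* A popularity permutation is drawn once from the seed, independent of the
  community labels; condition prescriptions then sample entities without
  replacement with probability proportional to ``rank ** -popularity_exponent``.
* Downstream operations need a connected network, and the study-style setup
  needs a minimum number of prescription entities per community; samples
  violating either constraint are redrawn a bounded number of times, after
  which connectivity is restored with a single bridging condition.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network import (
    AcupointNetwork,
    CommunityMap,
    NetworkError,
    PrescriptionTable,
    build_adn,
    connected_check,
)

__all__ = ["GeneratorConfig", "generate_prescriptions", "fixture_graphs",
           "star_network", "path_network", "complete_network"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-shaped generator settings.

    Defaults mirror the motivating data source: 50 conditions, 135 entities,
    15 communities, at most 10 entities per prescription, and a Zipf
    popularity skew with exponent 1 (a moderate scale-free-like tail).
    """

    n_conditions: int = 50
    n_entities: int = 135
    n_communities: int = 15
    prescription_size: int = 10
    popularity_exponent: float = 1.0
    community_size_profile: str | Sequence[int] = "auto"
    seed: int = 0
    min_community_nodes: int = 0
    max_retries: int = 50

    def __post_init__(self) -> None:
        if self.prescription_size > self.n_entities:
            raise NetworkError(
                f"prescription_size {self.prescription_size} exceeds "
                f"n_entities {self.n_entities}"
            )
        if self.n_communities > self.n_entities:
            raise NetworkError(
                f"n_communities {self.n_communities} exceeds n_entities {self.n_entities}"
            )
        if self.n_conditions < 1 or self.prescription_size < 1:
            raise NetworkError("need at least one condition and one entity per condition")


def _community_sizes(config: GeneratorConfig) -> list[int]:
    n, k = config.n_entities, config.n_communities
    profile = config.community_size_profile
    if isinstance(profile, str):
        if profile == "balanced":
            base, extra = divmod(n, k)
            return [base + (1 if i < extra else 0) for i in range(k)]
        if profile == "auto":
            if k < 3 or n < k + 3:
                base, extra = divmod(n, k)
                return [base + (1 if i < extra else 0) for i in range(k)]
            # two deliberately small communities, rest balanced
            small = [2, 3]
            rest = n - sum(small)
            base, extra = divmod(rest, k - 2)
            return small + [base + (1 if i < extra else 0) for i in range(k - 2)]
        raise NetworkError(f"unknown community size profile {profile!r}")
    sizes = list(profile)
    if len(sizes) != k or sum(sizes) != n or min(sizes) < 1:
        raise NetworkError(
            f"explicit community sizes must be {k} positive integers summing to {n}"
        )
    return sizes


def _entity_label(i: int, width: int) -> str:
    return f"A{i:0{width}d}"


def generate_prescriptions(
    config: GeneratorConfig,
) -> tuple[PrescriptionTable, CommunityMap]:
    """Draw a seeded prescription table and its community map.

    Deterministic under a fixed config (same seed → byte-identical tables).
    The induced network is guaranteed connected, by resampling and — as a
    last resort — one bridging condition; if ``min_community_nodes`` > 0,
    every community is additionally guaranteed that many prescription
    entities (by resampling only; an infeasible requirement raises).
    """
    rng = np.random.default_rng(config.seed)
    ent_width = max(3, len(str(config.n_entities)))
    entities = [_entity_label(i + 1, ent_width) for i in range(config.n_entities)]
    sizes = _community_sizes(config)
    com_width = max(2, len(str(config.n_communities)))
    community_ids = [f"M{j + 1:0{com_width}d}" for j in range(config.n_communities)]
    assignment: dict[str, str] = {}
    cursor = 0
    for community, size in zip(community_ids, sizes):
        for entity in entities[cursor : cursor + size]:
            assignment[entity] = community
        cursor += size
    communities = CommunityMap(assignment=assignment, communities=tuple(community_ids))

    if config.min_community_nodes > min(sizes):
        raise NetworkError(
            f"min_community_nodes={config.min_community_nodes} exceeds the "
            f"smallest community size {min(sizes)}"
        )

    # popularity over a random entity permutation, independent of communities
    order = rng.permutation(config.n_entities)
    ranks = np.empty(config.n_entities)
    ranks[order] = np.arange(1, config.n_entities + 1)
    probs = ranks ** (-config.popularity_exponent)
    probs /= probs.sum()

    cond_width = max(2, len(str(config.n_conditions)))
    entity_arr = np.array(entities)

    def draw_table() -> PrescriptionTable:
        records = []
        for c in range(config.n_conditions):
            chosen = rng.choice(
                entity_arr, size=config.prescription_size, replace=False, p=probs
            )
            records.append((f"D{c + 1:0{cond_width}d}", tuple(chosen)))
        return PrescriptionTable(
            records=tuple(records), max_size=config.prescription_size
        )

    def satisfies_quota(net: AcupointNetwork) -> bool:
        if config.min_community_nodes == 0:
            return True
        counts = {c: len(ms) for c, ms in net.community_members().items()}
        return all(v >= config.min_community_nodes for v in counts.values())

    table = draw_table()
    for attempt in range(config.max_retries):
        net = build_adn(table, communities)
        connected, components = connected_check(net)
        if connected and satisfies_quota(net):
            return table, communities
        logger.info(
            "resampling prescriptions (attempt %d): connected=%s, quota_ok=%s",
            attempt + 1, connected, satisfies_quota(net),
        )
        table = draw_table()

    net = build_adn(table, communities)
    if not satisfies_quota(net):
        raise NetworkError(
            f"could not satisfy min_community_nodes={config.min_community_nodes} "
            f"within {config.max_retries} resamples; relax the quota or enlarge "
            "the table"
        )
    connected, components = connected_check(net)
    if not connected:
        # bridge: one representative per component, chunked to prescription size
        representatives = [component[0] for component in components]
        bridge_records = list(table.records)
        step = max(2, config.prescription_size)
        start = 0
        bridge_index = 1
        # consecutive chunks overlap by one representative so the bridges chain
        while start < len(representatives) - 1:
            chunk = representatives[start : start + step]
            bridge_records.append((f"DBRIDGE{bridge_index}", tuple(chunk)))
            logger.warning("added bridging condition DBRIDGE%d over %d components",
                           bridge_index, len(chunk))
            bridge_index += 1
            start += step - 1
        table = PrescriptionTable(
            records=tuple(bridge_records), max_size=config.prescription_size
        )
    return table, communities


# ---------------------------------------------------------------------------
# Fixture networks with hand-checkable topology


def _single_community_net(graph: nx.Graph) -> AcupointNetwork:
    communities = CommunityMap(assignment={n: "M01" for n in graph.nodes})
    return AcupointNetwork(graph, communities)


def star_network(n: int) -> AcupointNetwork:
    """Star S_n on n nodes: center ``c`` plus n-1 leaves, unit weights."""
    if n < 2:
        raise ValueError("star needs at least 2 nodes")
    graph = nx.Graph()
    width = len(str(n))
    for i in range(1, n):
        graph.add_edge("c", f"l{i:0{width}d}", weight=1)
    return _single_community_net(graph)


def path_network(n: int) -> AcupointNetwork:
    """Path P_n with unit weights, nodes p1..pn."""
    if n < 2:
        raise ValueError("path needs at least 2 nodes")
    graph = nx.Graph()
    width = len(str(n))
    names = [f"p{i:0{width}d}" for i in range(1, n + 1)]
    for u, v in zip(names, names[1:]):
        graph.add_edge(u, v, weight=1)
    return _single_community_net(graph)


def complete_network(n: int) -> AcupointNetwork:
    """Complete graph K_n with unit weights, nodes k1..kn."""
    if n < 2:
        raise ValueError("complete graph needs at least 2 nodes")
    width = len(str(n))
    graph = nx.complete_graph([f"k{i:0{width}d}" for i in range(1, n + 1)])
    nx.set_edge_attributes(graph, 1, "weight")
    return _single_community_net(graph)


def fixture_graphs() -> dict[str, AcupointNetwork]:
    """Named toy networks whose centralities are known by hand.

    - ``star4``: 4-node star (center ``c``).
    - ``path3``: 3-node path; Key_node = (1.5, 1.0, 1.5).
    - ``k4``: complete graph on 4 nodes.
    - ``triangle_pendant``: triangle t1-t2-t3 plus pendant t4 on t3.
    - ``gprime``: 4-node weighted graph with edges
      (v1,v2,w=2), (v1,v3,w=1), (v2,v3,w=3), (v3,v4,w=1); diameter 2.
    - ``two_clique``: two overlapping prescriptions {a,b,c} and {b,c,d};
      w(b,c)=2, the four other pairs weight 1 (N=4, M=5).
    """
    triangle_pendant = nx.Graph()
    for u, v in [("t1", "t2"), ("t1", "t3"), ("t2", "t3"), ("t3", "t4")]:
        triangle_pendant.add_edge(u, v, weight=1)

    gprime = nx.Graph()
    for u, v, w in [("v1", "v2", 2), ("v1", "v3", 1), ("v2", "v3", 3), ("v3", "v4", 1)]:
        gprime.add_edge(u, v, weight=w)

    two_clique_table = PrescriptionTable.from_dict({"d1": ["a", "b", "c"], "d2": ["b", "c", "d"]})
    two_clique_communities = CommunityMap(
        assignment={"a": "M01", "b": "M01", "c": "M02", "d": "M02"}
    )

    return {
        "star4": star_network(4),
        "path3": path_network(3),
        "k4": complete_network(4),
        "triangle_pendant": _single_community_net(triangle_pendant),
        "gprime": _single_community_net(gprime),
        "two_clique": build_adn(two_clique_table, two_clique_communities),
    }
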