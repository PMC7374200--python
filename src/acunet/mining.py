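"""Community-constrained key-node selection.

The mining pipeline runs in two stages over a fixed community partition
(the 14 meridians plus the extraordinary points, 15 communities in the
motivating data):

1. *Candidate stage* — within each community, take the (up to) four nodes
   with the highest closeness centrality; a community with fewer nodes
   contributes all of them.  This caps the candidate set at 4 x
   n_communities dimensions while keeping a globally central representative
   slate per meridian.
2. *Key stage* — within each community's candidates, take the (up to) two
   nodes with the highest Key_node score.  The Key_node ranking can and does
   promote candidates that were not the community's closeness leaders, since
   it also credits edge weights.

Baseline algorithms are compared fairly by giving each the same per-community
quota, ranked directly by that method's own score (no closeness pre-filter).

Ties at either stage are broken by higher weighted degree, then lexicographic
entity id, so selections are total and reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .centrality import (
    CENTRALITY_METHODS,
    ScoreVector,
    closeness_centrality,
    compute_centrality,
    key_node_score,
    weighted_degree,
)
from .network import AcupointNetwork

__all__ = [
    "CandidateSet",
    "KeyNodeSet",
    "select_candidates",
    "select_key_nodes",
    "comparison_key_sets",
    "coverage_1hop",
]


@dataclass(frozen=True)
class CandidateSet:
    """Per-community ordered candidate lists with their closeness scores."""

    members: dict[str, tuple[tuple[str, float], ...]]

    @property
    def entities(self) -> list[str]:
        return [e for ranked in self.members.values() for e, _ in ranked]

    def __len__(self) -> int:
        return len(self.entities)

    def community(self, community: str) -> tuple[str, ...]:
        return tuple(e for e, _ in self.members.get(community, ()))

    def to_frame(self, method: str = "closeness") -> pd.DataFrame:
        rows = [
            (community, rank + 1, entity, method, score)
            for community, ranked in self.members.items()
            for rank, (entity, score) in enumerate(ranked)
        ]
        return pd.DataFrame(rows, columns=["community", "rank", "entity_id", "method", "score"])


@dataclass(frozen=True)
class KeyNodeSet:
    """Per-community ordered key-node lists with their selection scores."""

    method: str
    members: dict[str, tuple[tuple[str, float], ...]]

    @property
    def entities(self) -> list[str]:
        return [e for ranked in self.members.values() for e, _ in ranked]

    def __len__(self) -> int:
        return len(self.entities)

    def community(self, community: str) -> tuple[str, ...]:
        return tuple(e for e, _ in self.members.get(community, ()))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (community, rank + 1, entity, self.method, score)
            for community, ranked in self.members.items()
            for rank, (entity, score) in enumerate(ranked)
        ]
        return pd.DataFrame(rows, columns=["community", "rank", "entity_id", "method", "score"])


def _rank_members(
    members: list[str],
    scores: ScoreVector,
    strength: ScoreVector,
    top: int,
) -> tuple[tuple[str, float], ...]:
    # score desc, weighted degree desc, entity id asc
    ordered = sorted(members, key=lambda e: (-scores[e], -strength[e], e))
    return tuple((e, scores[e]) for e in ordered[:top])


def select_candidates(net: AcupointNetwork, per_community: int = 4) -> CandidateSet:
    """Stage 1: top ``per_community`` nodes by closeness within each community."""
    net.require_connected("select_candidates")
    closeness = closeness_centrality(net)
    strength = weighted_degree(net)
    members: dict[str, tuple[tuple[str, float], ...]] = {}
    for community, nodes in net.community_members().items():
        if not nodes:
            warnings.warn(f"community {community!r} has no network nodes; skipped", stacklevel=2)
            continue
        members[community] = _rank_members(nodes, closeness, strength, per_community)
    return CandidateSet(members=members)


def select_key_nodes(
    net: AcupointNetwork,
    candidates: CandidateSet | None = None,
    per_community: int = 2,
) -> KeyNodeSet:
    """Stage 2: top ``per_community`` candidates by Key_node per community.

    Key_node scores are computed on the full network; only the ranking is
    restricted to each community's candidate slate.
    """
    if candidates is None:
        candidates = select_candidates(net)
    scores = key_node_score(net)
    strength = weighted_degree(net)
    members: dict[str, tuple[tuple[str, float], ...]] = {}
    for community, ranked in candidates.members.items():
        pool = [e for e, _ in ranked]
        members[community] = _rank_members(pool, scores, strength, per_community)
    return KeyNodeSet(method="key_node", members=members)


def comparison_key_sets(
    net: AcupointNetwork,
    methods: list[str],
    per_community: int = 2,
    per_community_candidates: int = 4,
) -> dict[str, KeyNodeSet]:
    """Same-dimension key sets for each method, for fair comparison.

    Baselines rank every community member directly by their own score (no
    closeness pre-filter); the proposed ``key_node`` method always goes
    through the candidate stage first.
    """
    unknown = [m for m in methods if m not in CENTRALITY_METHODS]
    if unknown:
        raise ValueError(
            f"unknown methods {unknown}; available: {sorted(CENTRALITY_METHODS)}"
        )
    strength = weighted_degree(net)
    out: dict[str, KeyNodeSet] = {}
    for method in methods:
        if method == "key_node":
            candidates = select_candidates(net, per_community=per_community_candidates)
            out[method] = select_key_nodes(net, candidates, per_community=per_community)
            continue
        scores = compute_centrality(net, method)
        members: dict[str, tuple[tuple[str, float], ...]] = {}
        for community, nodes in net.community_members().items():
            if not nodes:
                continue
            members[community] = _rank_members(nodes, scores, strength, per_community)
        out[method] = KeyNodeSet(method=method, members=members)
    return out


def coverage_1hop(net: AcupointNetwork, seeds: set[str] | list[str]) -> float:
    """Fraction of all nodes that are a seed or adjacent to at least one seed."""
    seeds = set(seeds)
    unknown = sorted(seeds - set(net.nodes))
    if unknown:
        raise ValueError(f"unknown seed entities: {unknown}")
    covered = set(seeds)
    for seed in seeds:
        covered.update(net.graph.neighbors(seed))
    return len(covered) / net.n_nodes
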