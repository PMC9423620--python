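"""Seed-list construction: descending-order and community-aware schemes.

The classical scheme ranks all nodes by descending centrality and takes the
top *B*. Its pitfall is that the top nodes often sit in the same dense
region, saturating a shared zone of influence. The community-aware scheme
instead orders communities from biggest to smallest, sorts nodes by
centrality *within* their community, and emits nodes in round-robin passes
over the community order — pass one takes each community's best node, pass
two each community's second-best, and so on — stopping exactly when the
budget is reached. The selected spreaders are thereby scattered across all
dense regions of the network.

Ties (equal scores within a community, equal community sizes) are broken
uniformly at random from independent streams derived from the caller's
seed, so results are reproducible yet unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._rng import generator
from .centrality import CentralityScores
from .community import Partition, sort_communities

__all__ = ["RankedList", "descending_rank", "community_aware_rank"]


@dataclass(frozen=True)
class RankedList:
    """An ordered seed list of length ``budget`` produced by one scheme."""

    scheme: str
    measure: str
    nodes: tuple
    budget: int

    def __post_init__(self):
        if len(self.nodes) != self.budget:
            raise ValueError(f"ranked list length {len(self.nodes)} != budget {self.budget}")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("ranked list contains duplicate nodes")

    def __iter__(self):
        return iter(self.nodes)

    def __len__(self) -> int:
        return len(self.nodes)


def _check_budget(budget: int, n: int) -> None:
    if not 1 <= budget <= n:
        raise ValueError(f"budget must lie in [1, {n}] (the network size), got {budget}")


def _sorted_desc(nodes, scores: CentralityScores, rng) -> list:
    """Nodes in non-increasing score order, equal scores shuffled uniformly."""
    keys = {v: rng.random() for v in sorted(nodes, key=repr)}
    return sorted(nodes, key=lambda v: (-scores[v], keys[v]))


def descending_rank(scores: CentralityScores, budget: int, rng_seed: int) -> RankedList:
    """Classical scheme: globally top-``budget`` nodes by descending score."""
    nodes = list(scores.scores)
    _check_budget(budget, len(nodes))
    rng = generator(rng_seed, "score-ties")
    ordered = _sorted_desc(nodes, scores, rng)
    return RankedList(scheme="descending", measure=scores.measure,
                      nodes=tuple(ordered[:budget]), budget=budget)


def community_aware_rank(scores: CentralityScores, partition: Partition, budget: int,
                         rng_seed: int) -> RankedList:
    """Community-aware scheme: round-robin over size-ordered communities.

    Every scored node must be assigned to a community. The community order
    is computed once up front and never re-sorted as communities empty;
    exhausted communities are skipped, and the inner pass is cut immediately
    when the budget is reached.
    """
    nodes = list(scores.scores)
    _check_budget(budget, len(nodes))
    for v in nodes:
        if v not in partition:
            raise ValueError(f"node {v!r} is missing from the partition")

    order = sort_communities(partition, rng_seed)
    tie_rng = generator(rng_seed, "score-ties")
    queues = {}
    for cid in order:
        members = [v for v in partition.communities[cid] if v in scores.scores]
        queues[cid] = _sorted_desc(members, scores, tie_rng)

    ranked: list = []
    positions = {cid: 0 for cid in order}
    while len(ranked) < budget:
        for cid in order:
            pos = positions[cid]
            if pos < len(queues[cid]):
                ranked.append(queues[cid][pos])
                positions[cid] = pos + 1
                if len(ranked) == budget:
                    break
    return RankedList(scheme="community_aware", measure=scores.measure,
                      nodes=tuple(ranked), budget=budget)
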