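"""Partition bookkeeping: community ordering, mixing parameter, strength.

A :class:`Partition` is a non-overlapping assignment of nodes to communities.
The strength of a community structure is summarized by the mixing parameter
μ — the fraction of edges whose endpoints lie in different communities. Low
μ means dense, well-separated communities; high μ means community labels
carry little structural information.
"""

from __future__ import annotations

from typing import Hashable, Iterable, Mapping

import networkx as nx

from ._rng import generator

__all__ = [
    "Partition",
    "sort_communities",
    "mixing_parameter",
    "classify_strength",
    "detect",
]


class Partition:
    """Immutable node → community-id map with a derived community index.

    Communities are disjoint by construction (each node maps to exactly one
    id) and every community is non-empty.
    """

    def __init__(self, assignment: Mapping[Hashable, Hashable]):
        self._assignment = dict(assignment)
        comms: dict[Hashable, set] = {}
        for node, cid in self._assignment.items():
            comms.setdefault(cid, set()).add(node)
        self._communities = {cid: frozenset(members) for cid, members in comms.items()}

    @classmethod
    def from_communities(cls, communities: Mapping[Hashable, Iterable[Hashable]]) -> "Partition":
        assignment: dict = {}
        for cid, members in communities.items():
            for node in members:
                if node in assignment and assignment[node] != cid:
                    raise ValueError(
                        f"node {node!r} assigned to both {assignment[node]!r} and {cid!r}; "
                        "overlapping communities are unsupported"
                    )
                assignment[node] = cid
        return cls(assignment)

    @property
    def assignment(self) -> dict:
        return dict(self._assignment)

    @property
    def communities(self) -> dict:
        return dict(self._communities)

    def community_of(self, node) -> Hashable:
        return self._assignment[node]

    def size_of(self, cid) -> int:
        return len(self._communities[cid])

    @property
    def nodes(self) -> frozenset:
        return frozenset(self._assignment)

    def __len__(self) -> int:
        return len(self._communities)

    def __contains__(self, node) -> bool:
        return node in self._assignment

    def __eq__(self, other) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return self._assignment == other._assignment

    def __repr__(self) -> str:
        return f"Partition(|V|={len(self._assignment)}, |C|={len(self._communities)})"

    def require_covers(self, graph: nx.Graph) -> None:
        """Raise if any graph node lacks a community assignment."""
        missing = [v for v in graph.nodes if v not in self._assignment]
        if missing:
            raise ValueError(
                f"{len(missing)} graph node(s) missing from partition, e.g. {missing[0]!r}"
            )


def sort_communities(partition: Partition, rng_seed: int) -> list:
    """Community ids from the biggest community to the smallest.

    Equal-size communities are permuted uniformly at random under
    ``rng_seed``; the result is deterministic given the seed.
    """
    if len(partition) == 0:
        raise ValueError("empty partition")
    rng = generator(rng_seed, "community-order")
    by_size: dict[int, list] = {}
    for cid, members in partition.communities.items():
        by_size.setdefault(len(members), []).append(cid)
    ordered = []
    for size in sorted(by_size, reverse=True):
        tied = sorted(by_size[size], key=repr)  # stable base order before shuffling
        rng.shuffle(tied)
        ordered.extend(tied)
    return ordered


def mixing_parameter(graph: nx.Graph, partition: Partition) -> float:
    """Fraction of edges whose endpoints lie in different communities."""
    if graph.number_of_edges() == 0:
        raise ValueError("mixing parameter undefined on an edgeless graph")
    partition.require_covers(graph)
    assign = partition._assignment
    inter = sum(1 for u, v in graph.edges if assign[u] != assign[v])
    return inter / graph.number_of_edges()


def classify_strength(mu: float) -> str:
    """Label a mixing parameter as ``strong``, ``medium`` or ``weak``.

    Strong community structure: μ ≤ 0.20; medium: 0.20 < μ < 0.40;
    weak: μ ≥ 0.40.
    """
    if not 0.0 <= mu <= 1.0:
        raise ValueError(f"mixing parameter must lie in [0, 1], got {mu}")
    if mu <= 0.20:
        return "strong"
    if mu < 0.40:
        return "medium"
    return "weak"


def detect(graph: nx.Graph, method: str = "infomap", seed: int = 0) -> Partition:
    """Uncover communities with an external detection algorithm.

    Thin adapter over python-igraph. ``method`` is one of ``infomap``,
    ``louvain`` or ``leiden``; the community-detection internals are out of
    scope here, partitions may equally be supplied as files.
    """
    import igraph as ig

    nodes = list(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    g = ig.Graph(n=len(nodes), edges=[(index[u], index[v]) for u, v in graph.edges])
    import random as _random

    ig.set_random_number_generator(_random.Random(seed))
    if method == "infomap":
        clustering = g.community_infomap()
    elif method == "louvain":
        clustering = g.community_multilevel()
    elif method == "leiden":
        clustering = g.community_leiden(objective_function="modularity", n_iterations=-1)
    else:
        raise ValueError(f"unknown detection method {method!r}; choose infomap, louvain or leiden")
    return Partition({nodes[i]: cid for cid, members in enumerate(clustering) for i in members})
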