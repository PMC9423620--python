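"""The six node-centrality measures used for seed ranking.

Neighborhood-based: Degree, Maximum Neighborhood Component (MNC).
Path-based: Betweenness, Closeness.
Iterative-refinement-based: Katz, PageRank.

Scores are raw (unnormalized): the ranking schemes only sort, so any
monotone rescaling is immaterial. Betweenness is computed exactly with
Brandes' algorithm via igraph's C implementation — the experiment graphs
stay small enough (a few thousand nodes) that sampling is unnecessary.
Closeness on a disconnected graph is computed per connected component and
scaled by (n_comp − 1)/(n − 1), the Wasserman–Faust convention, so scores
stay finite and comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable

import networkx as nx
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = ["MEASURES", "CentralityScores", "compute_centrality", "mnc_score", "spectral_radius"]

MEASURES = ("degree", "mnc", "betweenness", "closeness", "katz", "pagerank")


@dataclass(frozen=True)
class CentralityScores:
    """One named measure's node → score map."""

    measure: str
    scores: dict

    def __getitem__(self, node) -> float:
        return self.scores[node]

    def items(self):
        return self.scores.items()

    def __len__(self) -> int:
        return len(self.scores)


def mnc_score(graph: nx.Graph, node: Hashable) -> int:
    """Size of the largest connected component among ``node``'s neighbors.

    The subgraph is induced by the open neighborhood N(node) — the node
    itself is excluded — so an isolated node scores 0 and a star center
    scores 1.
    """
    neigh = list(graph.neighbors(node))
    if not neigh:
        return 0
    sub = graph.subgraph(neigh)
    return max(len(c) for c in nx.connected_components(sub))


def spectral_radius(graph: nx.Graph) -> float:
    """Largest eigenvalue of the adjacency matrix."""
    n = graph.number_of_nodes()
    A = nx.adjacency_matrix(graph, dtype=float)
    if n <= 64:
        return float(np.max(np.linalg.eigvalsh(A.toarray())))
    val = spla.eigsh(A.astype(float), k=1, which="LA", return_eigenvectors=False)
    return float(val[0])


def _katz(graph: nx.Graph, alpha: float | None) -> dict:
    nodes = list(graph.nodes)
    A = nx.adjacency_matrix(graph, nodelist=nodes, dtype=float)
    rho = spectral_radius(graph)
    if alpha is None:
        alpha = 0.9 / rho if rho > 0 else 0.1
    elif rho > 0 and alpha >= 1.0 / rho:
        raise ValueError(
            f"Katz attenuation {alpha} >= 1/spectral radius ({1.0 / rho:.6g}); series diverges"
        )
    n = len(nodes)
    x = spla.spsolve(sp.identity(n, format="csc") - alpha * A.tocsc(), np.ones(n))
    # series sum over path lengths >= 1 (the constant offset does not affect order)
    return {v: float(x[i] - 1.0) for i, v in enumerate(nodes)}


def _betweenness(graph: nx.Graph) -> dict:
    import igraph as ig

    nodes = list(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    g = ig.Graph(n=len(nodes), edges=[(index[u], index[v]) for u, v in graph.edges])
    vals = g.betweenness()
    return {v: float(vals[i]) for i, v in enumerate(nodes)}


def compute_centrality(graph: nx.Graph, measure: str, *, katz_alpha: float | None = None,
                       pagerank_damping: float = 0.85) -> CentralityScores:
    """Compute one of the six measures for every node of ``graph``.

    ``katz_alpha`` defaults to 0.9 / spectral radius; ``pagerank_damping``
    defaults to 0.85.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot compute centrality on an empty graph")
    if measure == "degree":
        scores = {v: int(d) for v, d in graph.degree()}
    elif measure == "mnc":
        scores = {v: mnc_score(graph, v) for v in graph.nodes}
    elif measure == "betweenness":
        scores = _betweenness(graph)
    elif measure == "closeness":
        scores = {v: float(c) for v, c in nx.closeness_centrality(graph).items()}
    elif measure == "katz":
        scores = _katz(graph, katz_alpha)
    elif measure == "pagerank":
        scores = {v: float(c) for v, c in nx.pagerank(graph, alpha=pagerank_damping).items()}
    else:
        raise ValueError(f"unknown measure {measure!r}; valid measures: {', '.join(MEASURES)}")
    return CentralityScores(measure=measure, scores=scores)
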