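"""Read and write graphs and partitions in plain-text formats.

Node identifiers are opaque strings throughout: numeric-looking ids are not
coerced, which avoids 0/1-based renumbering bugs when moving between
formats. Inputs are collapsed to simple undirected graphs (self-loops and
duplicate edges dropped, with a logged count).
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx

from .community import Partition

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "read_gml",
    "read_partition",
    "write_partition",
]

log = logging.getLogger(__name__)


def _tokens(line: str) -> list[str]:
    return line.replace(",", " ").split()


def read_edge_list(path, comment_prefix: str = "#") -> nx.Graph:
    """Load a whitespace- or comma-delimited edge list as a simple graph.

    Every endpoint becomes a node; duplicate lines (in either orientation)
    collapse to one edge; self-loops are dropped with a logged count. Extra
    tokens per line (e.g. weights) are ignored with a logged notice.
    """
    path = Path(path)
    graph = nx.Graph()
    self_loops = 0
    extra_token_lines = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith(comment_prefix + "node "):
                # isolated-node record as written by write_edge_list
                graph.add_node(line[len(comment_prefix) + 5 :].strip())
                continue
            if not line or line.startswith(comment_prefix):
                continue
            toks = _tokens(line)
            if len(toks) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least 2 tokens, got {len(toks)}")
            if len(toks) > 2:
                extra_token_lines += 1
            u, v = toks[0], toks[1]
            if u == v:
                self_loops += 1
                graph.add_node(u)
                continue
            graph.add_edge(u, v)
    if self_loops:
        log.info("%s: dropped %d self-loop(s)", path, self_loops)
    if extra_token_lines:
        log.info("%s: ignored extra tokens (e.g. weights) on %d line(s)", path, extra_token_lines)
    return graph


def write_edge_list(graph: nx.Graph, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for u, v in graph.edges:
            fh.write(f"{u} {v}\n")
        # isolated nodes round-trip as degenerate "v v" comment lines would be
        # ambiguous; record them explicitly as comments instead
        for v in graph.nodes:
            if graph.degree(v) == 0:
                fh.write(f"#node {v}\n")


def read_gml(path) -> nx.Graph:
    """Load a GML file, keeping only node ids and edges.

    All other attributes are discarded; directed or multi-edges are collapsed
    to a simple undirected graph with a logged warning.
    """
    raw = nx.read_gml(str(path), label="id")
    simple = nx.Graph()
    simple.add_nodes_from(str(v) for v in raw.nodes)
    dropped = 0
    for u, v in raw.edges():
        su, sv = str(u), str(v)
        if su == sv or simple.has_edge(su, sv):
            dropped += 1
            continue
        simple.add_edge(su, sv)
    if raw.is_directed() or dropped:
        log.warning(
            "%s: collapsed to a simple undirected graph (%d self-loop/duplicate edge(s) dropped)",
            path,
            dropped,
        )
    return simple


def read_partition(path, comment_prefix: str = "#") -> Partition:
    """Load a two-column ``node community`` file as a :class:`Partition`.

    A node listed twice with different communities is an error (overlapping
    communities are unsupported). Consistency with any particular graph is
    checked at use time, not here.
    """
    path = Path(path)
    assignment: dict[str, str] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(comment_prefix):
                continue
            toks = _tokens(line)
            if len(toks) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'node community', got {len(toks)} token(s)")
            node, cid = toks[0], toks[1]
            if node in assignment and assignment[node] != cid:
                raise ValueError(
                    f"{path}:{lineno}: node {node!r} assigned to both "
                    f"{assignment[node]!r} and {cid!r} (overlapping communities unsupported)"
                )
            assignment[node] = cid
    return Partition(assignment)


def write_partition(partition: Partition, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for node, cid in partition.assignment.items():
            fh.write(f"{node} {cid}\n")
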