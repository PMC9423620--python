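"""Synthetic modular benchmark graphs.

``generate_lfr`` produces LFR-style networks: power-law degree sequence
(exponent γ, bounded by a maximum degree, mean pinned to a target average),
power-law community sizes (exponent θ, bounded min/max), a planted
node-to-community assignment, and a tunable mixing parameter μ — the
expected fraction of each node's edges that leave its community. The
procedure follows the classical benchmark construction: split each node's
degree into internal and external stubs (stochastic rounding, so the
realized mixing is unbiased), assign nodes to communities with the
kick-out loop (a node may only join a community strictly larger than its
internal degree), wire internal stubs per community and external stubs
globally with a configuration-model matching, and repair self-loops,
duplicate edges and intra-community external edges by recycling stubs.
Generation retries under derived seeds until the realized μ lies within
±0.05 of the target.

The planted ground-truth partition is returned alongside the graph,
matching experimental designs where planted communities are used directly
rather than re-detected.

``generate_planted_partition`` gives small Bernoulli block-model fixtures,
and ``toy_network`` a fixed 22-node worked example.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from ._rng import generator
from .community import Partition, mixing_parameter

__all__ = ["LFRParams", "generate_lfr", "generate_planted_partition", "toy_network"]

MU_TOLERANCE = 0.05  # acceptable |realized - target| mixing
_MAX_ATTEMPTS = 12


@dataclass(frozen=True)
class LFRParams:
    """Benchmark parameters; defaults give the standard 2500-node setting."""

    n: int = 2500
    avg_degree: float = 8.0
    max_degree: int = 27
    theta: float = 2.7  # community-size power-law exponent
    gamma: float = 2.7  # degree power-law exponent
    min_community: int = 4
    max_community: int = 250
    mu: float = 0.05

    def __post_init__(self):
        if not self.min_community <= self.max_community <= self.n:
            raise ValueError("need min_community <= max_community <= n")
        if not 0.0 < self.mu < 1.0:
            raise ValueError(f"mu must lie in (0, 1), got {self.mu}")
        if self.theta <= 1.0 or self.gamma <= 1.0:
            raise ValueError("power-law exponents must exceed 1")
        if not 1 <= self.max_degree < self.n:
            raise ValueError("need 1 <= max_degree < n")
        if not 1.0 <= self.avg_degree <= self.max_degree:
            raise ValueError("need 1 <= avg_degree <= max_degree")


class _GenerationError(RuntimeError):
    pass


def _powerlaw_probs(exponent: float, lo: int, hi: int, target_mean: float | None = None):
    """Discrete bounded power law p(k) ∝ k^-exponent on [lo, hi].

    With ``target_mean``, the lower cutoff is tuned continuously by scaling
    the boundary integer's weight (equivalent to a real-valued cutoff) so
    the expectation hits the target exactly.
    """
    ks = np.arange(lo, hi + 1, dtype=float)
    w = ks**-exponent
    if target_mean is None:
        return ks.astype(int), w / w.sum()

    def mean_with(lo_idx: int, c: float) -> float:
        ww = w[lo_idx:].copy()
        ww[0] *= c
        return float((ks[lo_idx:] * ww).sum() / ww.sum())

    if target_mean < mean_with(0, 1.0) or target_mean > hi:
        raise _GenerationError(
            f"mean {target_mean} unreachable for exponent {exponent} on [{lo}, {hi}]"
        )
    lo_idx = 0
    while lo_idx + 1 < len(ks) and mean_with(lo_idx + 1, 1.0) <= target_mean:
        lo_idx += 1
    c_lo, c_hi = 1e-12, 1.0  # mean decreases as boundary weight c grows
    for _ in range(80):
        c_mid = 0.5 * (c_lo + c_hi)
        if mean_with(lo_idx, c_mid) > target_mean:
            c_lo = c_mid
        else:
            c_hi = c_mid
    ww = w[lo_idx:].copy()
    ww[0] *= 0.5 * (c_lo + c_hi)
    return ks[lo_idx:].astype(int), ww / ww.sum()


def _degree_cutoff(gamma: float, kmax: int, target_mean: float) -> float:
    """Real lower cutoff x_min such that E[floor(X)] hits the target mean
    for X ~ bounded Pareto(gamma) on [x_min, kmax + 1)."""

    def mean_floor(xmin: float) -> float:
        b = kmax + 1.0
        a = 1.0 - gamma

        def cdf_mass(lo: float, hi: float) -> float:
            lo, hi = max(lo, xmin), min(hi, b)
            if hi <= lo:
                return 0.0
            return hi**a - lo**a  # unnormalized

        total = cdf_mass(xmin, b)
        ks = np.arange(int(np.floor(xmin)), kmax + 1)
        masses = np.array([cdf_mass(k, k + 1.0) for k in ks])
        return float((ks * masses).sum() / total)

    lo, hi = 1.0, float(kmax)
    if not mean_floor(lo) <= target_mean <= mean_floor(hi):
        raise _GenerationError(
            f"mean degree {target_mean} unreachable for gamma={gamma}, max degree {kmax}"
        )
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if mean_floor(mid) < target_mean:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _sample_degrees(p: LFRParams, rng: np.random.Generator) -> np.ndarray:
    """Floored continuous bounded power law with the requested mean."""
    xmin = _degree_cutoff(p.gamma, p.max_degree, p.avg_degree)
    a = 1.0 - p.gamma
    u = rng.random(p.n)
    x = (xmin**a + u * ((p.max_degree + 1.0) ** a - xmin**a)) ** (1.0 / a)
    deg = np.floor(x).astype(np.int64)
    np.clip(deg, 1, p.max_degree, out=deg)
    if deg.sum() % 2:  # stub count must be even
        i = int(rng.integers(p.n))
        deg[i] += 1 if deg[i] < p.max_degree else -1
    return deg


def _hall_feasible(sizes: np.ndarray, k_int_sorted: np.ndarray) -> bool:
    """Can communities of these sizes be filled, given that a node of
    internal degree d only fits a community strictly larger than d?

    Nested structure makes Hall's condition one-dimensional: for every
    size threshold t, the capacity of communities of size <= t must not
    exceed the number of nodes with internal degree < t.
    """
    for t in np.unique(sizes):
        capacity = int(sizes[sizes <= t].sum())
        hosts = int(np.searchsorted(k_int_sorted, t, side="left"))  # k_int <= t-1
        if capacity > hosts:
            return False
    return True


def _sample_community_sizes(p: LFRParams, k_int: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Power-law community sizes that can host the internal-degree sequence.

    If the requested minimum community size cannot be filled (every node's
    internal degree is too large for the smallest communities), the
    effective minimum is raised until the size sequence is feasible; the
    realized sizes always stay inside [min_community, max_community].
    """
    k_sorted = np.sort(k_int)
    smax = p.max_community
    for smin in range(p.min_community, smax + 1):
        for _ in range(8):  # a few draws per candidate minimum
            ks, probs = _powerlaw_probs(p.theta, smin, smax)
            sizes: list[int] = []
            total = 0
            while total < p.n:
                s = int(rng.choice(ks, p=probs))
                sizes.append(s)
                total += s
            excess = total - p.n
            if excess:
                if sizes[-1] - excess >= smin:
                    sizes[-1] -= excess
                else:
                    deficit = sizes.pop() - excess
                    while deficit > 0:
                        growable = [i for i, s in enumerate(sizes) if s < smax]
                        if not growable:
                            raise _GenerationError("cannot redistribute community-size remainder")
                        sizes[int(rng.choice(growable))] += 1
                        deficit -= 1
            arr = np.array(sizes, dtype=np.int64)
            if _hall_feasible(arr, k_sorted):
                return arr
    raise _GenerationError("no feasible community-size sequence for this degree split")


def _split_degrees(deg: np.ndarray, mu: float, max_size: int, rng: np.random.Generator):
    """Split each degree into external/internal stubs (stochastic rounding)."""
    ext_f = mu * deg
    k_ext = np.floor(ext_f).astype(np.int64)
    k_ext += (rng.random(len(deg)) < (ext_f - k_ext)).astype(np.int64)
    k_int = deg - k_ext
    # a node can only sit in a community strictly larger than its internal degree
    over = k_int > max_size - 1
    k_ext[over] += k_int[over] - (max_size - 1)
    k_int[over] = max_size - 1
    return k_int, k_ext


def _assign_communities(k_int: np.ndarray, k_ext: np.ndarray, sizes: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """Capacity-aware placement, largest internal degree first.

    Each node joins a community chosen at random (weighted by free slots)
    among those strictly larger than its internal degree. Total capacity
    equals n, so placing demanding nodes first keeps the packing feasible;
    in the rare case no fitting community has a free slot, the node's
    internal degree is capped to the largest available community and the
    excess moves to its external stubs (mutating ``k_int``/``k_ext``).
    """
    n, q = len(k_int), len(sizes)
    comm = np.full(n, -1, dtype=np.int64)
    free = sizes.copy()
    order = np.lexsort((rng.random(n), -k_int))
    for v in order:
        eligible = np.flatnonzero((sizes > k_int[v]) & (free > 0))
        if len(eligible) == 0:
            open_c = np.flatnonzero(free > 0)
            c = int(open_c[np.argmax(sizes[open_c])])
            excess = int(k_int[v] - (sizes[c] - 1))
            k_int[v] -= excess
            k_ext[v] += excess
        else:
            w = free[eligible].astype(float)
            c = int(rng.choice(eligible, p=w / w.sum()))
        comm[v] = c
        free[c] -= 1
    return comm


def _match_stubs(stubs: list[int], rng: np.random.Generator, forbid=None, max_rounds: int = 80):
    """Configuration-model matching into a simple edge set.

    Colliding stubs (self-loops, duplicates, forbidden pairs) are pooled and
    re-shuffled; deadlocks are broken by recycling stubs from already-placed
    edges. Returns (edges, dropped_pair_count).
    """
    edges: set[tuple[int, int]] = set()
    pool = list(stubs)
    for round_no in range(max_rounds):
        if not pool:
            return edges, 0
        rng.shuffle(pool)
        leftover: list[int] = []
        for i in range(0, len(pool) - 1, 2):
            u, v = pool[i], pool[i + 1]
            key = (u, v) if u < v else (v, u)
            if u == v or key in edges or (forbid is not None and forbid(u, v)):
                leftover.extend((u, v))
            else:
                edges.add(key)
        if len(pool) % 2:
            leftover.append(pool[-1])
        pool = leftover
        if pool and round_no >= 2 and edges:
            # recycle random placed edges to escape locked configurations
            recycle = min(len(edges), max(2, len(pool)))
            edge_list = list(edges)
            idx = rng.choice(len(edge_list), size=recycle, replace=False)
            for i in idx:
                u, v = edge_list[i]
                edges.discard((u, v))
                pool.extend((u, v))
    return edges, len(pool) // 2


def _realize_degree_sequence(idx: np.ndarray, degs: np.ndarray, rng: np.random.Generator):
    """Exact realization of a (near-)dense degree sequence, then randomized.

    Havel–Hakimi always realizes a graphical sequence as a simple graph;
    double-edge swaps then randomize it. Used for small dense communities
    where random stub-matching deadlocks.
    """
    seq = sorted((int(d) for d in degs), reverse=True)
    local = nx.havel_hakimi_graph(seq)
    # havel_hakimi_graph sorts internally; map its degree-sorted nodes back
    by_deg_local = sorted(local.nodes, key=lambda v: -local.degree(v))
    by_deg_ours = idx[np.argsort(-degs, kind="stable")]
    relabel = {lv: int(ov) for lv, ov in zip(by_deg_local, by_deg_ours)}
    m = local.number_of_edges()
    if m > 1:
        try:
            nx.double_edge_swap(local, nswap=4 * m, max_tries=40 * m + 100,
                                seed=int(rng.integers(2**31)))
        except nx.NetworkXException:
            pass  # near-complete: few legal swaps, realization is already valid
    return {(min(a, b), max(a, b)) for u, v in local.edges()
            for a, b in [(relabel[u], relabel[v])]}


def _attempt_lfr(p: LFRParams, rng: np.random.Generator):
    deg = _sample_degrees(p, rng)
    k_int, k_ext = _split_degrees(deg, p.mu, p.max_community, rng)
    sizes = _sample_community_sizes(p, k_int, rng)
    comm = _assign_communities(k_int, k_ext, sizes, rng)

    # per-community graphicality: internal stub sum must be even and the
    # sequence realizable; shave the largest internal degree until it is
    for c in range(len(sizes)):
        idx = np.flatnonzero(comm == c)
        for _ in range(len(idx) + 2):
            seq = [int(d) for d in k_int[idx]]
            if sum(seq) % 2 == 0 and nx.is_graphical(seq):
                break
            v = int(idx[np.argmax(k_int[idx])])
            if k_int[v] == 0:
                break
            k_int[v] -= 1
            k_ext[v] += 1

    edges: set[tuple[int, int]] = set()
    dropped = 0
    for c in range(len(sizes)):
        idx = np.flatnonzero(comm == c)
        stubs = np.repeat(idx, k_int[idx]).tolist()
        if not stubs:
            continue
        n_c, m_c = len(idx), len(stubs) // 2
        density = m_c / (n_c * (n_c - 1) / 2)
        if density > 0.55:
            edges |= _realize_degree_sequence(idx, k_int[idx], rng)
            continue
        placed, d = _match_stubs(stubs, rng)
        if d:
            edges |= _realize_degree_sequence(idx, k_int[idx], rng)
        else:
            edges |= placed

    ext_stubs = np.repeat(np.arange(p.n), k_ext).tolist()
    if len(ext_stubs) % 2:
        ext_stubs.pop(int(rng.integers(len(ext_stubs))))
    placed, d = _match_stubs(ext_stubs, rng, forbid=lambda u, v: comm[u] == comm[v])
    edges |= placed
    dropped += d
    if dropped > 0.02 * len(edges):
        raise _GenerationError(f"too many unplaceable stub pairs ({dropped})")

    graph = nx.Graph()
    graph.add_nodes_from(str(i) for i in range(p.n))
    graph.add_edges_from((str(u), str(v)) for u, v in edges)
    partition = Partition({str(i): f"c{comm[i]}" for i in range(p.n)})
    return graph, partition


def generate_lfr(params: LFRParams, rng_seed: int):
    """Generate one benchmark graph with its planted partition.

    Deterministic given ``rng_seed``. Retries internally (bounded) over
    derived seeds until the realized mixing parameter lies within
    ±0.05 of ``params.mu``; raises with the attempted seed count otherwise.
    """
    last = "no attempt"
    for attempt in range(_MAX_ATTEMPTS):
        rng = generator(rng_seed, "lfr", attempt)
        try:
            graph, partition = _attempt_lfr(params, rng)
        except _GenerationError as err:
            last = str(err)
            continue
        mu_real = mixing_parameter(graph, partition)
        if abs(mu_real - params.mu) <= MU_TOLERANCE:
            return graph, partition
        last = f"realized mu {mu_real:.3f} outside {params.mu}±{MU_TOLERANCE}"
    raise RuntimeError(f"LFR generation failed after {_MAX_ATTEMPTS} attempts: {last}")


def generate_planted_partition(q: int, size: int, p_in: float, p_out: float, rng_seed: int):
    """q blocks of ``size`` nodes; intra-pair edges w.p. p_in, inter w.p. p_out."""
    if q < 1 or size < 2:
        raise ValueError("need q >= 1 and size >= 2")
    if not 0.0 <= p_out <= p_in <= 1.0:
        raise ValueError("need 0 <= p_out <= p_in <= 1")
    rng = generator(rng_seed, "planted")
    n = q * size
    block = np.arange(n) // size
    graph = nx.Graph()
    graph.add_nodes_from(str(i) for i in range(n))
    iu, ju = np.triu_indices(n, k=1)
    p = np.where(block[iu] == block[ju], p_in, p_out)
    keep = rng.random(len(p)) < p
    graph.add_edges_from((str(int(u)), str(int(v))) for u, v in zip(iu[keep], ju[keep]))
    partition = Partition({str(i): f"c{block[i]}" for i in range(n)})
    return graph, partition


#: Synthetic 22-node worked example with three communities of sizes 9, 7, 6.
#: Constructed so that the three highest-degree nodes (5, 1, 4) all sit in
#: the largest community while the per-community degree leaders are 5, 13
#: and 19, and the three highest-betweenness nodes (13, 14, 15) all sit in
#: the middle community while the per-community betweenness leaders are 3,
#: 13 and 21 — the configuration in which the two ranking schemes diverge
#: most visibly.
_TOY_EDGES = [
    (5, 1), (5, 2), (5, 3), (5, 4), (5, 6), (5, 7), (5, 8), (5, 9),
    (1, 2), (1, 3), (1, 4), (1, 6), (1, 7), (1, 8),
    (4, 2), (4, 6), (4, 7), (4, 8), (4, 9),
    (3, 6), (3, 7), (3, 8),
    (2, 13), (3, 13),
    (13, 10), (13, 11), (13, 12), (13, 14), (14, 15), (14, 16), (10, 11), (11, 12),
    (15, 21),
    (19, 17), (19, 18), (19, 20), (19, 21), (19, 22), (21, 20), (21, 22), (17, 18),
]


def toy_network():
    """The fixed 22-node, 3-community example graph and its partition."""
    graph = nx.Graph((str(u), str(v)) for u, v in _TOY_EDGES)
    assignment = {}
    for i in range(1, 10):
        assignment[str(i)] = "C1"
    for i in range(10, 17):
        assignment[str(i)] = "C2"
    for i in range(17, 23):
        assignment[str(i)] = "C3"
    return graph, Partition(assignment)
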