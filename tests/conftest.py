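import networkx as nx
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from carank import Partition, toy_network

settings.register_profile(
    "ci", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy():
    """The 22-node, 3-community worked example (graph, partition)."""
    return toy_network()


@pytest.fixture()
def two_cliques_bridge():
    """Two 4-cliques joined by a single edge, with the obvious partition."""
    g = nx.Graph()
    for base, cid in ((0, "A"), (4, "B")):
        for i in range(base, base + 4):
            for j in range(i + 1, base + 4):
                g.add_edge(str(i), str(j))
    g.add_edge("0", "4")
    part = Partition({str(i): ("A" if i < 4 else "B") for i in range(8)})
    return g, part


def algorithm_oracle(scores: dict, communities_in_order: list, budget: int) -> list:
    """Literal transcription of the round-robin extraction pseudocode.

    ``communities_in_order`` is the sorted community set (largest first);
    per-community node lists are sorted by descending score, then nodes are
    popped one per community per pass until the budget is exhausted. Scores
    are assumed tie-free so the result is unique.
    """
    queues = [sorted(members, key=lambda v: -scores[v]) for members in communities_in_order]
    L: list = []
    B = budget
    while B != 0:
        for q in queues:
            if q:
                L.append(q.pop(0))
                B -= 1
                if B == 0:
                    break
    return L


def random_tie_free_instance(rng: np.random.Generator):
    """Random partition of <= 10 nodes into communities of distinct sizes,
    with distinct scores — the regime where the ranked list is unique."""
    candidates = [[s] for s in range(1, 11)]
    candidates += [[a, b] for a in range(1, 10) for b in range(a + 1, 11) if a + b <= 10]
    candidates += [
        [a, b, c]
        for a in range(1, 9)
        for b in range(a + 1, 10)
        for c in range(b + 1, 11)
        if a + b + c <= 10
    ]
    sizes = candidates[rng.integers(len(candidates))]
    n = sum(sizes)
    node_order = rng.permutation(n)
    communities, pos = [], 0
    for s in sizes:
        communities.append([str(v) for v in node_order[pos : pos + s]])
        pos += s
    score_vals = rng.permutation(n * 3)[:n].astype(float)
    scores = {str(v): float(score_vals[i]) for i, v in enumerate(node_order)}
    budget = int(rng.integers(1, n + 1))
    return scores, communities, budget
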