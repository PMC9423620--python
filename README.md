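# carank — community-aware ranking of influential spreaders

Centrality measures are the standard tool for picking the nodes that will
seed (or block) a spreading process on a network. Ranking all nodes by
descending centrality, however, tends to select nodes that sit next to each
other inside the same dense region, so their zones of influence overlap and
large parts of the network are never reached. `carank` implements a
community-aware alternative: given any centrality measure β and a partition
of the network into communities, it

1. sorts the communities from the biggest to the smallest (ties at random),
2. sorts nodes by β *within* their community (score ties at random), and
3. emits seeds round-robin — the best node of each community, then the
   second-best of each community, and so on — until the budget *B* is
   reached.

The selected spreaders are thereby scattered across every dense region of
the graph. The package is aimed at researchers in network epidemiology and
influence maximization who want to use the scheme on their own graphs or
reproduce its synthetic-benchmark evaluation.

## What the package contains

| module | contents |
| --- | --- |
| `carank.ranking` | `descending_rank`, `community_aware_rank` (the scheme above) |
| `carank.centrality` | Degree, Maximum Neighborhood Component, Betweenness, Closeness, Katz, PageRank |
| `carank.community` | `Partition`, community ordering, mixing parameter μ, strength labels, detection adapter (Infomap/Louvain/Leiden via igraph) |
| `carank.sir` | discrete-time SIR simulator, epidemic threshold, the outbreak-gain statistic ΔR |
| `carank.synth` | LFR-style modular benchmark generator, planted-partition fixtures, a 22-node worked example |
| `carank.experiments` | config-driven sweeps producing ΔR-vs-f_o curves with manifests |
| `carank.graph_io` | plain-text edge lists, GML, two-column partition files |

The evaluation statistic is

ΔR = 100 · (R̄_CA − R̄_DO) / n,

where R̄_CA and R̄_DO are the mean SIR outbreak sizes (recovered nodes)
when the top fraction f_o of nodes under the community-aware and the
descending-order ranking are initially infected, and n is the network
size. A positive ΔR means the community-aware seeds ignited the larger
epidemic. (The baseline-relative variant 100·(R̄_CA−R̄_DO)/R̄_DO is also
reported by `carank.sir.delta_r`.) The SIR transmission probability is
calibrated to the degree-distribution epidemic threshold
λ = c·⟨k⟩/(⟨k²⟩−⟨k⟩), with multiplier c = 1.5 and one-step recovery by
default; see `docs/methods.md` for why.

## Worked example

The bundled 22-node network has three communities (sizes 9, 7, 6) and a
strong community structure. With Degree centrality and a budget of three
seeds:

```python
from carank import (toy_network, compute_centrality, descending_rank,
                    community_aware_rank, mixing_parameter, classify_strength,
                    epidemic_threshold, SIRParams, delta_r)

graph, partition = toy_network()
mu = mixing_parameter(graph, partition)
print(f"n = {graph.number_of_nodes()}, m = {graph.number_of_edges()}, "
      f"|C| = {len(partition)}, mu = {mu:.3f} ({classify_strength(mu)})")

deg = compute_centrality(graph, "degree")
print("descending order, budget 3:   ", list(descending_rank(deg, 3, rng_seed=0)))
print("community-aware, budget 3:    ", list(community_aware_rank(deg, partition, 3, rng_seed=0)))

lam = 1.5 * epidemic_threshold(graph)
res = delta_r(graph, deg, partition, f_o=0.15,
              params=SIRParams(infection_prob=lam, runs=2000), rng_seed=7)
print(f"mean outbreak: community-aware {res.mean_recovered_ca:.1f}, "
      f"descending {res.mean_recovered_do:.1f}")
print(f"delta R = {res.percent_of_n:+.1f}% of the network (+/- {res.stderr_of_n:.1f})")
```

prints

```
n = 22, m = 41, |C| = 3, mu = 0.073 (strong)
descending order, budget 3:    ['5', '1', '4']
community-aware, budget 3:     ['5', '13', '19']
mean outbreak: community-aware 14.9, descending 9.8
delta R = +23.2% of the network (+/- 0.4)
```

The three highest-degree nodes (5, 1, 4) all sit in the largest community,
so the classical ranking concentrates every seed there and the epidemic
often dies before crossing the sparse bridges. The community-aware list
takes the degree leader of each community (5, 13, 19) instead, and the
mean outbreak grows from 9.8 to 14.9 nodes — a gain of 23 % of the network.

The same machinery runs from the shell: `carank rank`, `carank evaluate`,
`carank synth lfr`, `carank community --report`, and `carank run --config
exp.yaml` for full sweeps (see `--help` on each subcommand).

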