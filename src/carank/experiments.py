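"""Experiment orchestration: ΔR curves over networks × measures × budgets.

A single config drives the full sweep: a network source (LFR parameters
with a replicate count, or explicit graph/partition files), the centrality
measures, the f_o grid, and the SIR calibration. Every cell draws its RNG
stream from (master seed, replicate, measure, f_o), so execution order is
irrelevant and any cell can be recomputed in isolation. Each run writes a
manifest echoing all resolved settings — the SIR calibration knobs (λ
multiplier, run count, replicates) are always recorded alongside the
results they produced.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from ._rng import generator
from .centrality import MEASURES, compute_centrality
from .community import mixing_parameter
from .graph_io import read_edge_list, read_partition
from .sir import SIRParams, default_infection_prob, delta_r
from .synth import LFRParams, generate_lfr

__all__ = ["ExperimentConfig", "run_experiment", "peak_delta_r", "write_outputs"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExperimentConfig:
    measures: tuple[str, ...]
    fo_grid: tuple[float, ...]
    lfr: LFRParams | None = None
    replicates: int = 10
    graph_path: str | None = None
    partition_path: str | None = None
    runs: int = 500
    recovery_prob: float = 1.0
    lambda_multiplier: float = 1.5
    normalization: str = "network"  # "network": ΔR as % of n; "baseline": % of R̄_DO
    master_seed: int = 0
    label: str = "experiment"
    katz_alpha: float | None = None
    pagerank_damping: float = 0.85

    def __post_init__(self):
        if self.normalization not in ("network", "baseline"):
            raise ValueError("normalization must be 'network' or 'baseline'")
        if not self.measures:
            raise ValueError("at least one centrality measure is required")
        unknown = [m for m in self.measures if m not in MEASURES]
        if unknown:
            raise ValueError(f"unknown measure(s) {unknown}; valid: {', '.join(MEASURES)}")
        if not self.fo_grid:
            raise ValueError("f_o grid must be non-empty")
        bad = [f for f in self.fo_grid if not 0.0 < f <= 1.0]
        if bad:
            raise ValueError(f"f_o values must lie in (0, 1], got {bad}")
        if (self.lfr is None) == (self.graph_path is None):
            raise ValueError("exactly one network source required: lfr params or graph/partition paths")
        if self.graph_path is not None and self.partition_path is None:
            raise ValueError("a partition file is required with a graph file")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        data = dict(data)
        if "lfr" in data and data["lfr"] is not None:
            data["lfr"] = LFRParams(**data["lfr"])
        for key in ("measures", "fo_grid"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_manifest(self) -> dict:
        out = dataclasses.asdict(self)
        if self.lfr is not None:
            out["lfr"] = dataclasses.asdict(self.lfr)
        return out


def _networks(config: ExperimentConfig):
    if config.lfr is not None:
        for rep in range(config.replicates):
            seed = int(generator(config.master_seed, "network", rep).integers(2**31))
            yield f"{config.label}/lfr{rep}", generate_lfr(config.lfr, seed)
    else:
        graph = read_edge_list(config.graph_path)
        partition = read_partition(config.partition_path)
        partition.require_covers(graph)
        yield f"{config.label}/file", (graph, partition)


def run_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Evaluate ΔR for every network replicate × measure × f_o.

    Centralities are computed once per network. Returns one aggregated row
    per (measure, f_o): mean ΔR over replicates, its standard error, and
    the mean realized mixing parameter and community count of the networks.
    """
    rows = []
    for rep, (net_label, (graph, partition)) in enumerate(_networks(config)):
        lam = default_infection_prob(graph, config.lambda_multiplier)
        mu_real = mixing_parameter(graph, partition)
        log.info("network %s: n=%d m=%d mu=%.3f |C|=%d lambda=%.4f", net_label,
                 graph.number_of_nodes(), graph.number_of_edges(), mu_real, len(partition), lam)
        for measure in config.measures:
            try:
                scores = compute_centrality(graph, measure, katz_alpha=config.katz_alpha,
                                            pagerank_damping=config.pagerank_damping)
            except Exception as err:
                raise RuntimeError(f"centrality failed at ({net_label}, {measure})") from err
            for f_o in config.fo_grid:
                cell_seed = int(generator(config.master_seed, "cell", rep, measure, round(f_o * 10000)).integers(2**31))
                params = SIRParams(infection_prob=lam, recovery_prob=config.recovery_prob,
                                   runs=config.runs, rng_seed=0)
                try:
                    res = delta_r(graph, scores, partition, f_o, params, cell_seed)
                except Exception as err:
                    raise RuntimeError(f"delta_r failed at ({net_label}, {measure}, {f_o})") from err
                if config.normalization == "network":
                    value, err = res.percent_of_n, res.stderr_of_n
                else:
                    value, err = res.percent, res.stderr
                rows.append({
                    "network": net_label, "measure": measure, "f_o": f_o,
                    "delta_r_pct": value, "stderr": err,
                    "realized_mu": mu_real, "n_communities": len(partition),
                    "budget": res.budget,
                })
    per_cell = pd.DataFrame(rows)
    grouped = per_cell.groupby(["measure", "f_o"], as_index=False).agg(
        delta_r_pct=("delta_r_pct", "mean"),
        stderr=("delta_r_pct", lambda s: s.std(ddof=1) / (len(s) ** 0.5) if len(s) > 1 else 0.0),
        within_stderr=("stderr", lambda s: (s**2).mean() ** 0.5),
        realized_mu=("realized_mu", "mean"),
        n_communities=("n_communities", "mean"),
        replicates=("network", "nunique"),
    )
    return grouped.sort_values(["measure", "f_o"]).reset_index(drop=True)


def peak_delta_r(curve: pd.DataFrame) -> pd.DataFrame:
    """Per-measure maximum of the mean ΔR over the f_o grid."""
    idx = curve.groupby("measure")["delta_r_pct"].idxmax()
    return curve.loc[idx, ["measure", "f_o", "delta_r_pct", "stderr"]].reset_index(drop=True)


def write_outputs(curve: pd.DataFrame, config: ExperimentConfig, out_prefix) -> None:
    """Persist the curve as TSV plus a JSON manifest of resolved settings."""
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    curve.to_csv(f"{prefix}.tsv", sep="\t", index=False, float_format="%.6g")
    with open(f"{prefix}.manifest.json", "w") as fh:
        json.dump(config.to_manifest(), fh, indent=2, default=str)
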