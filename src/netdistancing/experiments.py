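"""Config-driven experiment runners: lambda sweeps, structure reports and
tipping-point reports comparing removal strategies at equal link density.

The runners operate at desk scale by default (10 configurations per
ensemble cell, 200 epidemic realizations) — enough to reproduce every
qualitative comparison; the full-scale study values (100 configurations,
640 realizations) are one config flag away.

``surrogate_highschool`` generates a community-structured stand-in for a
school-sized friendship network (a planted-partition / stochastic block
graph); it emulates scale and community structure only, not any measured
contact data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .graphs import (
    Graph,
    RG_RADIUS_MEAN_DEGREE_18,
    component_summary,
    degree_histogram,
    generate_ba,
    generate_rg,
    read_edge_list,
)
from .mcmc import DEFAULT_STEPS, mcmc_run, spawn_seeds
from .removal import (
    degree_cap_for_rate,
    degree_product_removal,
    edge_betweenness_removal,
    random_removal,
)
from .epidemic import EpidemicParams, tipping_scan

__all__ = [
    "ExperimentConfig",
    "surrogate_highschool",
    "graph_factory",
    "sample_removal",
    "run_lambda_sweep",
    "run_structure_report",
    "run_tipping_report",
]

STRATEGIES = ("random", "wcne", "degree-product", "degree-cap", "betweenness")


def surrogate_highschool(
    n: int = 1062,
    communities: int = 30,
    mean_degree: float = 8.0,
    intra_fraction: float = 0.9,
    seed: int = 0,
) -> Graph:
    """Community-structured random graph at school scale (synthetic).

    Planted-partition style: ``communities`` near-equal groups, with
    intra-group connection probability chosen so that ``intra_fraction`` of
    a node's expected degree is within its group.  With communities=1 this
    degenerates to an Erdős–Rényi graph at the target mean degree.
    """
    if communities < 1 or n < communities:
        raise ValueError("need 1 <= communities <= n")
    if not 0 < mean_degree < n - 1:
        raise ValueError("infeasible mean degree")
    if not 0 <= intra_fraction <= 1:
        raise ValueError("intra_fraction must be in [0, 1]")
    base, extra = divmod(n, communities)
    sizes = [base + 1] * extra + [base] * (communities - extra)
    s_bar = n / communities
    if communities == 1:
        p_in = mean_degree / (n - 1)
        p_out = 0.0
    else:
        p_in = intra_fraction * mean_degree / max(s_bar - 1, 1)
        p_out = (1 - intra_fraction) * mean_degree / (n - s_bar)
    if p_in > 1 or p_out > 1:
        raise ValueError("infeasible mean degree for this community layout")
    p = np.full((communities, communities), p_out)
    np.fill_diagonal(p, p_in)
    g = nx.stochastic_block_model(sizes, p.tolist(), seed=int(seed))
    return Graph.from_networkx(nx.Graph(g))


@dataclass
class ExperimentConfig:
    """One experiment: ensemble spec, strategy set, sweep grids, seeds.

    Serialisable to/from YAML; ``config_hash`` fingerprints the whole
    configuration so every output row is traceable to it.
    """

    ensemble: str = "ba"  # ba | rg | surrogate | file
    ensemble_params: dict = field(default_factory=dict)
    strategies: tuple = ("random", "wcne")
    rho_grid: tuple = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
    nu: float = 1000.0
    steps: int = DEFAULT_STEPS
    n_configs: int = 10
    epidemic: dict = field(
        default_factory=lambda: {
            "model": "sis",
            "delta": 0.5,
            "ratios": [round(0.04 * k, 2) for k in range(1, 26)],
            "threshold": 0.01,
            "n_realizations": 200,
            "initial_infected": 10,
            "max_steps": 1000,
        }
    )
    master_seed: int = 0

    def __post_init__(self):
        self.strategies = tuple(self.strategies)
        self.rho_grid = tuple(float(r) for r in self.rho_grid)
        if not self.rho_grid or not self.strategies:
            pass  # empty strategy set is allowed: runners emit empty tables
        for s in self.strategies:
            if s not in STRATEGIES:
                raise ValueError(f"unknown strategy {s!r}; choose from {STRATEGIES}")

    @property
    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def graph_factory(config: ExperimentConfig):
    """Callable seed -> starting Graph for the configured ensemble."""
    kind = config.ensemble
    p = config.ensemble_params
    if kind == "ba":
        return lambda s: generate_ba(p.get("n", 100), p.get("m", 10), seed=s)
    if kind == "rg":
        return lambda s: generate_rg(
            p.get("n", 100), p.get("radius", RG_RADIUS_MEAN_DEGREE_18), seed=s
        )
    if kind == "surrogate":
        return lambda s: surrogate_highschool(
            n=p.get("n", 1062),
            communities=p.get("communities", 30),
            mean_degree=p.get("mean_degree", 8.0),
            intra_fraction=p.get("intra_fraction", 0.9),
            seed=s,
        )
    if kind == "file":
        g = read_edge_list(p["path"])
        return lambda s: g
    raise ValueError(f"unknown ensemble {kind!r}")


def sample_removal(g: Graph, strategy: str, rho: float, nu: float, steps: int, seed: int) -> Graph:
    """One reduced network from the given strategy at removal rate rho."""
    if strategy == "random":
        return random_removal(g, rho, seed)
    if strategy == "wcne":
        return mcmc_run(g, rho=rho, nu=nu, steps=steps, seed=seed).final_graph
    if strategy == "degree-product":
        return degree_product_removal(g, rho, seed)
    if strategy == "degree-cap":
        return degree_cap_for_rate(g, rho, seed)
    if strategy == "betweenness":
        return edge_betweenness_removal(g, rho, seed)
    raise ValueError(f"unknown strategy {strategy!r}")


def _iter_samples(config: ExperimentConfig, strategy: str, rho: float):
    """Yield (config_index, sub_seed, reduced Graph) for one sweep cell."""
    factory = graph_factory(config)
    key = f"{strategy}/rho={rho}"
    graph_seeds = spawn_seeds(config.master_seed, config.n_configs, key + "/g")
    run_seeds = spawn_seeds(config.master_seed, config.n_configs, key + "/r")
    for k in range(config.n_configs):
        g = factory(int(graph_seeds[k]))
        yield k, int(run_seeds[k]), sample_removal(
            g, strategy, rho, config.nu, config.steps, int(run_seeds[k])
        )


def run_lambda_sweep(config: ExperimentConfig) -> pd.DataFrame:
    """Mean/sd of lambda_max per (strategy, rho) cell.

    WCNE cells additionally carry the inverse genericity nu; all cells use
    config.n_configs independent starting graphs.
    """
    from .graphs import largest_eigenvalue

    rows = []
    for strategy in config.strategies:
        for rho in config.rho_grid:
            lams = []
            sub_seed = None
            for _, s, reduced in _iter_samples(config, strategy, rho):
                sub_seed = s if sub_seed is None else sub_seed
                lams.append(largest_eigenvalue(reduced))
            rows.append(
                {
                    "strategy": strategy,
                    "rho": rho,
                    "nu": config.nu if strategy == "wcne" else np.nan,
                    "mean_lambda_max": float(np.mean(lams)),
                    "sd_lambda_max": float(np.std(lams, ddof=1)) if len(lams) > 1 else 0.0,
                    "n_configs": config.n_configs,
                    "sub_seed": sub_seed,
                    "config_hash": config.config_hash,
                }
            )
    return pd.DataFrame(rows)


def run_structure_report(config: ExperimentConfig):
    """Component and degree-distribution metrics per (strategy, rho) cell.

    Returns (metrics, degrees): the first with mean component count, mean
    giant-component size and degree variance; the second with the pooled
    degree histogram of the cell's samples.
    """
    metric_rows, degree_rows = [], []
    for strategy in config.strategies:
        for rho in config.rho_grid:
            comps, giants, dvars = [], [], []
            pooled = {}
            sub_seed = None
            n_nodes = None
            for _, s, reduced in _iter_samples(config, strategy, rho):
                sub_seed = s if sub_seed is None else sub_seed
                cs = component_summary(reduced)
                comps.append(cs.n_components)
                giants.append(cs.giant_size)
                h = degree_histogram(reduced)
                dvars.append(h.variance())
                n_nodes = reduced.n_nodes
                for k, c in h.counts.items():
                    pooled[k] = pooled.get(k, 0) + c
            metric_rows.append(
                {
                    "strategy": strategy,
                    "rho": rho,
                    "mean_n_components": float(np.mean(comps)),
                    "mean_giant_size": float(np.mean(giants)),
                    "mean_degree_variance": float(np.mean(dvars)),
                    "n_configs": config.n_configs,
                    "n_nodes": n_nodes,
                    "sub_seed": sub_seed,
                    "config_hash": config.config_hash,
                }
            )
            for k in sorted(pooled):
                degree_rows.append(
                    {
                        "strategy": strategy,
                        "rho": rho,
                        "degree": k,
                        "count": pooled[k],
                        "config_hash": config.config_hash,
                    }
                )
    return pd.DataFrame(metric_rows), pd.DataFrame(degree_rows)


def run_tipping_report(config: ExperimentConfig, early_stop: bool = True) -> pd.DataFrame:
    """Critical beta/delta ratio per (strategy, rho) cell.

    Reduced networks come from ``n_configs`` independent draws of the
    strategy; the SIS (or SIR) scan averages the cumulative infected
    fraction over them and over ``n_realizations`` epidemic realizations.
    """
    ep = config.epidemic
    params = EpidemicParams(
        beta=0.0,
        delta=ep["delta"],
        initial_infected=ep["initial_infected"],
        max_steps=ep["max_steps"],
        n_realizations=ep["n_realizations"],
    )
    rows = []
    for strategy in config.strategies:
        for rho in config.rho_grid:
            graphs = [reduced for _, _, reduced in _iter_samples(config, strategy, rho)]
            scan_seed = int(spawn_seeds(config.master_seed, 1, f"scan/{strategy}/{rho}")[0])
            curve = tipping_scan(
                graphs,
                ep["ratios"],
                delta=ep["delta"],
                params=params,
                seed=scan_seed,
                threshold=ep["threshold"],
                model=ep["model"],
                early_stop=early_stop,
            )
            rows.append(
                {
                    "strategy": strategy,
                    "rho": rho,
                    "critical_ratio": curve.critical_ratio,
                    "reached": curve.reached,
                    "threshold": ep["threshold"],
                    "model": ep["model"],
                    "n_configs": config.n_configs,
                    "sub_seed": scan_seed,
                    "config_hash": config.config_hash,
                }
            )
    return pd.DataFrame(rows)
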