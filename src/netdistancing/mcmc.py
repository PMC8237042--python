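"""Metropolis sampler of the well-controlling network ensemble (WCNE).

Given a social graph with E edges and a contact reduction rate rho, the
generic ensemble q^rho is the uniform distribution over subgraphs with
(1 - rho) E edges.  The canonical ensemble relative to it,

    p(N) = exp(-nu * lambda_max(N)) * q^rho(N) / Z,

biases removals toward low spectral radius, i.e. toward a high epidemic
threshold, while staying as close as possible to generic random removal.
The inverse genericity nu interpolates between uniform random removal
(nu = 0) and spectral-radius minimisation (nu -> infinity); ensembles at
reasonably high nu are the WCNE.

Sampling is plain Metropolis: the proposal swaps one uniformly chosen kept
edge with one uniformly chosen removed edge (symmetric, so no Hastings
correction), and is accepted with probability
min(1, exp(nu * (e_current - e_proposed))) where the energy e is
lambda_max of the kept subgraph.  The removed-edge count is invariant.

``exact_stationary_distribution`` enumerates the state space of small
instances and computes the Boltzmann weights (and Z) explicitly; it exists
as an independent oracle for the sampler and is never used by it.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .graphs import Graph, _lambda_max_from_arrays
from .removal import n_edges_to_remove

__all__ = [
    "acceptance_probability",
    "MCMCState",
    "MCMCTrace",
    "EnsembleSummary",
    "propose_swap",
    "mcmc_run",
    "sample_ensemble",
    "exact_stationary_distribution",
]

ENERGY_TOL = 1e-8

#: Steps after which lambda_max has reached its steady state for the
#: n=100, <k>=18 ensembles studied here.
DEFAULT_STEPS = 11_000

#: Default inverse-genericity sweep; 1000 is the "reasonably high" WCNE value.
NU_GRID = (0.0, 10.0, 100.0, 500.0, 1000.0)


def acceptance_probability(e_current: float, e_proposed: float, nu: float) -> float:
    """Metropolis acceptance min(1, exp(nu * (e_current - e_proposed)))."""
    if nu < 0:
        raise ValueError(f"nu must be >= 0, got {nu}")
    if e_proposed <= e_current:
        return 1.0
    return math.exp(-nu * (e_proposed - e_current))


@dataclass
class MCMCState:
    """Partition of the original edge set into kept and removed subsets.

    ``graph`` is the original (full) graph; ``kept_idx`` / ``removed_idx``
    index rows of ``graph.edge_array()``.  Their union is always the full
    index range and their sizes never change.
    """

    graph: Graph
    kept_idx: np.ndarray
    removed_idx: np.ndarray
    energy: float
    step: int = 0
    eigvec: np.ndarray | None = field(default=None, repr=False)

    @property
    def kept_edges(self) -> frozenset:
        e = self.graph.edge_array()
        return frozenset(map(tuple, e[self.kept_idx]))

    @property
    def removed_edges(self) -> frozenset:
        e = self.graph.edge_array()
        return frozenset(map(tuple, e[self.removed_idx]))

    def current_graph(self) -> Graph:
        return self.graph.subgraph_with_edges(self.kept_edges)


@dataclass
class MCMCTrace:
    """Per-step energy/acceptance record of one sampler run."""

    energies: np.ndarray
    accepted: np.ndarray
    initial_energy: float
    final_graph: Graph
    nu: float
    rho: float
    steps: int
    seed: int

    @property
    def final_energy(self) -> float:
        return float(self.energies[-1]) if len(self.energies) else self.initial_energy

    @property
    def acceptance_rate(self) -> float:
        return float(self.accepted.mean()) if len(self.accepted) else float("nan")


@dataclass
class EnsembleSummary:
    """Final energies of independent sampler runs plus their first moments."""

    final_energies: np.ndarray
    nu: float
    rho: float
    steps: int
    seed: int
    final_graphs: list | None = None

    @property
    def n_configs(self) -> int:
        return len(self.final_energies)

    @property
    def mean(self) -> float:
        return float(np.mean(self.final_energies))

    @property
    def std(self) -> float:
        return float(np.std(self.final_energies, ddof=1)) if self.n_configs > 1 else 0.0


def _initial_state(g: Graph, rho: float, rng: np.random.Generator) -> MCMCState:
    """Draw the starting partition from the generic ensemble q^rho."""
    edges = g.edge_array()
    n_remove = n_edges_to_remove(len(edges), rho)
    if n_remove == 0 or n_remove == len(edges):
        raise ValueError(
            f"degenerate rho={rho}: {n_remove} of {len(edges)} edges removed leaves "
            "no swap partner on one side"
        )
    # same draw as removal.random_removal, so a 0-step run reproduces it
    kept_idx = rng.choice(len(edges), size=len(edges) - n_remove, replace=False)
    removed_idx = np.setdiff1d(np.arange(len(edges)), kept_idx)
    u, v = edges[kept_idx, 0], edges[kept_idx, 1]
    energy, vec = _lambda_max_from_arrays(u.copy(), v.copy(), g.n_nodes, tol=ENERGY_TOL)
    return MCMCState(graph=g, kept_idx=kept_idx, removed_idx=removed_idx, energy=energy, eigvec=vec)


def propose_swap(state: MCMCState, rng) -> MCMCState:
    """Exchange one uniformly chosen kept edge with one removed edge.

    Returns a new state with the proposal's energy evaluated; the input
    state is untouched.  The proposal is symmetric by construction.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if len(state.kept_idx) == 0 or len(state.removed_idx) == 0:
        raise ValueError("cannot propose a swap: kept or removed edge set is empty")
    i = int(rng.integers(len(state.kept_idx)))
    j = int(rng.integers(len(state.removed_idx)))
    kept = state.kept_idx.copy()
    removed = state.removed_idx.copy()
    kept[i], removed[j] = removed[j], kept[i]
    edges = state.graph.edge_array()
    u, v = edges[kept, 0], edges[kept, 1]
    energy, vec = _lambda_max_from_arrays(
        u.copy(), v.copy(), state.graph.n_nodes, tol=ENERGY_TOL, v0=state.eigvec
    )
    return MCMCState(
        graph=state.graph,
        kept_idx=kept,
        removed_idx=removed,
        energy=energy,
        step=state.step + 1,
        eigvec=vec,
    )


def mcmc_run(g: Graph, rho: float, nu: float, steps: int, seed: int) -> MCMCTrace:
    """Run the Metropolis sampler for a fixed number of steps.

    The initial partition is a uniform random removal at rate rho drawn
    from the same seeded stream; each step proposes a kept/removed edge
    swap and applies the Metropolis rule with lambda_max as energy.  The
    trace records the post-decision energy at every step.
    """
    if nu < 0:
        raise ValueError(f"nu must be >= 0, got {nu}")
    if steps < 0:
        raise ValueError(f"steps must be >= 0, got {steps}")
    rng = np.random.default_rng(seed)
    state = _initial_state(g, rho, rng)
    initial_energy = state.energy
    edges = g.edge_array()
    n = g.n_nodes
    kept = state.kept_idx.copy()
    removed = state.removed_idx.copy()
    energy, vec = state.energy, state.eigvec

    energies = np.empty(steps)
    accepted = np.zeros(steps, dtype=bool)
    for t in range(steps):
        i = int(rng.integers(len(kept)))
        j = int(rng.integers(len(removed)))
        kept[i], removed[j] = removed[j], kept[i]
        u, v = edges[kept, 0], edges[kept, 1]
        e_new, vec_new = _lambda_max_from_arrays(u.copy(), v.copy(), n, tol=ENERGY_TOL, v0=vec)
        if rng.random() < acceptance_probability(energy, e_new, nu):
            energy, vec = e_new, vec_new
            accepted[t] = True
        else:
            kept[i], removed[j] = removed[j], kept[i]
        energies[t] = energy

    final = g.subgraph_with_edges(map(tuple, edges[kept]))
    return MCMCTrace(
        energies=energies,
        accepted=accepted,
        initial_energy=initial_energy,
        final_graph=final,
        nu=nu,
        rho=rho,
        steps=steps,
        seed=seed,
    )


def spawn_seeds(master_seed: int, n: int, key: str = "") -> np.ndarray:
    """Deterministic sub-seeds (< 2**31) from a master seed and a label."""
    entropy = [master_seed] + [ord(c) for c in key]
    ss = np.random.SeedSequence(entropy)
    return np.random.default_rng(ss).integers(2**31, size=n)


def sample_ensemble(
    graph_factory,
    rho: float,
    nu: float,
    steps: int,
    n_configs: int,
    seed: int,
    keep_graphs: bool = True,
) -> EnsembleSummary:
    """Independent sampler runs on independently generated starting graphs.

    ``graph_factory(seed) -> Graph`` supplies the starting networks (one
    fresh graph per configuration).  The summary collects the FINAL energy
    of each run — the steady-state estimate used throughout.
    """
    if n_configs < 1:
        raise ValueError("n_configs must be >= 1")
    graph_seeds = spawn_seeds(seed, n_configs, "graphs")
    run_seeds = spawn_seeds(seed, n_configs, "runs")
    finals = np.empty(n_configs)
    graphs = [] if keep_graphs else None
    for k in range(n_configs):
        g = graph_factory(int(graph_seeds[k]))
        trace = mcmc_run(g, rho=rho, nu=nu, steps=steps, seed=int(run_seeds[k]))
        finals[k] = trace.final_energy
        if keep_graphs:
            graphs.append(trace.final_graph)
    return EnsembleSummary(
        final_energies=finals, nu=nu, rho=rho, steps=steps, seed=seed, final_graphs=graphs
    )


def exact_stationary_distribution(g: Graph, rho: float, nu: float, max_states: int = 100_000):
    """Boltzmann distribution over all fixed-size kept-edge subsets.

    Enumerates every subgraph with (1 - rho) E edges, weights it by
    exp(-nu * lambda_max) and normalises by the explicitly computed Z.
    Test oracle for the sampler; refuses state spaces larger than
    ``max_states``.

    Returns a dict mapping frozenset-of-kept-edges -> probability.
    """
    edges = sorted(g.edges)
    n_remove = n_edges_to_remove(len(edges), rho)
    n_keep = len(edges) - n_remove
    n_states = math.comb(len(edges), n_keep)
    if n_states > max_states:
        raise ValueError(f"state space too large: C({len(edges)}, {n_keep}) = {n_states}")
    subsets = []
    energies = []
    from .graphs import largest_eigenvalue

    for kept in itertools.combinations(edges, n_keep):
        subsets.append(frozenset(kept))
        energies.append(largest_eigenvalue(g.subgraph_with_edges(kept)))
    energies = np.asarray(energies)
    # shift by the minimum so weights never underflow to all-zero
    w = np.exp(-nu * (energies - energies.min()))
    p = w / w.sum()
    return dict(zip(subsets, p.tolist()))
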