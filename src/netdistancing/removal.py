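"""Link-removal (social-distancing) strategies.

All strategies delete ``round(rho * E)`` edges from the original graph —
rho is the contact reduction rate — and leave the node set untouched, so
ensembles produced by different strategies are comparable at equal link
density.  ``degree_cap_removal`` is the exception: it is parameterised by
the cap k_max rather than rho (``degree_cap_for_rate`` matches a cap to a
target rate).

Degree-homogenizing strategies (degree product, degree cap) emulate
contact-limiting policies; they narrow the degree distribution, which is
what drives the reduction of the spectral radius.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np

from .graphs import Graph

__all__ = [
    "n_edges_to_remove",
    "random_removal",
    "degree_product_removal",
    "degree_cap_removal",
    "degree_cap_for_rate",
    "edge_betweenness_removal",
]


def n_edges_to_remove(n_edges: int, rho: float) -> int:
    """round-half-up of rho * E, applied once to the original edge count."""
    if not 0 < rho < 1:
        raise ValueError(f"rho must be in (0, 1), got {rho}")
    return int(math.floor(rho * n_edges + 0.5))


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def random_removal(g: Graph, rho: float, seed) -> Graph:
    """Retain a uniformly random subset of round((1-rho)*E) edges.

    Samples the generic ensemble: the uniform distribution over subgraphs
    of g with the given edge count.
    """
    rng = _as_rng(seed)
    edges = g.edge_array()
    n_remove = n_edges_to_remove(len(edges), rho)
    keep_idx = rng.choice(len(edges), size=len(edges) - n_remove, replace=False)
    return g.subgraph_with_edges(map(tuple, edges[keep_idx]))


def degree_product_removal(g: Graph, rho: float, seed) -> Graph:
    """Iteratively delete an edge maximising deg(u)*deg(v), ties at random.

    Degrees are recomputed after every single deletion, so the strategy
    keeps chipping at whichever hub pair currently dominates.
    """
    rng = _as_rng(seed)
    edges = g.edge_array()
    n_remove = n_edges_to_remove(len(edges), rho)
    deg = g.degrees().astype(np.int64)
    alive = np.ones(len(edges), dtype=bool)
    u, v = edges[:, 0], edges[:, 1]
    for _ in range(n_remove):
        prod = np.where(alive, deg[u] * deg[v], -1)
        best = np.flatnonzero(prod == prod.max())
        pick = best[rng.integers(len(best))]
        alive[pick] = False
        deg[u[pick]] -= 1
        deg[v[pick]] -= 1
    return g.subgraph_with_edges(map(tuple, edges[alive]))


def degree_cap_removal(g: Graph, k_max: int, seed, order=None) -> Graph:
    """Cap every node's degree at k_max.

    Nodes are processed in ``order`` (default: ascending node id); a node
    whose CURRENT degree exceeds k_max has a uniformly random selection of
    all but k_max of its links removed.  Earlier removals count: a node's
    degree may already have dropped by the time it is processed.
    """
    if k_max < 0:
        raise ValueError(f"k_max must be >= 0, got {k_max}")
    rng = _as_rng(seed)
    order = range(g.n_nodes) if order is None else order
    adj = {i: set() for i in range(g.n_nodes)}
    for a, b in g.edges:
        adj[a].add(b)
        adj[b].add(a)
    removed = set()
    for node in order:
        excess = len(adj[node]) - k_max
        if excess <= 0:
            continue
        neighbours = sorted(adj[node])
        drop = rng.choice(len(neighbours), size=excess, replace=False)
        for i in drop:
            other = neighbours[i]
            adj[node].discard(other)
            adj[other].discard(node)
            removed.add((node, other) if node < other else (other, node))
    return g.subgraph_with_edges(g.edges - removed)


def degree_cap_for_rate(g: Graph, rho: float, seed) -> Graph:
    """Degree-cap removal matched to an exact removal rate.

    Finds the smallest k_max whose cap removal (under this seed) deletes at
    most round(rho*E) edges, applies it, then deletes additional uniformly
    random edges to hit the target count exactly.
    """
    rng = _as_rng(seed)
    edges = g.edge_array()
    target = n_edges_to_remove(len(edges), rho)
    max_deg = int(g.degrees().max(initial=0))
    capped = g
    # Deleting fewer edges as k_max grows: scan caps upward, keep the first
    # (most aggressive) one that stays within budget.  Each candidate uses a
    # seed spawned deterministically from the master rng.
    cap_seeds = rng.integers(2**31, size=max_deg + 1)
    for k in range(max_deg + 1):
        trial = degree_cap_removal(g, k, np.random.default_rng(cap_seeds[k]))
        if g.n_edges - trial.n_edges <= target:
            capped = trial
            break
    shortfall = target - (g.n_edges - capped.n_edges)
    if shortfall > 0:
        kept = np.array(sorted(capped.edges), dtype=np.int64)
        keep_idx = rng.choice(len(kept), size=len(kept) - shortfall, replace=False)
        return g.subgraph_with_edges(map(tuple, kept[keep_idx]))
    return capped


def edge_betweenness_removal(g: Graph, rho: float, seed=0) -> Graph:
    """Iteratively delete the edge with the highest betweenness centrality,
    recomputed after every deletion; ties broken uniformly at random.

    Included for comparison: concentrating removals on bridges fragments
    the network but performs worse than uniform removal at lowering the
    spectral radius.
    """
    rng = _as_rng(seed)
    n_remove = n_edges_to_remove(g.n_edges, rho)
    h = g.to_networkx()
    for _ in range(n_remove):
        bc = nx.edge_betweenness_centrality(h)
        best_val = max(bc.values())
        best = [e for e, c in bc.items() if c >= best_val - 1e-12]
        a, b = best[rng.integers(len(best))]
        h.remove_edge(a, b)
    return g.subgraph_with_edges((min(a, b), max(a, b)) for a, b in h.edges())
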