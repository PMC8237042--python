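"""Graph container, generators, edge-list I/O and spectral/structural metrics.

The central object is :class:`Graph`, an immutable undirected simple graph
over 0-based integer node ids.  Isolated nodes are first-class: the node
count is independent of the edge set, which matters when link removal
disconnects individuals from the contact network.

The key spectral quantity is the largest eigenvalue of the adjacency
matrix, lambda_max.  For discrete-time SIS dynamics the epidemic threshold
is tau = 1/lambda_max: for infection/recovery ratios beta/delta below tau
an outbreak dies out, above it the disease becomes endemic.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.optimize import brentq

__all__ = [
    "Graph",
    "DegreeHistogram",
    "ComponentSummary",
    "generate_ba",
    "generate_rg",
    "calibrate_rg_radius",
    "RG_RADIUS_MEAN_DEGREE_18",
    "largest_eigenvalue",
    "epidemic_threshold",
    "degree_histogram",
    "component_summary",
    "read_edge_list",
    "write_edge_list",
]

# Dense eigendecomposition below this size; Lanczos above.
_DENSE_EIG_CUTOFF = 64


class EdgeListFormatError(ValueError):
    """Malformed edge-list file (self-loop, duplicate edge, bad token)."""


@dataclass(frozen=True)
class Graph:
    """Undirected simple graph: ``n_nodes`` and a set of edges ``(u, v)``, u < v.

    Parameters
    ----------
    n_nodes:
        Number of nodes; ids are ``0 .. n_nodes-1``.  May exceed the largest
        endpoint so that isolated nodes are representable.
    edges:
        Frozenset of canonical (min, max) pairs.  No self-loops.
    """

    n_nodes: int
    edges: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.n_nodes <= 0:
            raise ValueError(f"n_nodes must be positive, got {self.n_nodes}")
        edges = frozenset((int(u), int(v)) if u < v else (int(v), int(u)) for u, v in self.edges)
        for u, v in edges:
            if u == v:
                raise ValueError(f"self-loop at node {u}")
            if not (0 <= u < self.n_nodes and 0 <= v < self.n_nodes):
                raise ValueError(f"edge ({u}, {v}) out of range for n_nodes={self.n_nodes}")
        object.__setattr__(self, "edges", edges)

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_edges(cls, n_nodes: int, edges) -> "Graph":
        return cls(n_nodes=n_nodes, edges=frozenset(tuple(e) for e in edges))

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Graph":
        nodes = sorted(g.nodes())
        if nodes != list(range(len(nodes))):
            relabel = {u: i for i, u in enumerate(nodes)}
            g = nx.relabel_nodes(g, relabel)
        return cls(n_nodes=g.number_of_nodes(), edges=frozenset(g.edges()))

    # -- views -------------------------------------------------------------

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_array(self) -> np.ndarray:
        """Edges as a sorted (E, 2) int array; shape (0, 2) when empty."""
        if not self.edges:
            return np.empty((0, 2), dtype=np.int64)
        return np.array(sorted(self.edges), dtype=np.int64)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        e = self.edge_array()
        if len(e):
            np.add.at(deg, e[:, 0], 1)
            np.add.at(deg, e[:, 1], 1)
        return deg

    def adjacency(self, dense: bool = False):
        """Symmetric 0/1 adjacency matrix (CSR by default)."""
        e = self.edge_array()
        data = np.ones(2 * len(e))
        rows = np.concatenate([e[:, 0], e[:, 1]])
        cols = np.concatenate([e[:, 1], e[:, 0]])
        a = sp.csr_array((data, (rows, cols)), shape=(self.n_nodes, self.n_nodes))
        return a.toarray() if dense else a

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g

    def subgraph_with_edges(self, edges) -> "Graph":
        """Same node set, restricted edge set (must be a subset)."""
        edges = frozenset(tuple(e) for e in edges)
        if not edges <= self.edges:
            raise ValueError("edges are not a subset of this graph's edges")
        return Graph(n_nodes=self.n_nodes, edges=edges)


@dataclass(frozen=True)
class DegreeHistogram:
    """Mapping degree -> node count; counts sum to n_nodes."""

    counts: dict
    n_nodes: int

    def mean_degree(self) -> float:
        return sum(k * c for k, c in self.counts.items()) / self.n_nodes

    def variance(self) -> float:
        mu = self.mean_degree()
        return sum(c * (k - mu) ** 2 for k, c in self.counts.items()) / self.n_nodes

    def to_rows(self):
        return [(k, self.counts[k]) for k in sorted(self.counts)]


@dataclass(frozen=True)
class ComponentSummary:
    """Connected-component census: count plus sizes sorted descending."""

    n_components: int
    component_sizes: tuple

    @property
    def giant_size(self) -> int:
        return self.component_sizes[0]

    def to_rows(self):
        return [(i + 1, s) for i, s in enumerate(self.component_sizes)]


# ---------------------------------------------------------------------------
# generators


def generate_ba(n: int, m: int, seed: int) -> Graph:
    """Barabási–Albert preferential-attachment graph.

    Growth from an m-node seed; each new node attaches to m existing nodes,
    so the edge count is (n - m) * m.  With n=100, m=10 this gives 900 edges
    and mean degree 18, a dense online-social-network-like topology.
    """
    if not 1 <= m < n:
        raise ValueError(f"need 1 <= m < n, got m={m}, n={n}")
    return Graph.from_networkx(nx.barabasi_albert_graph(n, m, seed=seed))


def generate_rg(n: int, radius: float, seed: int) -> Graph:
    """Random geometric graph: n uniform points in the unit square,
    edge iff Euclidean distance <= radius (hard, non-periodic boundary).

    Spatially embedded, high-clustering topology typical of in-person
    contact networks.  The edge count fluctuates between seeds.
    """
    if not 0 < radius:
        raise ValueError(f"radius must be positive, got {radius}")
    radius = min(radius, math.sqrt(2.0))
    rng = np.random.default_rng(seed)
    pos = rng.random((n, 2))
    d2 = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=-1)
    iu, ju = np.triu_indices(n, k=1)
    hit = d2[iu, ju] <= radius * radius
    return Graph.from_edges(n, zip(iu[hit].tolist(), ju[hit].tolist()))


def _expected_rg_degree(radius: float, n: int) -> float:
    # P(|X - Y| <= r) for X, Y uniform in the unit square, r <= 1:
    # pi r^2 - 8/3 r^3 + 1/2 r^4  (boundary-corrected disc area).
    r = radius
    return (n - 1) * (math.pi * r * r - (8.0 / 3.0) * r**3 + 0.5 * r**4)


def calibrate_rg_radius(n: int, target_mean_degree: float) -> float:
    """Connection radius giving the requested expected mean degree for n
    uniform points in the unit square, accounting for the hard boundary."""
    if not 0 < target_mean_degree < n - 1:
        raise ValueError("target mean degree must be in (0, n-1)")
    return brentq(lambda r: _expected_rg_degree(r, n) - target_mean_degree, 1e-9, 1.0)


#: Radius for mean degree ~18 at n=100 in the unit square (boundary-corrected).
RG_RADIUS_MEAN_DEGREE_18 = 0.27228


# ---------------------------------------------------------------------------
# spectral metrics


def _lambda_max_from_arrays(
    u: np.ndarray,
    v: np.ndarray,
    n: int,
    tol: float = 1e-8,
    v0=None,
    dense_cutoff: int = _DENSE_EIG_CUTOFF,
):
    """Largest adjacency eigenvalue from endpoint arrays.

    Returns (lambda_max, eigenvector-or-None).  Dense solve below the size
    cutoff; warm-startable Lanczos (matrix-free bincount matvec) above.
    The eigenvector is returned so that MCMC sweeps can warm-start the next
    evaluation, which makes the 11,000-step runs tractable.
    """
    if len(u) == 0:
        return 0.0, None
    if n <= dense_cutoff:
        a = np.zeros((n, n))
        a[u, v] = 1.0
        a[v, u] = 1.0
        w, vecs = np.linalg.eigh(a)
        return float(w[-1]), vecs[:, -1]

    def matvec(x):
        x = np.asarray(x).ravel()
        return np.bincount(u, weights=x[v], minlength=n) + np.bincount(v, weights=x[u], minlength=n)

    op = spla.LinearOperator((n, n), matvec=matvec, dtype=float)
    try:
        w, vecs = spla.eigsh(op, k=1, which="LA", tol=tol, v0=v0)
    except spla.ArpackNoConvergence:
        a = np.zeros((n, n))
        a[u, v] = 1.0
        a[v, u] = 1.0
        w, vecs = np.linalg.eigh(a)
        return float(w[-1]), vecs[:, -1]
    return float(w[0]), vecs[:, 0]


def largest_eigenvalue(g: Graph, tol: float = 1e-8, method: str = "auto") -> float:
    """Largest eigenvalue of the 0/1 adjacency matrix (0 for no edges).

    ``method`` selects the solver: "auto" (dense up to the size cutoff,
    Lanczos above), "dense", or "iterative".
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    cutoff = {"auto": _DENSE_EIG_CUTOFF, "dense": 10**9, "iterative": 0}[method]
    e = g.edge_array()
    lam, _ = _lambda_max_from_arrays(e[:, 0], e[:, 1], g.n_nodes, tol=tol, dense_cutoff=cutoff)
    return lam


def epidemic_threshold(g: Graph) -> float:
    """SIS epidemic threshold tau = 1/lambda_max; inf for an edgeless graph."""
    lam = largest_eigenvalue(g)
    return math.inf if lam == 0.0 else 1.0 / lam


def degree_histogram(g: Graph) -> DegreeHistogram:
    counts = Counter(g.degrees().tolist())
    return DegreeHistogram(counts=dict(counts), n_nodes=g.n_nodes)


def component_summary(g: Graph) -> ComponentSummary:
    sizes = sorted((len(c) for c in nx.connected_components(g.to_networkx())), reverse=True)
    return ComponentSummary(n_components=len(sizes), component_sizes=tuple(sizes))


# ---------------------------------------------------------------------------
# edge-list I/O


def read_edge_list(path) -> Graph:
    """Read a two-column whitespace-separated edge list.

    ``#`` lines are comments; a ``# n_nodes=<int>`` header fixes the node
    count (otherwise max id + 1).  Self-loops and duplicate edges are
    rejected with the offending line number.
    """
    edges = set()
    n_nodes = None
    max_id = -1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                stripped = line.lstrip("#").strip().replace(" ", "")
                if stripped.startswith("n_nodes="):
                    n_nodes = int(stripped.split("=", 1)[1])
                continue
            parts = line.split()
            if len(parts) != 2:
                raise EdgeListFormatError(f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise EdgeListFormatError(f"{path}:{lineno}: non-integer node id in {line!r}") from exc
            if u == v:
                raise EdgeListFormatError(f"{path}:{lineno}: self-loop at node {u}")
            e = (u, v) if u < v else (v, u)
            if e in edges:
                raise EdgeListFormatError(f"{path}:{lineno}: duplicate edge {e}")
            if u < 0 or v < 0:
                raise EdgeListFormatError(f"{path}:{lineno}: negative node id")
            edges.add(e)
            max_id = max(max_id, u, v)
    if n_nodes is None:
        n_nodes = max_id + 1 if max_id >= 0 else 1
    return Graph.from_edges(n_nodes, edges)


def write_edge_list(g: Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n_nodes={g.n_nodes}\n")
        for u, v in sorted(g.edges):
            fh.write(f"{u}\t{v}\n")
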