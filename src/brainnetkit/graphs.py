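"""Binary graph construction and graph-theory metrics.

Weighted connectivity matrices are binarized by retaining a fixed fraction
(the *sparsity*) of the strongest edges.  All topological metrics operate on
the resulting undirected binary graph: clustering coefficient (Cp),
characteristic path length (Lp), global/local/nodal efficiency, node degree,
node betweenness, and the small-world indices Gamma/Lambda/Sigma computed
against degree-preserving random nulls.  Curves over a sparsity grid are
summarised threshold-free by their trapezoidal area under the curve (AUC).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "BinaryGraph",
    "GlobalMetrics",
    "NodalMetrics",
    "threshold_by_sparsity",
    "clustering_coefficient",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "nodal_efficiency",
    "degree",
    "betweenness",
    "rewire_preserving_degree",
    "small_world_indices",
    "auc_over_sparsity",
    "default_sparsity_grid",
]

GLOBAL_METRIC_NAMES = ("Cp", "Lp", "Gamma", "Lambda", "Sigma", "Eglobal", "Elocal")
NODAL_METRIC_NAMES = ("degree", "betweenness", "efficiency")


def default_sparsity_grid(lo: float = 0.05, hi: float = 0.40, step: float = 0.01) -> np.ndarray:
    """Sparsity grid 0.05..0.40 in steps of 0.01 (36 points) by default."""
    n = int(round((hi - lo) / step)) + 1
    return np.round(lo + step * np.arange(n), 10)


@dataclass
class BinaryGraph:
    """Undirected, unweighted graph stored as a dense 0/1 adjacency matrix."""

    adjacency: np.ndarray
    sparsity: float = float("nan")

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("self-loops are not allowed")
        self.adjacency = a.astype(np.uint8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edge_set(self) -> set[tuple[int, int]]:
        i, j = np.nonzero(np.triu(self.adjacency))
        return set(zip(i.tolist(), j.tolist()))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edge_set())
        return g


@dataclass
class GlobalMetrics:
    """Per-sparsity global metric curves plus their AUC summaries."""

    grid: np.ndarray
    curves: dict[str, np.ndarray]
    auc: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.auc:
            self.auc = {k: auc_over_sparsity(v, self.grid) for k, v in self.curves.items()}


@dataclass
class NodalMetrics:
    """Per-node, per-sparsity metric curves plus per-node AUC summaries."""

    grid: np.ndarray
    curves: dict[str, np.ndarray]  # metric -> (n_sparsity, n_nodes)
    auc: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.auc:
            self.auc = {
                k: np.array([auc_over_sparsity(v[:, i], self.grid) for i in range(v.shape[1])])
                for k, v in self.curves.items()
            }


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def threshold_by_sparsity(weights: np.ndarray, sparsity: float) -> BinaryGraph:
    """Binarize a symmetric weight matrix at a target edge density.

    Keeps the ``round(sparsity * n(n-1)/2)`` largest off-diagonal weights
    (signed, not absolute, by default in callers); ties at the cutoff are
    broken in favour of the lower (row, col) index pair so the edge count is
    exact and the result deterministic.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weights must be a square matrix")
    if not np.allclose(w, w.T, equal_nan=True):
        raise ValueError("weights must be symmetric")
    if not (0.0 < sparsity <= 1.0):
        raise ValueError(f"sparsity must lie in (0, 1], got {sparsity}")
    n = w.shape[0]
    n_pairs = n * (n - 1) // 2
    n_edges = _round_half_away(sparsity * n_pairs)
    iu, ju = np.triu_indices(n, k=1)
    vals = w[iu, ju]
    # lexsort: primary key last — sort by descending weight, then (i, j)
    order = np.lexsort((ju, iu, -vals))
    keep = order[:n_edges]
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[iu[keep], ju[keep]] = 1
    adj |= adj.T
    return BinaryGraph(adj, sparsity=float(sparsity))


def degree(g: BinaryGraph) -> np.ndarray:
    return g.adjacency.sum(axis=1).astype(int)


def clustering_coefficient(g: BinaryGraph) -> tuple[np.ndarray, float]:
    """Per-node clustering (2*triangles / k(k-1), 0 for k<2) and its mean Cp."""
    a = g.adjacency.astype(float)
    k = a.sum(axis=1)
    tri2 = np.einsum("ij,jk,ki->i", a, a, a)  # = 2 * triangles per node
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri2 / denom, 0.0)
    return c, float(c.mean())


def _distance_matrix(adj: np.ndarray) -> np.ndarray:
    """All-pairs unweighted shortest-path distances.

    Dense breadth-first expansion by boolean matrix products; for the graph
    sizes used here (<= a few hundred nodes) this beats sparse-graph
    routines, whose per-call setup dominates in permutation loops.
    """
    a = adj.astype(float)
    n = a.shape[0]
    d = np.where(a > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    known = (a > 0) | np.eye(n, dtype=bool)
    frontier = a > 0
    dist = 1
    while frontier.any():
        nxt = ((frontier.astype(float) @ a) > 0) & ~known
        if not nxt.any():
            break
        dist += 1
        d[nxt] = dist
        known |= nxt
        frontier = nxt
    return d


def characteristic_path_length(g: BinaryGraph) -> float:
    """Mean shortest-path length over reachable node pairs.

    Unreachable pairs are excluded from the mean rather than contributing an
    infinite distance; a graph with no edges has no defined path length.
    """
    if g.n_edges == 0:
        raise ValueError("characteristic path length undefined for an empty graph")
    d = _distance_matrix(g.adjacency)
    mask = np.isfinite(d) & ~np.eye(g.n_nodes, dtype=bool)
    return float(d[mask].mean())


def global_efficiency(g: BinaryGraph) -> float:
    d = _distance_matrix(g.adjacency)
    n = g.n_nodes
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def nodal_efficiency(g: BinaryGraph) -> np.ndarray:
    """Per-node mean inverse distance to every other node."""
    d = _distance_matrix(g.adjacency)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (g.n_nodes - 1)


def local_efficiency(g: BinaryGraph) -> float:
    """Mean, over nodes, of the global efficiency of each neighbourhood subgraph."""
    a = g.adjacency
    vals = np.zeros(g.n_nodes)
    for i in range(g.n_nodes):
        nbr = np.nonzero(a[i])[0]
        if nbr.size < 2:
            continue
        sub = a[np.ix_(nbr, nbr)]
        d = _distance_matrix(sub)
        with np.errstate(divide="ignore"):
            inv = 1.0 / d
        inv[~np.isfinite(inv)] = 0.0
        np.fill_diagonal(inv, 0.0)
        m = nbr.size
        vals[i] = inv.sum() / (m * (m - 1))
    return float(vals.mean())


def betweenness(g: BinaryGraph) -> np.ndarray:
    """Unnormalized shortest-path betweenness (fractional counting)."""
    bc = nx.betweenness_centrality(g.to_networkx(), normalized=False)
    return np.array([bc[i] for i in range(g.n_nodes)])


def rewire_preserving_degree(
    g: BinaryGraph, n_swap_attempts: int, seed: int | np.random.Generator
) -> BinaryGraph:
    """Degree-preserving randomization by repeated double-edge swaps.

    Each attempt draws two edges (a,b), (c,d) and rewires them to (a,d),
    (c,b) unless that would create a self-loop or a duplicate edge.
    Connectivity is not enforced.
    """
    if n_swap_attempts < 1:
        raise ValueError("n_swap_attempts must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    edges = sorted(g.edge_set())
    if len(edges) < 2:
        return BinaryGraph(g.adjacency.copy(), sparsity=g.sparsity)
    edge_set = set(edges)
    m = len(edges)
    for _ in range(n_swap_attempts):
        e1, e2 = rng.integers(0, m, size=2)
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if rng.random() < 0.5:
            c, d = d, c
        if a == d or c == b:
            continue
        new1 = (min(a, d), max(a, d))
        new2 = (min(c, b), max(c, b))
        if new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard(edges[e1])
        edge_set.discard(edges[e2])
        edge_set.add(new1)
        edge_set.add(new2)
        edges[e1] = new1
        edges[e2] = new2
    adj = np.zeros_like(g.adjacency)
    for i, j in edge_set:
        adj[i, j] = adj[j, i] = 1
    return BinaryGraph(adj, sparsity=g.sparsity)


def small_world_indices(
    g: BinaryGraph,
    n_random: int = 100,
    seed: int | np.random.Generator = 0,
    swaps_per_edge: int = 10,
) -> tuple[float, float, float]:
    """Normalized clustering (Gamma), path length (Lambda) and their ratio Sigma.

    Both normalizers are means over ``n_random`` degree-preserving rewired
    null networks.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    _, cp = clustering_coefficient(g)
    lp = characteristic_path_length(g)
    cps, lps = [], []
    n_attempts = max(1, swaps_per_edge * g.n_edges)
    for _ in range(n_random):
        r = rewire_preserving_degree(g, n_attempts, rng)
        _, c = clustering_coefficient(r)
        cps.append(c)
        lps.append(characteristic_path_length(r))
    mean_cp, mean_lp = float(np.mean(cps)), float(np.mean(lps))
    if mean_cp == 0 or mean_lp == 0:
        raise ValueError("random-network normalizer is zero; Gamma/Lambda undefined")
    gamma = cp / mean_cp
    lam = lp / mean_lp
    return gamma, lam, gamma / lam


def auc_over_sparsity(values, grid) -> float:
    """Trapezoidal area under a metric curve over the sparsity grid."""
    values = np.asarray(values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if values.shape != grid.shape:
        raise ValueError("values and grid must have the same length")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    return float(np.trapezoid(values, grid))
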