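"""Binary graph construction and small-world metrics.

A weighted connectivity matrix is binarized with a proportional threshold
kappa (the fraction of strongest connections kept).  On the binary graph we
compute the mean clustering coefficient (CC), the characteristic path
length over mutually reachable pairs (cPL), and small-worldness

    SW = (CC / CC_rand) / (cPL / cPL_rand),

where the null quantities are ensemble means over degree-preserving
(Maslov–Sneppen double-edge-swap) randomizations of the same graph.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .connectivity import ConnectivityMatrix

logger = logging.getLogger(__name__)

DEFAULT_KAPPA = 0.2
DEFAULT_KAPPA_GRID = tuple(np.round(np.arange(0.10, 0.301, 0.02), 2))
DEFAULT_N_RAND = 1000
DEFAULT_SWAPS_PER_EDGE = 5


class UndefinedMetricError(ValueError):
    """Raised when a graph metric is undefined (e.g. edgeless graph)."""


@dataclass
class BinaryGraph:
    """Undirected simple graph as a symmetric 0/1 adjacency matrix."""

    adjacency: np.ndarray
    kappa: float | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("no self-loops allowed")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        self.adjacency = a.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def edge_list(self) -> np.ndarray:
        i, j = np.nonzero(np.triu(self.adjacency, 1))
        return np.column_stack([i, j])


@dataclass
class GraphMetricSet:
    """CC, cPL and null-normalized small-worldness at one threshold."""

    cc: float
    cpl: float
    cc_rand_mean: float
    cpl_rand_mean: float
    n_rand: int
    band: str | None = None
    kappa: float | None = None

    @property
    def cc_norm(self) -> float:
        return self.cc / self.cc_rand_mean

    @property
    def cpl_norm(self) -> float:
        return self.cpl / self.cpl_rand_mean

    @property
    def sw(self) -> float:
        return self.cc_norm / self.cpl_norm


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def proportional_threshold(matrix: ConnectivityMatrix | np.ndarray, kappa: float) -> BinaryGraph:
    """Keep the ``round(kappa * n(n-1)/2)`` strongest connections.

    Ties at the cutoff are broken deterministically by ascending
    (row, column) index.
    """
    if not 0 < kappa <= 1:
        raise ValueError("kappa must be in (0, 1]")
    w = matrix.values if isinstance(matrix, ConnectivityMatrix) else np.asarray(matrix, float)
    n = w.shape[0]
    n_pairs = n * (n - 1) // 2
    n_edges = _round_half_away(kappa * n_pairs)
    iu, ju = np.triu_indices(n, 1)
    weights = w[iu, ju]
    # stable sort on (-weight, row, col): lexsort's last key is primary
    order = np.lexsort((ju, iu, -weights))
    keep = order[:n_edges]
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu[keep], ju[keep]] = 1
    adj += adj.T
    return BinaryGraph(adj, kappa=kappa)


def clustering_coefficient(graph: BinaryGraph) -> float:
    """Mean over nodes of the local clustering coefficient.

    Local clustering is the number of edges among a node's neighbours
    divided by k(k-1)/2; nodes of degree < 2 contribute 0.
    """
    a = graph.adjacency.astype(float)
    k = a.sum(axis=1)
    triangles = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    denom = k * (k - 1) / 2.0
    local = np.zeros_like(k)
    mask = k >= 2
    local[mask] = triangles[mask] / denom[mask]
    return float(local.mean())


def characteristic_path_length(graph: BinaryGraph) -> float:
    """Mean shortest-path length over mutually reachable node pairs.

    Unreachable pairs are excluded from the average (the connected-nodes
    convention); an edgeless graph has no reachable pair and raises
    :class:`UndefinedMetricError`.
    """
    if graph.n_edges == 0:
        raise UndefinedMetricError("cPL undefined: graph has no edges")
    d = shortest_path(csr_matrix(graph.adjacency), method="D", unweighted=True)
    off = ~np.eye(graph.n_nodes, dtype=bool)
    finite = np.isfinite(d) & off
    return float(d[finite].mean())


def _swap_kernel(adj, edges, picks, flips, target):
    """Sequential double-edge-swap walk; returns the number of swaps done.

    Mutates ``adj`` (n x n int8) and ``edges`` (m x 2 int64) in place,
    consuming the pre-drawn candidate arrays in order.
    """
    swaps = 0
    for t in range(picks.shape[0]):
        if swaps >= target:
            break
        e1 = picks[t, 0]
        e2 = picks[t, 1]
        if e1 == e2:
            continue
        a = edges[e1, 0]
        b = edges[e1, 1]
        c = edges[e2, 0]
        d = edges[e2, 1]
        if flips[t] == 1:
            c, d = d, c
        if a == d or c == b:
            continue
        if adj[a, d] == 1 or adj[c, b] == 1:
            continue
        adj[a, b] = 0
        adj[b, a] = 0
        adj[c, d] = 0
        adj[d, c] = 0
        adj[a, d] = 1
        adj[d, a] = 1
        adj[c, b] = 1
        adj[b, c] = 1
        edges[e1, 0] = a
        edges[e1, 1] = d
        edges[e2, 0] = c
        edges[e2, 1] = b
        swaps += 1
    return swaps


try:  # compiled fast path; the pure-Python kernel is the reference semantics
    from numba import njit

    _swap_kernel_jit = njit(cache=True)(_swap_kernel)
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _swap_kernel_jit = _swap_kernel


def rewire_degree_preserving(
    graph: BinaryGraph,
    swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
    seed: int | np.random.Generator = 0,
    max_tries_per_edge: int = 20,
) -> BinaryGraph:
    """Maslov–Sneppen double-edge-swap randomization.

    Attempts ``swaps_per_edge * E`` successful swaps, rejecting any swap
    that would create a self-loop or duplicate edge, with a cap of
    ``max_tries_per_edge * E`` attempts.  The degree sequence and edge
    count are invariant.  Graphs with no legal swap (e.g. complete graphs)
    are returned unchanged with a warning.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    edges = graph.edge_list().astype(np.int64)
    m = len(edges)
    if m < 2:
        warnings.warn("graph has fewer than 2 edges; returning input unchanged")
        return BinaryGraph(graph.adjacency.copy(), kappa=graph.kappa)
    adj = graph.adjacency.copy()
    target = swaps_per_edge * m
    max_tries = max_tries_per_edge * m
    picks = rng.integers(0, m, size=(max_tries, 2))
    flips = rng.integers(0, 2, size=max_tries)
    swaps = _swap_kernel_jit(adj, edges, picks, flips, target)
    if swaps == 0:
        warnings.warn("no legal degree-preserving swap found; returning input unchanged")
    elif swaps < target:
        logger.debug("rewiring reached attempt cap: %d/%d swaps", swaps, target)
    return BinaryGraph(adj, kappa=graph.kappa)


def small_worldness(
    graph: BinaryGraph,
    n_rand: int = DEFAULT_N_RAND,
    swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
    seed: int | np.random.SeedSequence = 0,
    band: str | None = None,
) -> GraphMetricSet:
    """Small-worldness against an ensemble of rewired null graphs.

    ``cc_rand_mean`` and ``cpl_rand_mean`` are means over ``n_rand``
    independently rewired graphs; SW = (CC/CC_rand)/(cPL/cPL_rand).
    Deterministic for a fixed seed.
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    cc = clustering_coefficient(graph)
    cpl = characteristic_path_length(graph)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    cc_r = np.empty(n_rand)
    cpl_r = np.empty(n_rand)
    for r, child in enumerate(ss.spawn(n_rand)):
        null = rewire_degree_preserving(
            graph, swaps_per_edge=swaps_per_edge, seed=np.random.default_rng(child)
        )
        cc_r[r] = clustering_coefficient(null)
        cpl_r[r] = characteristic_path_length(null)
    return GraphMetricSet(
        cc=cc,
        cpl=cpl,
        cc_rand_mean=float(cc_r.mean()),
        cpl_rand_mean=float(cpl_r.mean()),
        n_rand=n_rand,
        band=band,
        kappa=graph.kappa,
    )


def metrics_over_thresholds(
    matrix: ConnectivityMatrix,
    kappas: tuple[float, ...] = DEFAULT_KAPPA_GRID,
    n_rand: int = DEFAULT_N_RAND,
    swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
    seed: int | np.random.SeedSequence = 0,
) -> list[GraphMetricSet]:
    """One :class:`GraphMetricSet` per proportional threshold."""
    if list(kappas) != sorted(kappas):
        raise ValueError("kappas must be sorted ascending")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    out = []
    for kappa, child in zip(kappas, ss.spawn(len(kappas))):
        g = proportional_threshold(matrix, kappa)
        out.append(
            small_worldness(
                g,
                n_rand=n_rand,
                swaps_per_edge=swaps_per_edge,
                seed=child,
                band=matrix.band,
            )
        )
    return out
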