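"""Binary graph construction and topology metrics for sensor networks.

Connectivity matrices are binarized at the median of all scenario data
within each test condition (per subject by default), forcing ~50% edge
density so that topology, not overall coupling strength, is compared
across conditions.  On the binary graph we compute:

* characteristic path length  L = mean over ordered pairs of the
  shortest hop distance (finite pairs only; unreachable pairs are
  counted and excluded),
* global efficiency  E_global = mean over ordered pairs of 1/distance
  (unreachable pairs contribute 0),
* local efficiency   E_local(i) = E_global of the subgraph induced by
  the neighbors of node i (nodes of degree < 2 score 0),
* clustering coefficient  C = mean over nodes of 2 E_i / (k_i (k_i - 1)),
  with E_i the number of edges among node i's neighbors,
* small-worldness  sigma = gamma / lambda, where gamma = C / C_random
  and lambda = L / L_random are normalized against the means of an
  ensemble of degree-preserving surrogate random networks (default 100);
  sigma > 1 is the small-world criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .connectivity import ConnectivityMatrix

logger = logging.getLogger(__name__)

DEFAULT_N_SURROGATES = 100


@dataclass
class BinaryGraph:
    """Undirected, unweighted graph from a thresholded wPLI matrix."""

    adjacency: np.ndarray
    threshold: float | None = None
    condition: tuple[str, str, str] | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=bool)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric (undirected graph)")
        if a.diagonal().any():
            raise ValueError("self-loops not allowed")
        self.adjacency = a

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def density(self) -> float:
        n = self.n_nodes
        return self.n_edges / (n * (n - 1) / 2)

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)


@dataclass
class GraphMetrics:
    """All topology metrics of one binary graph, plus surrogate normalizers."""

    L: float
    E_global: float
    E_local_per_node: np.ndarray
    E_local_mean: float
    C: float
    gamma: float | None = None
    lam: float | None = None
    sigma: float | None = None
    n_surrogates: int = 0
    unreachable_pairs: int = 0


def median_threshold(
    matrices: Iterable[ConnectivityMatrix],
    scope: str = "subject-test",
) -> dict[tuple, float]:
    """Median binarization threshold per group of connectivity matrices.

    ``scope='subject-test'`` (default) pools the upper-triangle values of
    all scenarios within each (subject, test) pair — the comparison made
    across scenarios of one test session then happens at matched density.
    ``scope='global'`` pools everything into a single threshold.
    Edges are entries *strictly greater* than the threshold.
    """
    matrices = list(matrices)
    if not matrices:
        raise ValueError("no matrices to threshold")
    labels = matrices[0].channel_labels
    for m in matrices:
        if m.channel_labels != labels:
            raise ValueError("all matrices must share channel labels")
    groups: dict[tuple, list[np.ndarray]] = {}
    for m in matrices:
        if scope == "subject-test":
            if m.condition is None:
                raise ValueError("matrices need condition labels for subject-test scope")
            key = (m.condition[0], m.condition[1])
        elif scope == "global":
            key = ("all",)
        else:
            raise ValueError(f"unknown scope {scope!r}")
        groups.setdefault(key, []).append(m.upper_triangle())
    return {k: float(np.median(np.concatenate(v))) for k, v in groups.items()}


def binarize(matrix: ConnectivityMatrix, threshold: float) -> BinaryGraph:
    """Edges where wPLI is strictly above the threshold (ties are non-edges)."""
    return BinaryGraph(
        adjacency=matrix.values > threshold,
        threshold=threshold,
        condition=matrix.condition,
    )


def shortest_path_lengths(g: BinaryGraph) -> np.ndarray:
    """Pairwise hop distances (BFS); unreachable pairs are ``inf``."""
    return _csgraph_shortest_path(
        g.adjacency.astype(np.int8), method="D", unweighted=True, directed=False
    )


def char_path_length(g: BinaryGraph, dist: np.ndarray | None = None) -> tuple[float, int]:
    """Characteristic path length and the count of unreachable ordered pairs.

    Mean hop distance over ordered node pairs; pairs with no connecting
    path are excluded from the average and returned as a count (infinite
    distances would otherwise make the ensuing lambda normalization
    meaningless).
    """
    if g.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if dist is None:
        dist = shortest_path_lengths(g)
    off = ~np.eye(g.n_nodes, dtype=bool)
    d = dist[off]
    finite = np.isfinite(d)
    n_unreachable = int((~finite).sum())
    if not finite.any():
        raise ValueError("graph has no connected pairs; L undefined")
    if n_unreachable:
        logger.warning(
            "char_path_length: %d unreachable ordered pairs excluded", n_unreachable
        )
    return float(d[finite].mean()), n_unreachable


def global_efficiency(g: BinaryGraph, dist: np.ndarray | None = None) -> float:
    """Mean inverse hop distance over ordered pairs (unreachable -> 0)."""
    if g.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if dist is None:
        dist = shortest_path_lengths(g)
    off = ~np.eye(g.n_nodes, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist[off]
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.mean())


def local_efficiency(g: BinaryGraph) -> tuple[np.ndarray, float]:
    """Per-node local efficiency and its mean.

    For node i, the global efficiency of the subgraph induced by its
    neighbors (node i itself excluded).  Degree < 2 nodes score 0.
    """
    a = g.adjacency
    n = g.n_nodes
    per_node = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        if nbrs.size < 2:
            continue
        sub = BinaryGraph(adjacency=a[np.ix_(nbrs, nbrs)])
        per_node[i] = global_efficiency(sub)
    return per_node, float(per_node.mean())


def clustering_coefficient(g: BinaryGraph) -> float:
    """Average node transitivity 2 E_i / (k_i (k_i - 1)); degree<2 -> 0."""
    a = g.adjacency
    n = g.n_nodes
    if n < 2:
        raise ValueError("need at least 2 nodes")
    vals = np.zeros(n)
    deg = g.degrees
    for i in range(n):
        k = deg[i]
        if k < 2:
            continue
        nbrs = np.flatnonzero(a[i])
        e_i = a[np.ix_(nbrs, nbrs)].sum() // 2  # edges among neighbors
        vals[i] = 2.0 * e_i / (k * (k - 1))
    return float(vals.mean())


def _edge_swap_surrogate(
    adj: np.ndarray, rng: np.random.Generator, n_attempts: int
) -> tuple[np.ndarray, int]:
    # Maslov–Sneppen rewiring: repeatedly pick two edges (a,b), (c,d) and
    # swap to (a,d), (c,b) when this creates no self-loop or multi-edge.
    a = adj.copy()
    edges = np.array(np.triu(a, 1).nonzero()).T
    m = len(edges)
    done = 0
    for _ in range(n_attempts):
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        x, y = edges[i]
        u, v = edges[j]
        if rng.random() < 0.5:
            u, v = v, u
        if len({x, y, u, v}) < 4:
            continue
        if a[x, v] or a[u, y]:
            continue
        a[x, y] = a[y, x] = False
        a[u, v] = a[v, u] = False
        a[x, v] = a[v, x] = True
        a[u, y] = a[y, u] = True
        edges[i] = (x, v)
        edges[j] = (u, y)
        done += 1
    return a, done


def surrogate_ensemble(
    g: BinaryGraph,
    n: int = DEFAULT_N_SURROGATES,
    seed: int | np.random.SeedSequence | None = None,
    swaps_per_edge: int = 10,
) -> tuple[float, float]:
    """Mean clustering and path length of degree-preserving random surrogates.

    Each surrogate applies ``swaps_per_edge * n_edges`` attempted
    degree-preserving edge swaps.  For graphs that cannot be rewired at
    all (e.g. a star, where every edge shares the hub), the ensemble
    falls back to density-matched Erdos–Renyi G(n, m) graphs with a
    warning.  Disconnected surrogates use the same finite-pairs-only
    convention for L as the observed graph.

    Returns
    -------
    (C_random, L_random)
        Ensemble means of the clustering coefficient and characteristic
        path length.
    """
    if g.n_edges < 1:
        raise ValueError("graph needs at least one edge for surrogates")
    rng = np.random.default_rng(seed)
    n_attempts = swaps_per_edge * g.n_edges
    c_vals = np.empty(n)
    l_vals = np.empty(n)
    fallback = False
    for k in range(n):
        adj, done = _edge_swap_surrogate(g.adjacency, rng, n_attempts)
        if k == 0 and done == 0:
            fallback = True
            logger.warning(
                "surrogate_ensemble: degree-preserving rewiring impossible; "
                "falling back to density-matched random graphs"
            )
        if fallback:
            adj = _gnm_adjacency(g.n_nodes, g.n_edges, rng)
        sg = BinaryGraph(adjacency=adj)
        c_vals[k] = clustering_coefficient(sg)
        l_vals[k], _ = char_path_length(sg)
    return float(c_vals.mean()), float(l_vals.mean())


def _gnm_adjacency(n_nodes: int, n_edges: int, rng: np.random.Generator) -> np.ndarray:
    iu = np.triu_indices(n_nodes, k=1)
    pick = rng.choice(iu[0].size, size=n_edges, replace=False)
    a = np.zeros((n_nodes, n_nodes), dtype=bool)
    a[iu[0][pick], iu[1][pick]] = True
    return a | a.T


def small_worldness(
    g: BinaryGraph, ensemble: tuple[float, float]
) -> tuple[float, float, float]:
    """(gamma, lambda, sigma) against surrogate normalizers (C_random, L_random)."""
    c_random, l_random = ensemble
    if c_random <= 0 or l_random <= 0:
        raise ValueError("surrogate normalizers must be positive")
    c = clustering_coefficient(g)
    l_obs, _ = char_path_length(g)
    gamma = c / c_random
    lam = l_obs / l_random
    return gamma, lam, gamma / lam


def compute_metrics(
    g: BinaryGraph,
    n_surrogates: int = DEFAULT_N_SURROGATES,
    seed: int | np.random.SeedSequence | None = None,
) -> GraphMetrics:
    """All graph metrics for one binary graph, with surrogate normalization.

    Set ``n_surrogates=0`` to skip the (comparatively costly) surrogate
    ensemble; gamma/lambda/sigma are then ``None``.
    """
    dist = shortest_path_lengths(g)
    l_obs, n_unreach = char_path_length(g, dist)
    e_glob = global_efficiency(g, dist)
    e_loc, e_loc_mean = local_efficiency(g)
    c = clustering_coefficient(g)
    gamma = lam = sigma = None
    if n_surrogates > 0:
        ens = surrogate_ensemble(g, n=n_surrogates, seed=seed)
        gamma, lam, sigma = small_worldness(g, ens)
    return GraphMetrics(
        L=l_obs,
        E_global=e_glob,
        E_local_per_node=e_loc,
        E_local_mean=e_loc_mean,
        C=c,
        gamma=gamma,
        lam=lam,
        sigma=sigma,
        n_surrogates=n_surrogates,
        unreachable_pairs=n_unreach,
    )
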