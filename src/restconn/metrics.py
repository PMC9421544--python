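"""Whole-brain integration/segregation metrics and null-model machinery.

Integration: characteristic path length (CPL) and global efficiency, using
shortest paths with edge length 1/weight (binary: 1). Segregation: per-node
clustering (Watts-Strogatz binary; Onnela geometric-mean triangle intensity
weighted), local efficiency (global efficiency of each node's neighborhood
subgraph) and Newman-Girvan modularity Q. Small-worldness sigma compares
clustering and path length against a Maslov-Sneppen ensemble of
degree-preserving rewires.

Disconnected networks do not error: path-based metrics average over
reachable pairs and set a ``disconnected`` flag, because proportionally
thresholded subject networks can fragment at sparse densities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components, shortest_path

from restconn.types import Partition, ThresholdedNetwork, ValidationError

try:  # jitted double-edge-swap kernel; pure-python fallback below
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap


@njit(cache=True)
def _swap_kernel_labeled(edges, adj_mask, labels, pick1, pick2, flip):  # pragma: no cover
    """Double-edge swaps restricted to between-module edges.

    Like :func:`_swap_kernel` but a swap is accepted only if both proposed
    edges still join different modules, so every node's within-module
    neighborhood (and hence within/between degree split) is preserved.
    """
    swapped = 0
    for t in range(pick1.shape[0]):
        e1 = pick1[t]
        e2 = pick2[t]
        if e1 == e2:
            continue
        a = edges[e1, 0]
        b = edges[e1, 1]
        c = edges[e2, 0]
        d = edges[e2, 1]
        if flip[t]:
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            continue
        if labels[a] == labels[d] or labels[c] == labels[b]:
            continue
        if adj_mask[a, d] or adj_mask[c, b]:
            continue
        adj_mask[a, b] = 0
        adj_mask[b, a] = 0
        adj_mask[c, d] = 0
        adj_mask[d, c] = 0
        adj_mask[a, d] = 1
        adj_mask[d, a] = 1
        adj_mask[c, b] = 1
        adj_mask[b, c] = 1
        edges[e1, 0] = a
        edges[e1, 1] = d
        edges[e2, 0] = c
        edges[e2, 1] = b
        swapped += 1
    return swapped


@njit(cache=True)
def _swap_kernel(edges, adj_mask, pick1, pick2, flip):  # pragma: no cover
    """Sequential double-edge swaps on an edge array.

    ``edges`` is (m, 2) int64, ``adj_mask`` an n x n uint8 adjacency
    indicator (mutated in place), ``pick1``/``pick2``/``flip`` pregenerated
    randomness (one entry per attempt). Returns the number of swaps made.
    """
    swapped = 0
    for t in range(pick1.shape[0]):
        e1 = pick1[t]
        e2 = pick2[t]
        if e1 == e2:
            continue
        a = edges[e1, 0]
        b = edges[e1, 1]
        c = edges[e2, 0]
        d = edges[e2, 1]
        if flip[t]:
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            continue
        if adj_mask[a, d] or adj_mask[c, b]:
            continue
        adj_mask[a, b] = 0
        adj_mask[b, a] = 0
        adj_mask[c, d] = 0
        adj_mask[d, c] = 0
        adj_mask[a, d] = 1
        adj_mask[d, a] = 1
        adj_mask[c, b] = 1
        adj_mask[b, c] = 1
        edges[e1, 0] = a
        edges[e1, 1] = d
        edges[e2, 0] = c
        edges[e2, 1] = b
        swapped += 1
    return swapped


def shortest_path_lengths(net: ThresholdedNetwork) -> np.ndarray:
    """All-pairs distance matrix; edge length = 1/weight, unreachable = inf."""
    adj = net.adjacency
    with np.errstate(divide="ignore"):
        lengths = np.where(adj > 0, 1.0 / np.where(adj > 0, adj, 1.0), 0.0)
    if net.mode == "binary":
        lengths = (adj > 0).astype(float)
    return shortest_path(lengths, method="D", directed=False, unweighted=False)


def _finite_offdiag(dist: np.ndarray) -> tuple[np.ndarray, bool]:
    n = dist.shape[0]
    mask = ~np.eye(n, dtype=bool)
    vals = dist[mask]
    finite = np.isfinite(vals)
    return vals[finite], bool((~finite).any())


def characteristic_path_length(
    net: ThresholdedNetwork, dist: np.ndarray | None = None
) -> tuple[float, bool]:
    """Mean shortest-path distance over reachable node pairs.

    Returns ``(cpl, disconnected)``; the flag is True when any pair is
    unreachable (mean then covers reachable pairs only).
    """
    if dist is None:
        dist = shortest_path_lengths(net)
    vals, disconnected = _finite_offdiag(dist)
    cpl = float(vals.mean()) if vals.size else np.inf
    return cpl, disconnected


def global_efficiency(
    net: ThresholdedNetwork, dist: np.ndarray | None = None
) -> float:
    """Mean inverse shortest-path distance over all pairs (1/inf = 0)."""
    if dist is None:
        dist = shortest_path_lengths(net)
    n = dist.shape[0]
    if n < 2:
        return 0.0
    mask = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(dist[mask] > 0, 1.0 / dist[mask], 0.0)
    return float(np.where(np.isfinite(inv), inv, 0.0).mean())


def clustering_coefficient(net: ThresholdedNetwork) -> tuple[np.ndarray, float]:
    """Per-node clustering and its mean.

    Binary: Watts-Strogatz triangle fraction. Weighted: Onnela geometric-mean
    triangle intensity with weights rescaled by the network maximum. Nodes
    with degree < 2 get 0.
    """
    adj = net.adjacency
    n = net.n_nodes
    deg = net.degrees().astype(float)
    denom = deg * (deg - 1)
    if net.mode == "binary":
        a = (adj > 0).astype(float)
        triangles = np.diag(a @ a @ a)
    else:
        wmax = adj.max()
        w = (adj / wmax) ** (1.0 / 3.0) if wmax > 0 else adj
        triangles = np.diag(w @ w @ w)
    cc = np.zeros(n)
    ok = denom > 0
    cc[ok] = triangles[ok] / denom[ok]
    return cc, float(cc.mean()) if n else 0.0


def local_efficiency(net: ThresholdedNetwork) -> tuple[np.ndarray, float]:
    """Global efficiency of each node's neighborhood subgraph; mean over nodes."""
    adj = net.adjacency
    n = net.n_nodes
    eloc = np.zeros(n)
    for i in range(n):
        nbrs = np.nonzero(adj[i])[0]
        if nbrs.size < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        subnet = ThresholdedNetwork(sub, density=1.0, mode=net.mode)
        eloc[i] = global_efficiency(subnet)
    return eloc, float(eloc.mean()) if n else 0.0


def modularity_q(
    net: ThresholdedNetwork,
    partition: Partition | np.ndarray,
    resolution: float = 1.0,
) -> float:
    """Newman-Girvan Q for a node partition, generalized to weights.

    Q = sum_s (w_ss / W - resolution * (s_s / 2W)^2) with W the total edge
    weight, w_ss the within-module weight and s_s the summed strength of
    module s.
    """
    labels = partition.labels if isinstance(partition, Partition) else np.asarray(partition)
    adj = net.adjacency
    if labels.shape[0] != adj.shape[0]:
        raise ValidationError("partition does not cover all nodes")
    two_w = adj.sum()
    if two_w == 0:
        return 0.0
    q = 0.0
    strengths = adj.sum(axis=1)
    for s in np.unique(labels):
        idx = labels == s
        w_ss = adj[np.ix_(idx, idx)].sum() / 2.0
        s_s = strengths[idx].sum()
        q += w_ss / (two_w / 2.0) - resolution * (s_s / two_w) ** 2
    return float(q)


def maslov_sneppen_rewire(
    net: ThresholdedNetwork,
    iterations_per_edge: int = 20,
    seed: int | np.random.Generator = 0,
) -> ThresholdedNetwork:
    """Degree-preserving double-edge-swap randomization.

    Repeatedly picks two edges (a-b, c-d) and rewires to (a-d, c-b),
    rejecting swaps that would create self-loops or multi-edges; weights
    travel with their edge. Attempts = iterations_per_edge x edge count.
    Preserves the degree sequence exactly and the weight multiset.

    Swap-free graphs (e.g. a clique) are returned unchanged with
    ``flags["rewire_fallback"]`` set.
    """
    rng = np.random.default_rng(seed)
    edges = net.edge_list().astype(np.int64)
    m = edges.shape[0]
    if m < 2:
        out = ThresholdedNetwork(net.adjacency.copy(), net.density, net.mode)
        out.flags["rewire_fallback"] = True
        return out
    weights = net.adjacency[edges[:, 0], edges[:, 1]].copy()
    n = net.n_nodes
    attempts = iterations_per_edge * m
    pick1 = rng.integers(0, m, size=attempts)
    pick2 = rng.integers(0, m, size=attempts)
    flip = rng.random(attempts) < 0.5
    adj_mask = (net.adjacency > 0).astype(np.uint8)
    swapped = _swap_kernel(edges, adj_mask, pick1, pick2, flip)
    adj = np.zeros((n, n))
    adj[edges[:, 0], edges[:, 1]] = weights
    adj[edges[:, 1], edges[:, 0]] = weights
    out = ThresholdedNetwork(adj, net.density, net.mode)
    if swapped == 0:
        out.flags["rewire_fallback"] = True
    return out


def between_module_rewire(
    net: ThresholdedNetwork,
    labels: np.ndarray,
    iterations_per_edge: int = 20,
    seed: int | np.random.Generator = 0,
) -> ThresholdedNetwork:
    """Degree-preserving rewiring of between-module edges only.

    Double-edge swaps are drawn from the between-module edge set and
    accepted only when both proposed edges still join different modules, so
    every node's within-module neighborhood — and hence its within/between
    degree split — is preserved exactly; only the allocation of
    between-module edges across foreign modules is randomized. This is the
    null model used to normalize the participation coefficient.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    edges = net.edge_list().astype(np.int64)
    between = labels[edges[:, 0]] != labels[edges[:, 1]]
    edges_b = edges[between]
    m = edges_b.shape[0]
    if m < 2:
        out = ThresholdedNetwork(net.adjacency.copy(), net.density, net.mode)
        out.flags["rewire_fallback"] = True
        return out
    weights_b = net.adjacency[edges_b[:, 0], edges_b[:, 1]].copy()
    attempts = iterations_per_edge * m
    pick1 = rng.integers(0, m, size=attempts)
    pick2 = rng.integers(0, m, size=attempts)
    flip = rng.random(attempts) < 0.5
    adj_mask = (net.adjacency > 0).astype(np.uint8)
    swapped = _swap_kernel_labeled(
        edges_b, adj_mask, labels.astype(np.int64), pick1, pick2, flip
    )
    adj = net.adjacency.copy()
    # remove the old between-module edges, lay down the rewired ones
    old = edges[between]
    adj[old[:, 0], old[:, 1]] = 0.0
    adj[old[:, 1], old[:, 0]] = 0.0
    adj[edges_b[:, 0], edges_b[:, 1]] = weights_b
    adj[edges_b[:, 1], edges_b[:, 0]] = weights_b
    out = ThresholdedNetwork(adj, net.density, net.mode)
    if swapped == 0:
        out.flags["rewire_fallback"] = True
    return out


def null_ensemble(
    net: ThresholdedNetwork,
    size: int,
    iterations_per_edge: int = 20,
    seed: int | np.random.Generator = 0,
) -> list[ThresholdedNetwork]:
    """Ensemble of independent Maslov-Sneppen rewires of one network."""
    rng = np.random.default_rng(seed)
    return [
        maslov_sneppen_rewire(net, iterations_per_edge, rng) for _ in range(size)
    ]


def small_worldness(
    net: ThresholdedNetwork,
    n_null: int = 100,
    iterations_per_edge: int = 20,
    seed: int | np.random.Generator = 0,
) -> float:
    """sigma = (CC / <CC_null>) / (CPL / <CPL_null>).

    Null means are taken over ``n_null`` degree-preserving rewires; sigma > 1
    indicates lattice-like clustering with random-like path length.
    """
    _, cc = clustering_coefficient(net)
    cpl, _ = characteristic_path_length(net)
    cc_null = np.empty(n_null)
    cpl_null = np.empty(n_null)
    for b, null in enumerate(null_ensemble(net, n_null, iterations_per_edge, seed)):
        _, cc_null[b] = clustering_coefficient(null)
        cpl_null[b], _ = characteristic_path_length(null)
    if cc_null.mean() == 0:
        raise ValidationError("null ensemble has zero mean clustering")
    return float((cc / cc_null.mean()) / (cpl / cpl_null.mean()))


@dataclass
class GlobalMetrics:
    """Whole-brain summary of one thresholded network."""

    cpl: float
    e_glob: float
    e_loc_mean: float
    cc_mean: float
    modularity_q: float
    small_worldness: float
    disconnected: bool

    def as_dict(self) -> dict:
        return {
            "cpl": self.cpl,
            "e_glob": self.e_glob,
            "e_loc_mean": self.e_loc_mean,
            "cc_mean": self.cc_mean,
            "modularity_q": self.modularity_q,
            "small_worldness": self.small_worldness,
            "disconnected": self.disconnected,
        }


def is_connected(net: ThresholdedNetwork) -> bool:
    n_comp, _ = connected_components(net.adjacency > 0, directed=False)
    return int(n_comp) == 1


def global_metrics(
    net: ThresholdedNetwork,
    partition: Partition | None = None,
    n_null: int = 100,
    iterations_per_edge: int = 20,
    seed: int | np.random.Generator = 0,
    compute_sw: bool = True,
) -> GlobalMetrics:
    """All whole-brain metrics of one network in a single pass.

    ``partition`` (for Q) defaults to a single seeded Louvain run; pass the
    consensus partition for reproducible group-level reporting. Set
    ``compute_sw=False`` to skip the (expensive) null ensemble.
    """
    from restconn.community import louvain  # deferred: avoids import cycle

    dist = shortest_path_lengths(net)
    cpl, disconnected = characteristic_path_length(net, dist)
    e_glob = global_efficiency(net, dist)
    _, e_loc = local_efficiency(net)
    _, cc = clustering_coefficient(net)
    if partition is None:
        partition = louvain(net, seed=seed)
    q = modularity_q(net, partition)
    sw = (
        small_worldness(net, n_null, iterations_per_edge, seed)
        if compute_sw
        else np.nan
    )
    return GlobalMetrics(cpl, e_glob, e_loc, cc, q, sw, disconnected)
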