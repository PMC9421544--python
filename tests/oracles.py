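"""Independent brute-force oracles for cross-checking graph metrics.

Everything here is deliberately naive (triple loops, explicit enumeration)
and shares no code with the implementation under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def floyd_warshall_distances(adj: np.ndarray, binary: bool) -> np.ndarray:
    """All-pairs shortest paths by triple-loop Floyd-Warshall."""
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for i in range(n):
        for j in range(n):
            if adj[i, j] > 0:
                dist[i, j] = 1.0 if binary else 1.0 / adj[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    return dist


def cpl_oracle(adj: np.ndarray, binary: bool) -> tuple[float, bool]:
    dist = floyd_warshall_distances(adj, binary)
    vals = [dist[i, j] for i in range(len(adj)) for j in range(len(adj)) if i != j]
    finite = [v for v in vals if math.isfinite(v)]
    return (sum(finite) / len(finite) if finite else math.inf,
            len(finite) < len(vals))


def global_efficiency_oracle(adj: np.ndarray, binary: bool) -> float:
    dist = floyd_warshall_distances(adj, binary)
    n = len(adj)
    total = sum(
        1.0 / dist[i, j] if math.isfinite(dist[i, j]) and dist[i, j] > 0 else 0.0
        for i in range(n) for j in range(n) if i != j
    )
    return total / (n * (n - 1)) if n > 1 else 0.0


def clustering_oracle(adj: np.ndarray, binary: bool) -> np.ndarray:
    """Watts-Strogatz (binary) / Onnela geometric-mean (weighted) CC."""
    n = adj.shape[0]
    wmax = adj.max() if adj.max() > 0 else 1.0
    cc = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        total = 0.0
        for a, b in itertools.combinations(nbrs, 2):
            if adj[a, b] > 0:
                if binary:
                    total += 1.0
                else:
                    total += (adj[i, a] / wmax * adj[i, b] / wmax
                              * adj[a, b] / wmax) ** (1.0 / 3.0)
        cc[i] = 2.0 * total / (k * (k - 1))
    return cc


def local_efficiency_oracle(adj: np.ndarray, binary: bool) -> np.ndarray:
    n = adj.shape[0]
    eloc = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j] > 0]
        if len(nbrs) < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        eloc[i] = global_efficiency_oracle(sub, binary)
    return eloc


def modularity_oracle(adj: np.ndarray, labels: np.ndarray) -> float:
    """Double-sum Newman-Girvan Q with the configuration null."""
    two_w = adj.sum()
    if two_w == 0:
        return 0.0
    k = adj.sum(axis=1)
    n = adj.shape[0]
    q = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += adj[i, j] - k[i] * k[j] / two_w
    return q / two_w


def bh_stepup_oracle(p: np.ndarray, alpha: float) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up rejection rule."""
    m = len(p)
    order = np.argsort(p)
    reject = np.zeros(m, dtype=bool)
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * alpha / m:
            k_max = rank
    reject[order[:k_max]] = True
    return reject


def pearson_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Two-pass covariance / sigma formula."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    sx = math.sqrt(sum((a - mx) ** 2 for a in x) / n)
    sy = math.sqrt(sum((b - my) ** 2 for b in y) / n)
    return cov / (sx * sy)


def random_weighted_graph(n: int, p_edge: float, rng: np.random.Generator,
                          binary: bool = False) -> np.ndarray:
    """Random symmetric nonnegative adjacency with zero diagonal."""
    adj = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                adj[i, j] = adj[j, i] = 1.0 if binary else rng.uniform(0.1, 1.0)
    return adj
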