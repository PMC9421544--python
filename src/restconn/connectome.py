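"""Connectivity matrices and density thresholding.

Pipeline entry: parcellated BOLD time series -> Pearson correlation matrix
-> (optional Fisher z) -> proportional thresholding over a density grid.
Proportional ("matching") thresholding keeps the k strongest edges so every
subject's network has exactly the same number of nodes and edges, removing
density as a between-subject confound.

Conventions (documented in docs/methods.md): edges are ranked by signed r,
negative weights surviving the cut are zeroed, k is rounded half away from
zero, and weight ties are broken by lexicographic (i, j) node order so the
edge set is deterministic and nested across densities.
"""

from __future__ import annotations

import numpy as np

from restconn.types import (
    ConnectivityMatrix,
    ThresholdedNetwork,
    TimeSeriesMatrix,
    ValidationError,
)

#: |r| is clipped to this bound before arctanh so Fisher z stays finite.
R_CLIP = 1.0 - 1e-7


def compute_fc(ts: TimeSeriesMatrix) -> ConnectivityMatrix:
    """Pearson correlation between all parcel pairs, zero diagonal.

    Raises :class:`ValidationError` naming the parcel if any column is
    constant (undefined correlation).
    """
    if ts.n_timepoints < 3:
        raise ValidationError("need at least 3 timepoints for correlation")
    bad = ts.constant_parcels()
    if bad:
        raise ValidationError(f"constant time series for parcel(s): {', '.join(bad)}")
    r = np.corrcoef(ts.values, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(r, scale="pearson_r", parcel_labels=list(ts.parcel_labels))


def fisher_z(cm: ConnectivityMatrix) -> ConnectivityMatrix:
    """Variance-stabilizing arctanh transform of a Pearson r matrix."""
    if cm.scale != "pearson_r":
        raise ValidationError("fisher_z expects a pearson_r matrix")
    z = np.arctanh(np.clip(cm.values, -R_CLIP, R_CLIP))
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(z, scale="fisher_z", parcel_labels=list(cm.parcel_labels))


def fisher_z_inverse(cm: ConnectivityMatrix) -> ConnectivityMatrix:
    """tanh back-transform of a Fisher z matrix."""
    if cm.scale != "fisher_z":
        raise ValidationError("fisher_z_inverse expects a fisher_z matrix")
    r = np.tanh(cm.values)
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(r, scale="pearson_r", parcel_labels=list(cm.parcel_labels))


def edge_count_at_density(n_nodes: int, density: float) -> int:
    """k = round(density * N(N-1)/2), half away from zero."""
    total = n_nodes * (n_nodes - 1) // 2
    return int(np.floor(density * total + 0.5))


def _ranked_edges(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle edges sorted by descending signed weight.

    Ties broken by lexicographic (i, j) order for determinism.
    """
    n = values.shape[0]
    iu, ju = np.triu_indices(n, 1)
    w = values[iu, ju]
    order = np.lexsort((ju, iu, -w))
    return np.column_stack([iu[order], ju[order]]), w[order]


def proportional_threshold(
    cm: ConnectivityMatrix, density: float, mode: str = "weighted"
) -> ThresholdedNetwork:
    """Keep the k strongest off-diagonal edges at the given density.

    Ranking uses signed r; retained negative weights are set to 0 so that
    all downstream metrics operate on nonnegative weights. ``mode="binary"``
    sets surviving edges to 1.
    """
    if not (0 < density <= 1):
        raise ValidationError("density must lie in (0, 1]")
    n = cm.n_nodes
    k = edge_count_at_density(n, density)
    if k == 0:
        raise ValidationError(f"density {density} retains zero edges for N={n}")
    edges, weights = _ranked_edges(cm.values)
    adj = np.zeros((n, n))
    keep = edges[:k]
    kept_w = np.maximum(weights[:k], 0.0) if mode == "weighted" else np.ones(k)
    adj[keep[:, 0], keep[:, 1]] = kept_w
    adj += adj.T
    return ThresholdedNetwork(adj, density=density, mode=mode)


def density_grid(
    start: float = 0.10, stop: float = 0.40, step: float = 0.01
) -> np.ndarray:
    """Strictly increasing density grid, rounded to avoid float drift.

    Default is the 10-40% analysis band in 1% increments (31 points); the
    full exploratory grid is ``density_grid(0.01, 0.40)``.
    """
    n_steps = int(round((stop - start) / step))
    grid = np.round(start + step * np.arange(n_steps + 1), 10)
    if (grid <= 0).any() or (grid > 1).any() or (np.diff(grid) <= 0).any():
        raise ValidationError("density grid must be strictly increasing within (0, 1]")
    return grid


def threshold_series(
    cm: ConnectivityMatrix, grid: np.ndarray | None = None, mode: str = "weighted"
) -> list[ThresholdedNetwork]:
    """One thresholded network per grid density.

    Deterministic tie-breaking makes the edge sets nested: the network at
    density d is a subgraph of the network at any d' > d.
    """
    if grid is None:
        grid = density_grid()
    return [proportional_threshold(cm, float(d), mode=mode) for d in grid]


def group_average_fc(
    cms: list[ConnectivityMatrix], density: float = 0.10, mode: str = "weighted"
) -> ThresholdedNetwork:
    """Group-representative network: z-average, back-transform, threshold.

    Subject matrices are averaged in Fisher-z space (variance-stabilized),
    mapped back to r, and proportionally thresholded (default: top 10% of
    connections, the density used for group-level hub detection).
    """
    if not cms:
        raise ValidationError("need at least one connectivity matrix")
    n = cms[0].n_nodes
    if any(cm.n_nodes != n for cm in cms):
        raise ValidationError("all connectivity matrices must share dimensions")
    zsum = np.zeros((n, n))
    for cm in cms:
        zsum += cm.values if cm.scale == "fisher_z" else fisher_z(cm).values
    mean_r = np.tanh(zsum / len(cms))
    np.fill_diagonal(mean_r, 0.0)
    avg = ConnectivityMatrix(mean_r, scale="pearson_r",
                             parcel_labels=list(cms[0].parcel_labels))
    return proportional_threshold(avg, density, mode=mode)
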