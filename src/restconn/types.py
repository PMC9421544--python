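"""Core containers shared across the pipeline.

All containers are thin dataclasses around numpy arrays with validation at
construction: downstream stages rely on the invariants enforced here
(symmetry, zero diagonal, exact edge counts) rather than re-checking them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ValidationError(ValueError):
    """Input violates a structural invariant (bad spec, malformed matrix)."""


def _as_labels(labels, n: int) -> list[str]:
    if labels is None:
        return [f"parcel_{i + 1}" for i in range(n)]
    labels = [str(x) for x in labels]
    if len(labels) != n:
        raise ValidationError(f"expected {n} parcel labels, got {len(labels)}")
    return labels


@dataclass
class TimeSeriesMatrix:
    """One subject's parcellated signal: T timepoints x N parcels."""

    values: np.ndarray
    subject_id: str = "subject"
    parcel_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("time series must be a 2-D T x N matrix")
        if not np.isfinite(self.values).all():
            raise ValidationError(
                f"time series for {self.subject_id} contains missing/non-finite values"
            )
        self.parcel_labels = _as_labels(self.parcel_labels, self.n_parcels)

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.values.shape[1]

    def constant_parcels(self) -> list[str]:
        """Labels of zero-variance columns (flagged, not silently dropped)."""
        sd = self.values.std(axis=0)
        return [self.parcel_labels[i] for i in np.nonzero(sd == 0)[0]]


@dataclass
class ConnectivityMatrix:
    """N x N symmetric weighted functional connectivity, zero diagonal.

    ``scale`` records whether entries are Pearson r or Fisher z values.
    """

    values: np.ndarray
    scale: str = "pearson_r"
    parcel_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape[1] != n:
            raise ValidationError("connectivity matrix must be square")
        if self.scale not in ("pearson_r", "fisher_z"):
            raise ValidationError(f"unknown scale {self.scale!r}")
        if not np.allclose(self.values, self.values.T, atol=1e-12, rtol=0):
            raise ValidationError("connectivity matrix not symmetric within 1e-12")
        if np.abs(np.diag(self.values)).max(initial=0.0) != 0.0:
            raise ValidationError("connectivity matrix diagonal must be zero")
        if self.scale == "pearson_r":
            off = self.values[~np.eye(n, dtype=bool)] if n else self.values
            if off.size and (np.abs(off) > 1 + 1e-12).any():
                raise ValidationError("pearson_r entries must lie in [-1, 1]")
        self.parcel_labels = _as_labels(self.parcel_labels, n)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class ThresholdedNetwork:
    """Connectivity at a fixed edge density; the object all metrics consume.

    ``adjacency`` is symmetric, nonnegative, zero-diagonal. ``mode`` is
    "weighted" (surviving correlation weights kept) or "binary" (survivors
    set to 1).
    """

    adjacency: np.ndarray
    density: float = 1.0
    mode: str = "weighted"
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        n = self.adjacency.shape[0]
        if self.adjacency.ndim != 2 or self.adjacency.shape[1] != n:
            raise ValidationError("adjacency must be square")
        if not np.allclose(self.adjacency, self.adjacency.T, atol=1e-12, rtol=0):
            raise ValidationError("adjacency must be symmetric")
        if np.abs(np.diag(self.adjacency)).max(initial=0.0) != 0.0:
            raise ValidationError("adjacency diagonal must be zero")
        if (self.adjacency < 0).any():
            raise ValidationError("adjacency weights must be nonnegative")
        if not (0 < self.density <= 1):
            raise ValidationError("density must lie in (0, 1]")
        if self.mode not in ("weighted", "binary"):
            raise ValidationError(f"unknown mode {self.mode!r}")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, 1)))

    def edge_list(self) -> np.ndarray:
        """(m, 2) array of upper-triangle edges in lexicographic order."""
        i, j = np.nonzero(np.triu(self.adjacency, 1))
        return np.column_stack([i, j])

    def degrees(self) -> np.ndarray:
        return np.count_nonzero(self.adjacency, axis=1)

    def strengths(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)


@dataclass
class Partition:
    """Module labels per node, contiguous 1..M, with the partition's Q."""

    labels: np.ndarray
    q: float = np.nan

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise ValidationError("partition labels must be a non-empty 1-D array")
        uniq = np.unique(self.labels)
        if not np.array_equal(uniq, np.arange(1, uniq.size + 1)):
            raise ValidationError("module labels must be contiguous 1..M")

    @property
    def n_modules(self) -> int:
        return int(self.labels.max())

    @property
    def n_nodes(self) -> int:
        return self.labels.size

    def module_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_modules + 1)[1:]


def relabel_contiguous(raw_labels: np.ndarray) -> np.ndarray:
    """Map arbitrary integer community ids to contiguous 1..M.

    Modules are numbered by order of first appearance so the result is
    deterministic for a fixed label vector.
    """
    raw_labels = np.asarray(raw_labels)
    _, first = np.unique(raw_labels, return_index=True)
    order = raw_labels[np.sort(first)]
    mapping = {old: new for new, old in enumerate(order, start=1)}
    return np.array([mapping[x] for x in raw_labels], dtype=int)
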