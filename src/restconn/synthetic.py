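"""Synthetic two-group cohorts with known connectome structure.

The generator draws each subject's parcellated time series from a
stationary zero-mean multivariate Gaussian whose correlation template has
block-modular structure: ``within_r`` inside modules, ``between_r``
between modules, unit diagonal. Planted features give every downstream
stage ground truth:

* hub nodes receive elevated between-module loadings (degree heterogeneity
  and connector-hub candidates);
* effect nodes have their between-module coupling shifted by
  ``effect_delta`` in group B only (a localized group difference that
  propagates to the participation coefficient);
* one behavior node's between-module loading is jittered per subject and
  the behavioral score is built from that jitter at correlation
  ``rho_behavior`` (a planted brain-behavior association);
* group ages differ by ``age_shift`` years (a nuisance covariate).

A stationary Gaussian (no hemodynamics, no autocorrelation) is sufficient
because every downstream statistic operates on Pearson correlations of the
series. Covariances are repaired to the nearest correlation-like PSD
matrix by eigenvalue clipping when planted shifts break positive
semidefiniteness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from restconn.types import ThresholdedNetwork, TimeSeriesMatrix, ValidationError

PSD_TOL = 1e-8


@dataclass
class CohortSpec:
    """Parameters of a synthetic two-group cohort.

    Defaults emulate the study design this pipeline targets: 28 + 29
    subjects, 250 timepoints, five modules, with a desk-scale 90-node
    connectome (scalable to 333).
    """

    n_per_group: tuple[int, int] = (28, 29)
    n_nodes: int = 90
    n_timepoints: int = 250
    n_modules: int = 5
    module_sizes: tuple[int, ...] | None = None
    within_r: float = 0.5
    within_spread: float = 0.08
    between_r: float = 0.1
    hub_nodes: tuple[int, ...] | None = None
    hub_boost: float = 0.45
    hub_partners: int = 2
    effect_nodes: tuple[int, ...] = (20, 40, 60)
    effect_delta: float = -0.15
    behavior_node: int = 75
    behavior_jitter_sd: float = 0.06
    rho_behavior: float = 0.6
    age_mean: float = 10.9
    age_sd: float = 1.5
    age_shift: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.module_sizes is None:
            base = self.n_nodes // self.n_modules
            sizes = [base] * self.n_modules
            for i in range(self.n_nodes - base * self.n_modules):
                sizes[i] += 1
            self.module_sizes = tuple(sizes)
        if self.hub_nodes is None:
            # first node of each module gets elevated cross-module loading
            bounds = np.cumsum((0,) + tuple(self.module_sizes))[:-1]
            self.hub_nodes = tuple(int(b) for b in bounds)
        self.validate()

    def validate(self) -> None:
        if min(self.n_per_group) < 1 or self.n_timepoints < 10:
            raise ValidationError("need n >= 1 per group and T >= 10")
        if sum(self.module_sizes) != self.n_nodes:
            raise ValidationError("module_sizes must sum to n_nodes")
        if not (0 <= self.between_r < self.within_r < 1):
            raise ValidationError("require 0 <= between_r < within_r < 1")
        nodes = set(self.hub_nodes) | set(self.effect_nodes) | {self.behavior_node}
        if any(not (0 <= v < self.n_nodes) for v in nodes):
            raise ValidationError("node ids must lie in [0, n_nodes)")

    def module_labels(self) -> np.ndarray:
        """Ground-truth partition, labels 1..M."""
        return np.repeat(np.arange(1, self.n_modules + 1), self.module_sizes)


@dataclass
class SyntheticCohort:
    """Generated cohort: per-subject series, design table and ground truth."""

    spec: CohortSpec
    subjects: list[TimeSeriesMatrix]
    design: pd.DataFrame
    truth_partition: np.ndarray
    effect_nodes: tuple[int, ...]
    hub_nodes: tuple[int, ...]
    behavior_node: int
    #: latent per-subject coupling jitter at the behavior node (ground truth
    #: for the planted brain-behavior association)
    behavior_coupling: np.ndarray | None = None

    def by_group(self) -> dict[str, list[TimeSeriesMatrix]]:
        out: dict[str, list[TimeSeriesMatrix]] = {}
        for subj, grp in zip(self.subjects, self.design["group"]):
            out.setdefault(grp, []).append(subj)
        return out


def nearest_psd_correlation(cov: np.ndarray, tol: float = PSD_TOL) -> np.ndarray:
    """Clip negative eigenvalues to 0 and renormalize the diagonal to 1."""
    cov = (cov + cov.T) / 2.0
    vals, vecs = np.linalg.eigh(cov)
    if vals.min() >= 0:
        return cov
    vals = np.clip(vals, 0.0, None)
    repaired = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    if (d <= tol).any():
        raise ValidationError("PSD repair produced a degenerate diagonal")
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return (repaired + repaired.T) / 2.0


def build_covariance(spec: CohortSpec) -> np.ndarray:
    """Block-modular correlation template with planted hub loadings.

    The template is a within-module block part plus a rank-one global
    factor g g^T that carries all between-module coupling:

    * non-hub global loadings are sqrt(between_r), so between-module
      entries sit at exactly ``between_r``;
    * hub loadings are sqrt(between_r + hub_boost), elevating hub cross-
      module edges (hub-hub pairs reach between_r + hub_boost, a
      rich-club-like motif that keeps sparse thresholded networks in one
      component and plants high-strength hub ground truth);
    * within-module off-diagonals average ``within_r``; with
      ``within_spread > 0`` they decay smoothly with in-module node
      distance (within_r + spread for adjacent nodes down to
      within_r - spread), emulating the graded edge weights of real FC so
      proportional thresholding is not decided by ties.

    The factor construction is PSD by design up to the hub rows' reduced
    idiosyncratic variance; nearest-PSD repair handles any residual
    indefiniteness.
    """
    spec.validate()
    labels = spec.module_labels()
    same = labels[:, None] == labels[None, :]
    base = spec.within_r - spec.between_r  # block part on top of the factor
    cov = np.where(same, base, 0.0).astype(float)
    if spec.within_spread > 0:
        bounds = np.cumsum((0,) + tuple(spec.module_sizes))
        for s in range(spec.n_modules):
            lo, hi = bounds[s], bounds[s + 1]
            m = hi - lo
            if m < 3:
                continue
            idx = np.arange(m)
            d = np.abs(idx[:, None] - idx[None, :])  # in-module chain distance
            taper = 1.0 - 2.0 * (d - 1) / (m - 2)
            cov[lo:hi, lo:hi] = base + spec.within_spread * taper
    g = np.full(spec.n_nodes, np.sqrt(spec.between_r))
    if spec.n_modules > 1 and spec.between_r + spec.hub_boost < 1:
        g[list(spec.hub_nodes)] = np.sqrt(spec.between_r + spec.hub_boost)
    cov += np.outer(g, g)
    np.fill_diagonal(cov, 1.0)
    if np.abs(cov).max() > 1.0:
        raise ValidationError("planted loadings push correlations outside (-1, 1)")
    return nearest_psd_correlation(cov)


def _apply_between_shift(
    cov: np.ndarray, labels: np.ndarray, nodes: tuple[int, ...], delta: float
) -> np.ndarray:
    """Shift the between-module entries of the given nodes by delta."""
    out = cov.copy()
    same = labels[:, None] == labels[None, :]
    for v in nodes:
        other = ~same[v]
        other[v] = False
        out[v, other] += delta
        out[other, v] += delta
    np.fill_diagonal(out, 1.0)
    if np.abs(out).max() > 1.0:
        raise ValidationError("effect_delta pushes correlations outside (-1, 1)")
    return nearest_psd_correlation(out)


def simulate_subject(
    cov: np.ndarray,
    n_timepoints: int,
    seed: int | np.random.Generator,
    subject_id: str = "subject",
) -> TimeSeriesMatrix:
    """T x N draw from a zero-mean multivariate normal with the given cov."""
    if n_timepoints < 10:
        raise ValidationError("need T >= 10")
    cov = np.asarray(cov, float)
    vals, vecs = np.linalg.eigh((cov + cov.T) / 2.0)
    if vals.min() < -PSD_TOL:
        raise ValidationError("covariance is not positive semidefinite")
    rng = np.random.default_rng(seed)
    factor = vecs * np.sqrt(np.clip(vals, 0.0, None))
    draws = rng.standard_normal((n_timepoints, cov.shape[0]))
    return TimeSeriesMatrix(draws @ factor.T, subject_id=subject_id)


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate the full two-group cohort with recorded ground truth.

    Group B ("apd_like") uses a covariance with ``effect_delta`` applied at
    the effect nodes' between-module entries. Every subject's behavior-node
    loading is jittered; the behavioral score mixes the standardized jitter
    with Gaussian noise at correlation ``rho_behavior``. Ages are Gaussian
    with the group B mean shifted by ``age_shift``. Bit-reproducible for a
    fixed spec (all randomness flows from ``spec.seed``).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    labels = spec.module_labels()
    cov_control = build_covariance(spec)
    cov_case = _apply_between_shift(
        cov_control, labels, spec.effect_nodes, spec.effect_delta
    )
    n_b, n_a = spec.n_per_group  # (APD-like, control-like) per study design
    groups = ["apd_like"] * n_b + ["control_like"] * n_a
    base_cov = [cov_case] * n_b + [cov_control] * n_a

    n_total = n_b + n_a
    jitter = rng.normal(0.0, spec.behavior_jitter_sd, size=n_total)
    noise = rng.standard_normal(n_total)
    z_jitter = (jitter - jitter.mean()) / jitter.std()
    score = spec.rho_behavior * z_jitter + np.sqrt(
        max(0.0, 1 - spec.rho_behavior**2)
    ) * noise
    ages = np.concatenate([
        rng.normal(spec.age_mean, spec.age_sd, n_b),
        rng.normal(spec.age_mean + spec.age_shift, spec.age_sd, n_a),
    ])

    subjects = []
    for i in range(n_total):
        cov_i = _apply_between_shift(
            base_cov[i], labels, (spec.behavior_node,), float(jitter[i])
        )
        subjects.append(
            simulate_subject(cov_i, spec.n_timepoints, rng, subject_id=f"sub-{i + 1:03d}")
        )
    design = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "group": groups,
            "age": ages,
            "score": score,
        }
    )
    return SyntheticCohort(
        spec=spec,
        subjects=subjects,
        design=design,
        truth_partition=labels,
        effect_nodes=spec.effect_nodes,
        hub_nodes=spec.hub_nodes,
        behavior_node=spec.behavior_node,
        behavior_coupling=jitter,
    )


# ---------------------------------------------------------------------------
# analytic fixture graphs


def fixture_graph(name: str, *args, seed: int = 0) -> ThresholdedNetwork:
    """Small analytic graphs used as metric oracles.

    Families: ring_lattice(n, k), star(n), clique(n), two_cliques(n),
    planted_partition(n, M, p_in, p_out), path(n). All are binary
    (weights 1), symmetric, zero diagonal.
    """
    builders = {
        "ring_lattice": lambda n, k: nx.watts_strogatz_graph(n, k, 0.0),
        "star": lambda n: nx.star_graph(n - 1),
        "clique": nx.complete_graph,
        "two_cliques": lambda n: nx.disjoint_union(
            nx.complete_graph(n), nx.complete_graph(n)
        ),
        "planted_partition": lambda n, m, p_in, p_out: nx.planted_partition_graph(
            m, n // m, p_in, p_out, seed=seed
        ),
        "path": nx.path_graph,
    }
    if name not in builders:
        raise ValidationError(f"unknown fixture family {name!r}")
    g = builders[name](*args)
    adj = nx.to_numpy_array(g)
    return ThresholdedNetwork(adj, density=1.0, mode="binary")
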