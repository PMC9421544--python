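"""Permutation group statistics for nodal and edgewise connectome measures.

Inference follows the permutation-GLM approach: nuisance covariates
(demeaned) are regressed out once, group labels are permuted over the
residuals (Freedman-Lane), and two-tailed p-values use the (1 + exceed) /
(B + 1) estimator so p >= 1/(B+1). Nodal tests share a single permutation
schedule across all nodes and measures, which keeps the joint
Benjamini-Hochberg FDR correction coherent. Edgewise group differences use
the network-based statistic (NBS): suprathreshold components compared
against a permutation null of maximal component sizes (FWE control).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests

from restconn.types import ValidationError


# ---------------------------------------------------------------------------
# curve summarization


def auc_over_densities(densities: np.ndarray, curve: np.ndarray) -> float:
    """Trapezoid area under a metric-vs-density curve (x in density units)."""
    densities = np.asarray(densities, float)
    curve = np.asarray(curve, float)
    if densities.size < 2:
        raise ValidationError("need at least 2 grid points for an AUC")
    bad = np.nonzero(~np.isfinite(curve))[0]
    if bad.size:
        raise ValidationError(f"non-finite curve value at density {densities[bad[0]]}")
    return float(np.trapezoid(curve, densities))


# ---------------------------------------------------------------------------
# permutation two-sample tests (Freedman-Lane)


def _residualize(y: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Residuals of y (n x m) on [1, demeaned covariates] by least squares."""
    y = np.atleast_2d(np.asarray(y, float))
    if y.shape[0] == 1:
        y = y.T
    n = y.shape[0]
    if covariates is None or covariates.size == 0:
        return y - y.mean(axis=0)
    x = np.atleast_2d(np.asarray(covariates, float))
    if x.shape[0] == 1:
        x = x.T
    x = x - x.mean(axis=0)
    design = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def _welch_t_matrix(values: np.ndarray, group_a: np.ndarray, group_b: np.ndarray) -> np.ndarray:
    """Welch t per column for group_a vs group_b row masks; 0/0 -> 0."""
    a = values[group_a]
    b = values[group_b]
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1) / na
    vb = b.var(axis=0, ddof=1) / nb
    denom = np.sqrt(va + vb)
    diff = a.mean(axis=0) - b.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0), 0.0)
    return t


def permutation_schedule(
    n: int, n_perm: int, seed: int | np.random.Generator
) -> np.ndarray:
    """(B, n) permutation index matrix; one shared schedule per analysis."""
    rng = np.random.default_rng(seed)
    return np.array([rng.permutation(n) for _ in range(n_perm)])


def _welch_t_batch(
    resid: np.ndarray, masks_a: np.ndarray, na: int, nb: int
) -> np.ndarray:
    """Welch t for a batch of group-A membership masks (B x n) at once.

    Uses sums and sums of squares via matrix products; returns (B, m).
    """
    total = resid.sum(axis=0)
    total_sq = (resid**2).sum(axis=0)
    sum_a = masks_a @ resid
    ssq_a = masks_a @ (resid**2)
    sum_b = total - sum_a
    ssq_b = total_sq - ssq_a
    mean_a, mean_b = sum_a / na, sum_b / nb
    var_a = np.maximum(ssq_a - sum_a**2 / na, 0.0) / (na - 1)
    var_b = np.maximum(ssq_b - sum_b**2 / nb, 0.0) / (nb - 1)
    denom = np.sqrt(var_a / na + var_b / nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom > 0, (mean_a - mean_b) / np.where(denom > 0, denom, 1.0), 0.0)


def permutation_ttest_matrix(
    values: np.ndarray,
    groups: np.ndarray,
    covariates: np.ndarray | None = None,
    n_perm: int = 20000,
    seed: int | np.random.Generator = 0,
    schedule: np.ndarray | None = None,
    chunk: int = 2000,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch-t permutation test per column with nuisance covariates.

    Freedman-Lane style: ``values`` (n_subjects x m) are residualized on the
    demeaned covariates, the observed Welch t compares the two groups on
    those residuals, and the null is built by permuting subject rows (group
    labels fixed). Two-tailed p = (1 + #{|t*| >= |t|}) / (B + 1). All
    columns share one permutation schedule.
    """
    values = np.atleast_2d(np.asarray(values, float))
    if values.shape[0] == 1:
        values = values.T
    groups = np.asarray(groups)
    codes = np.unique(groups)
    if codes.size != 2:
        raise ValidationError("exactly two groups required")
    mask_a = groups == codes[0]
    na, nb = int(mask_a.sum()), int((~mask_a).sum())
    if na < 2 or nb < 2:
        raise ValidationError("each group needs n >= 2")
    resid = _residualize(values, covariates)
    t_obs = _welch_t_matrix(resid, mask_a, ~mask_a)
    if schedule is None:
        schedule = permutation_schedule(values.shape[0], n_perm, seed)
    n = values.shape[0]
    exceed = np.ones(values.shape[1])
    for lo in range(0, schedule.shape[0], chunk):
        block = schedule[lo:lo + chunk]
        masks = np.zeros((block.shape[0], n))
        rows = np.repeat(np.arange(block.shape[0]), na)
        masks[rows, block[:, mask_a].ravel()] = 1.0
        t_null = _welch_t_batch(resid, masks, na, nb)
        exceed += (np.abs(t_null) >= np.abs(t_obs)[None, :] - 1e-12).sum(axis=0)
    p = exceed / (schedule.shape[0] + 1)
    return t_obs, np.minimum(p, 1.0)


def permutation_ttest(
    values: np.ndarray,
    groups: np.ndarray,
    covariates: np.ndarray | None = None,
    n_perm: int = 20000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Scalar convenience wrapper around :func:`permutation_ttest_matrix`."""
    t, p = permutation_ttest_matrix(
        np.asarray(values, float).reshape(-1, 1), groups, covariates, n_perm, seed
    )
    return float(t[0]), float(p[0])


# ---------------------------------------------------------------------------
# FDR


def fdr_correct_joint(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up over the pooled p-vector.

    Returns (q_values, significant flags). Pooling all nodes and measures
    into one family implements joint correction across ROIs and measures.
    """
    p_values = np.asarray(p_values, float).ravel()
    if p_values.size == 0:
        raise ValidationError("empty p-value vector")
    if ((p_values <= 0) | (p_values > 1)).any():
        raise ValidationError("p-values must lie in (0, 1]")
    reject, q_values, *_ = multipletests(p_values, alpha=q, method="fdr_bh")
    return q_values, reject


# ---------------------------------------------------------------------------
# nodal suite


def nodal_test_suite(
    auc_tables: dict[str, np.ndarray],
    groups: np.ndarray,
    covariates: np.ndarray | None = None,
    n_perm: int = 20000,
    q: float = 0.05,
    seed: int | np.random.Generator = 0,
    fdr_scope: str = "joint",
) -> pd.DataFrame:
    """Permutation t-tests per node per measure with joint FDR.

    ``auc_tables`` maps measure name (e.g. "pc", "pc_norm", "wmz") to an
    (n_subjects x n_nodes) AUC matrix. One shared permutation schedule
    covers every node and measure; p-values are then BH-corrected jointly
    (``fdr_scope="per_measure"`` pools within each measure instead).
    """
    measures = list(auc_tables)
    stacked = np.hstack([np.asarray(auc_tables[m], float) for m in measures])
    n_nodes = {m: np.asarray(auc_tables[m]).shape[1] for m in measures}
    t, p = permutation_ttest_matrix(
        stacked, groups, covariates, n_perm=n_perm, seed=seed
    )
    rows = []
    offset = 0
    for m in measures:
        for node in range(n_nodes[m]):
            rows.append({"node_id": node + 1, "measure": m,
                         "t": t[offset + node], "p": p[offset + node]})
        offset += n_nodes[m]
    out = pd.DataFrame(rows)
    if fdr_scope == "joint":
        out["q"], out["significant"] = fdr_correct_joint(out["p"].values, q)
    elif fdr_scope == "per_measure":
        out["q"] = np.nan
        out["significant"] = False
        for m in measures:
            idx = out["measure"] == m
            qs, rej = fdr_correct_joint(out.loc[idx, "p"].values, q)
            out.loc[idx, "q"] = qs
            out.loc[idx, "significant"] = rej
    else:
        raise ValidationError(f"unknown fdr_scope {fdr_scope!r}")
    return out


# ---------------------------------------------------------------------------
# network-based statistic


@dataclass
class NBSResult:
    """Suprathreshold components with FWE-corrected p-values."""

    components: list[np.ndarray] = field(default_factory=list)  # (m, 2) edge arrays
    sizes: list[int] = field(default_factory=list)
    fwe_p: list[float] = field(default_factory=list)
    directions: list[int] = field(default_factory=list)  # +1: A>B, -1: A<B
    null_max_sizes: np.ndarray = field(default_factory=lambda: np.array([]))

    def significant(self, alpha: float = 0.05) -> list[int]:
        return [i for i, p in enumerate(self.fwe_p) if p < alpha]


def _suprathreshold_components(
    t: np.ndarray, t_init: float, n_nodes: int, iu: np.ndarray, ju: np.ndarray
) -> list[tuple[np.ndarray, int]]:
    """Connected components of edges with t > t_init and t < -t_init."""
    comps = []
    for sign in (1, -1):
        mask = (sign * t) > t_init
        if not mask.any():
            continue
        ei, ej = iu[mask], ju[mask]
        g = coo_matrix((np.ones(ei.size), (ei, ej)), shape=(n_nodes, n_nodes))
        n_comp, labels = connected_components(g, directed=False)
        for c in range(n_comp):
            edge_in = labels[ei] == c
            if edge_in.sum() >= 1 and (labels == c).sum() > 1:
                comps.append((np.column_stack([ei[edge_in], ej[edge_in]]), sign))
    return comps


def _max_component_size(t: np.ndarray, t_init: float, n_nodes: int,
                        iu: np.ndarray, ju: np.ndarray) -> int:
    best = 0
    for comp, _ in _suprathreshold_components(t, t_init, n_nodes, iu, ju):
        best = max(best, comp.shape[0])
    return best


def nbs(
    fisher_z_stack: np.ndarray,
    groups: np.ndarray,
    covariates: np.ndarray | None = None,
    t_init: float = 3.9856,
    n_perm: int = 10000,
    seed: int | np.random.Generator = 0,
) -> NBSResult:
    """Network-based statistic on a subject stack of Fisher-z matrices.

    Edgewise Welch t on Freedman-Lane residuals (covariates demeaned and
    regressed out); suprathreshold graphs are formed separately for t >
    t_init and t < -t_init; observed component sizes (edge counts) are
    compared against the permutation null of the maximal component size
    over both directions. FWE p = (1 + #{max* >= size}) / (B + 1).
    """
    if t_init <= 0:
        raise ValidationError("t_init must be positive")
    stack = np.asarray(fisher_z_stack, float)
    if stack.ndim != 3 or stack.shape[1] != stack.shape[2]:
        raise ValidationError("expect an (n_subjects, N, N) stack")
    n_sub, n_nodes, _ = stack.shape
    groups = np.asarray(groups)
    codes = np.unique(groups)
    if codes.size != 2:
        raise ValidationError("exactly two groups required")
    mask_a = groups == codes[0]
    mask_b = groups == codes[1]
    iu, ju = np.triu_indices(n_nodes, 1)
    edges = stack[:, iu, ju]  # n_sub x E
    resid = _residualize(edges, covariates)
    t_obs = _welch_t_matrix(resid, mask_a, mask_b)
    observed = _suprathreshold_components(t_obs, t_init, n_nodes, iu, ju)
    result = NBSResult()
    rng = np.random.default_rng(seed)
    na, nb = int(mask_a.sum()), int(mask_b.sum())
    null_max = np.empty(n_perm, dtype=int)
    chunk = max(1, min(n_perm, 20_000_000 // max(1, resid.shape[1] * 8)))
    done = 0
    while done < n_perm:
        b_count = min(chunk, n_perm - done)
        masks = np.zeros((b_count, n_sub))
        for b in range(b_count):
            masks[b, rng.permutation(n_sub)[mask_a]] = 1.0
        t_null = _welch_t_batch(resid, masks, na, nb)
        for b in range(b_count):
            null_max[done + b] = _max_component_size(
                t_null[b], t_init, n_nodes, iu, ju
            )
        done += b_count
    result.null_max_sizes = null_max
    for comp, sign in observed:
        size = comp.shape[0]
        p = (1 + int((null_max >= size).sum())) / (n_perm + 1)
        result.components.append(comp)
        result.sizes.append(size)
        result.fwe_p.append(p)
        result.directions.append(sign)
    return result


# ---------------------------------------------------------------------------
# behavior associations


def partial_correlation_perm(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    n_perm: int = 20000,
    seed: int | np.random.Generator = 0,
    schedule: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation partial correlation of each column of x with y.

    Both sides are residualized on the covariates (least squares, with
    intercept); the statistic is the Pearson correlation of residuals and
    the null permutes the y-residual vector. Returns (r, p) per column.
    """
    x = np.atleast_2d(np.asarray(x, float))
    if x.shape[0] == 1:
        x = x.T
    y = np.asarray(y, float).ravel()
    n = x.shape[0]
    if y.size != n:
        raise ValidationError("x and y must align on subjects")
    if n < 4:
        raise ValidationError("need at least 4 subjects")
    rx = _residualize(x, covariates)
    ry = _residualize(y.reshape(-1, 1), covariates).ravel()
    sd_x = rx.std(axis=0)
    sd_y = ry.std()
    if sd_y == 0 or (x.shape[1] == 1 and sd_x[0] == 0):
        raise ValidationError("constant residuals: correlation undefined")
    ok = sd_x > 0  # e.g. all-zero WMZ in a spread-free module: r=0, p=1
    safe_sd = np.where(ok, sd_x, 1.0)

    def corr(yv: np.ndarray) -> np.ndarray:
        r = (rx * (yv - yv.mean())[:, None]).mean(axis=0) / (safe_sd * yv.std())
        return np.where(ok, r, 0.0)

    r_obs = corr(ry)
    if schedule is None:
        schedule = permutation_schedule(n, n_perm, seed)
    # ry is residualized with an intercept, so it is centered and its std is
    # permutation-invariant: null correlations reduce to one matrix product
    exceed = np.ones(x.shape[1])
    chunk = 2000
    for lo in range(0, schedule.shape[0], chunk):
        block = schedule[lo:lo + chunk]
        r_null = (ry[block] @ rx) / (n * safe_sd * sd_y)
        r_null[:, ~ok] = 0.0
        exceed += (np.abs(r_null) >= np.abs(r_obs)[None, :] - 1e-12).sum(axis=0)
    p = np.minimum(exceed / (schedule.shape[0] + 1), 1.0)
    return r_obs, p


def behavior_association_suite(
    auc_tables: dict[str, np.ndarray],
    score: np.ndarray,
    covariates: np.ndarray | None = None,
    n_perm: int = 20000,
    q: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Partial correlation of every nodal measure with a behavioral score.

    Shares one permutation schedule across nodes and measures, then applies
    joint BH FDR. Subjects with missing scores must be excluded upstream.
    """
    measures = list(auc_tables)
    stacked = np.hstack([np.asarray(auc_tables[m], float) for m in measures])
    n_nodes = {m: np.asarray(auc_tables[m]).shape[1] for m in measures}
    schedule = permutation_schedule(stacked.shape[0], n_perm, seed)
    r, p = partial_correlation_perm(
        stacked, score, covariates, schedule=schedule
    )
    rows = []
    offset = 0
    for m in measures:
        for node in range(n_nodes[m]):
            rows.append({"node_id": node + 1, "measure": m,
                         "r": r[offset + node], "p": p[offset + node]})
        offset += n_nodes[m]
    out = pd.DataFrame(rows)
    out["q"], out["significant"] = fdr_correct_joint(out["p"].values, q)
    return out


# ---------------------------------------------------------------------------
# demographic tables


def two_sample_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Pooled-variance two-sample t from printed summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs n >= 2")
    t, p = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return float(t), float(p)


def chi_square_2x2(counts: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction, df=1."""
    counts = np.asarray(counts, float)
    if counts.shape != (2, 2):
        raise ValidationError("expect a 2x2 count table")
    chi2, p, _, _ = sps.chi2_contingency(counts, correction=False)
    return float(chi2), float(p)


def demographic_tests(rows: list[dict]) -> pd.DataFrame:
    """Demographic comparison table from per-variable summaries.

    Each row dict is either
      {"variable", "kind": "continuous", "mean1", "sd1", "n1", "mean2", "sd2", "n2"}
    or
      {"variable", "kind": "categorical", "counts": 2x2 array-like}.
    Continuous variables get a pooled two-sample t; categorical a Pearson
    chi-square (df=1, no continuity correction).
    """
    out = []
    for row in rows:
        if row["kind"] == "continuous":
            stat, p = two_sample_t_from_summary(
                row["mean1"], row["sd1"], row["n1"],
                row["mean2"], row["sd2"], row["n2"],
            )
            test = "t"
        elif row["kind"] == "categorical":
            stat, p = chi_square_2x2(np.asarray(row["counts"]))
            test = "chi2"
        else:
            raise ValidationError(f"unknown variable kind {row['kind']!r}")
        out.append({"variable": row["variable"], "test": test,
                    "statistic": stat, "p": p})
    return pd.DataFrame(out)
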