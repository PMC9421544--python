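"""Consensus Louvain modules and connector/provincial hub classification.

Module structure is found by repeated seeded Louvain runs whose run-to-run
co-assignment frequencies form an agreement matrix; thresholding and
re-clustering that matrix until all runs coincide gives a consensus
partition (Lancichinetti-Fortunato consensus clustering). Node roles are
then quantified by the within-module degree z-score (WMZ, intra-modular
strength standardized within the module) and the participation coefficient
(PC, dispersion of strength across modules), plus a null-normalized PC that
corrects PC's mechanical dependence on intra-modular degree. Hubs are
classified by the quadrant rule: WMZ > 1 marks a hub; PC_norm above/below
0.5 splits connector from provincial roles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from restconn.metrics import between_module_rewire, modularity_q
from restconn.types import (
    Partition,
    ThresholdedNetwork,
    ValidationError,
    relabel_contiguous,
)

HUB_WMZ_THRESHOLD = 1.0
HUB_PC_THRESHOLD = 0.5


def _one_louvain_pass(
    adj: np.ndarray, resolution: float, rng: np.random.Generator
) -> np.ndarray:
    """Phase 1 of Louvain: greedy local moves until no gain; returns labels."""
    n = adj.shape[0]
    labels = np.arange(n)
    strengths = adj.sum(axis=1)
    two_w = adj.sum()
    if two_w == 0:
        return labels
    # community aggregates
    comm_strength = strengths.copy().astype(float)
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            ci = labels[i]
            # strength from i to each community (excluding self-loop)
            nbrs = np.nonzero(adj[i])[0]
            w_to = {}
            for j in nbrs:
                if j == i:
                    continue
                w_to[labels[j]] = w_to.get(labels[j], 0.0) + adj[i, j]
            comm_strength[ci] -= strengths[i]
            base = w_to.get(ci, 0.0) - resolution * strengths[i] * comm_strength[ci] / two_w
            best_c, best_gain = ci, 0.0
            for c, w in w_to.items():
                if c == ci:
                    continue
                gain = (w - resolution * strengths[i] * comm_strength[c] / two_w) - base
                if gain > best_gain + 1e-12:
                    best_gain, best_c = gain, c
            labels[i] = best_c
            comm_strength[best_c] += strengths[i]
            if best_c != ci:
                improved = True
    return labels


def _aggregate(adj: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Phase 2 of Louvain: collapse communities into super-nodes.

    Self-loops on the aggregated graph carry the within-community weight.
    """
    comms = np.unique(labels)
    one_hot = (labels[:, None] == comms[None, :]).astype(float)
    return one_hot.T @ adj @ one_hot


def louvain(
    net: ThresholdedNetwork | np.ndarray,
    resolution: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> Partition:
    """Greedy two-phase Louvain maximizing weighted modularity Q.

    Node sweep order is randomized by ``seed``; Q never decreases across
    passes (asserted). Returns the partition with contiguous 1..M labels and
    its modularity.
    """
    adj = net.adjacency if isinstance(net, ThresholdedNetwork) else np.asarray(net, float)
    if adj.size == 0:
        raise ValidationError("cannot cluster an empty graph")
    rng = np.random.default_rng(seed)
    n = adj.shape[0]
    node_labels = np.arange(n)
    level_adj = adj.copy()
    np.fill_diagonal(level_adj, 0.0)
    wrapper = ThresholdedNetwork(level_adj.copy(), density=1.0, mode="weighted")
    prev_q = -np.inf
    # self-loops accumulate within-community weight between levels
    for _ in range(100):
        labels = _one_louvain_pass(level_adj, resolution, rng)
        labels = relabel_contiguous(labels) - 1
        node_labels = labels[node_labels]
        q = modularity_q(wrapper, node_labels + 1, resolution)
        assert q >= prev_q - 1e-9, "Louvain pass decreased Q"
        if q <= prev_q + 1e-12:
            break
        prev_q = q
        level_adj = _aggregate(level_adj, labels)
    final = relabel_contiguous(node_labels)
    return Partition(final, q=modularity_q(wrapper, final, resolution))


def agreement_matrix(partitions: list[np.ndarray]) -> np.ndarray:
    """N x N co-assignment frequency over runs; diagonal 1."""
    n = partitions[0].size
    agree = np.zeros((n, n))
    for labels in partitions:
        agree += labels[:, None] == labels[None, :]
    agree /= len(partitions)
    np.fill_diagonal(agree, 1.0)
    return agree


def consensus_partition(
    net: ThresholdedNetwork,
    n_runs: int = 1000,
    tau: float = 0.5,
    resolution: float = 1.0,
    seed: int | np.random.Generator = 0,
    max_consensus_iter: int = 50,
) -> tuple[Partition, np.ndarray]:
    """Consensus clustering over repeated stochastic Louvain runs.

    Runs Louvain ``n_runs`` times, builds the co-assignment agreement
    matrix, zeroes entries below ``tau`` and re-clusters the agreement
    matrix, iterating until every run returns the same partition. Returns
    that partition (with Q measured on the original network) and the first
    agreement matrix.
    """
    if n_runs < 1:
        raise ValidationError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    mat = net.adjacency
    first_agreement = None
    for _ in range(max_consensus_iter):
        runs = [louvain(mat, resolution, rng).labels for _ in range(n_runs)]
        all_same = all(np.array_equal(runs[0], r) for r in runs[1:])
        agree = agreement_matrix(runs)
        if first_agreement is None:
            first_agreement = agree
        if all_same:
            labels = relabel_contiguous(runs[0])
            return Partition(labels, q=modularity_q(net, labels)), first_agreement
        thresholded = np.where(agree >= tau, agree, 0.0)
        np.fill_diagonal(thresholded, 0.0)
        if thresholded.sum() == 0:
            # below-tau everywhere: runs share no structure; keep best run
            best = max(runs, key=lambda r: modularity_q(net, relabel_contiguous(r)))
            labels = relabel_contiguous(best)
            return Partition(labels, q=modularity_q(net, labels)), first_agreement
        mat = thresholded
    raise ValidationError(
        f"consensus did not converge within {max_consensus_iter} iterations"
    )


def within_module_strength(
    net: ThresholdedNetwork, partition: Partition
) -> np.ndarray:
    """Each node's summed edge weight to nodes of its own module."""
    labels = partition.labels
    same = labels[:, None] == labels[None, :]
    return (net.adjacency * same).sum(axis=1)


def within_module_zscore(
    net: ThresholdedNetwork, partition: Partition
) -> np.ndarray:
    """WMZ: within-module strength standardized within each module.

    Standardization uses the sample standard deviation (ddof=1, the
    convention of the standard toolbox routine); modules with zero spread
    (including singletons) get WMZ = 0.
    """
    if partition.n_nodes != net.n_nodes:
        raise ValidationError("partition does not cover all nodes")
    k_within = within_module_strength(net, partition)
    wmz = np.zeros(net.n_nodes)
    for s in range(1, partition.n_modules + 1):
        idx = partition.labels == s
        if idx.sum() < 2:
            continue
        sd = k_within[idx].std(ddof=1)
        if sd > 0:
            wmz[idx] = (k_within[idx] - k_within[idx].mean()) / sd
    return wmz


def participation_coefficient(
    net: ThresholdedNetwork, partition: Partition
) -> np.ndarray:
    """PC_i = 1 - sum_s (k_is / k_i)^2 over modules s (strengths k).

    0 for nodes whose edges all stay within their own module (and for
    isolated nodes); approaches 1 - 1/M for a perfectly even spread.
    """
    if partition.n_nodes != net.n_nodes:
        raise ValidationError("partition does not cover all nodes")
    labels = partition.labels
    strength = net.strengths()
    pc = np.zeros(net.n_nodes)
    ok = strength > 0
    ratio_sq = np.zeros(net.n_nodes)
    for s in range(1, partition.n_modules + 1):
        k_is = net.adjacency[:, labels == s].sum(axis=1)
        ratio_sq[ok] += (k_is[ok] / strength[ok]) ** 2
    pc[ok] = 1.0 - ratio_sq[ok]
    return pc


def normalized_participation_coefficient(
    net: ThresholdedNetwork,
    partition: Partition,
    n_null: int = 1000,
    iterations_per_edge: int = 20,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """PC normalized against between-module-randomized null networks.

    Raw PC is mechanically depressed for nodes with a large share of
    intra-modular edges, so differences in PC can reflect within-module
    degree rather than genuine inter-modular dispersion. This routine
    randomizes the between-module edges ``n_null`` times (degree-preserving
    swaps restricted so every node's within-module neighborhood stays
    fixed; see :func:`restconn.metrics.between_module_rewire`), computes
    each node's null PC distribution under the same partition, and removes
    the node-specific mechanical offset while keeping the network-wide
    scale:

        pc_norm_i = clip(pc_i - median_b pc_null_i(b) + M_null, 0, 1)

    where M_null is the grand median of the null PCs. Because a node's
    own-module strength is identical in every null, the (k_own / k)^2 term
    cancels in pc_i - median_b, leaving only the evenness of the node's
    between-module allocation relative to chance. Deterministic under
    ``seed``. If the network admits no between-module rewiring, raw PC is
    returned with a warning flag on the network.
    """
    if n_null < 1:
        raise ValidationError("n_null must be >= 1")
    rng = np.random.default_rng(seed)
    pc = participation_coefficient(net, partition)
    pc_null = np.empty((n_null, net.n_nodes))
    any_rewired = False
    for b in range(n_null):
        null = between_module_rewire(net, partition.labels, iterations_per_edge, rng)
        if not null.flags.get("rewire_fallback"):
            any_rewired = True
        pc_null[b] = participation_coefficient(null, partition)
    if not any_rewired:
        net.flags["pc_norm_fallback"] = True
        return pc
    node_median = np.median(pc_null, axis=0)
    grand_median = float(np.median(pc_null))
    return np.clip(pc - node_median + grand_median, 0.0, 1.0)


def classify_hubs(
    wmz: np.ndarray,
    pc_norm: np.ndarray,
    partition: Partition | None = None,
    pc: np.ndarray | None = None,
) -> pd.DataFrame:
    """Quadrant rule for node roles.

    connector hub: WMZ > 1 and PC_norm > 0.5; provincial hub: WMZ > 1 and
    PC_norm < 0.5; the same PC_norm split names the non-hub quadrants.
    Inequalities are strict: boundary values fall to non-hub / provincial.
    """
    wmz = np.asarray(wmz, float)
    pc_norm = np.asarray(pc_norm, float)
    if wmz.shape != pc_norm.shape:
        raise ValidationError("wmz and pc_norm must align")
    is_hub = wmz > HUB_WMZ_THRESHOLD
    is_connector = pc_norm > HUB_PC_THRESHOLD
    role = np.where(
        is_hub,
        np.where(is_connector, "connector hub", "provincial hub"),
        np.where(is_connector, "connector non-hub", "provincial non-hub"),
    )
    out = pd.DataFrame(
        {
            "node_id": np.arange(1, wmz.size + 1),
            "wmz": wmz,
            "pc_norm": pc_norm,
            "role": role,
        }
    )
    if pc is not None:
        out.insert(2, "pc", np.asarray(pc, float))
    if partition is not None:
        out["module"] = partition.labels
    return out


def module_summary(
    partition: Partition,
    hub_table: pd.DataFrame,
    parcel_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-module report: node count, hub counts and hemisphere-grouped lists.

    ``parcel_table`` (node_id, label, hemisphere, functional_network)
    supplies 1-based atlas ids and hemispheres; hub lists are rendered as
    e.g. "L 1,6,62 R 290,322". Without a parcel table nodes are listed by
    their 1-based index.
    """
    if "module" not in hub_table.columns:
        hub_table = hub_table.assign(module=partition.labels)
    if parcel_table is not None:
        hemi = parcel_table.set_index("node_id")["hemisphere"]
    else:
        hemi = pd.Series("", index=hub_table["node_id"].values)

    def _fmt(nodes: pd.Series) -> str:
        parts = []
        for h in ("L", "R", ""):
            ids = [str(n) for n in nodes if hemi.get(n, "") == h]
            if ids:
                parts.append((h + " " if h else "") + ",".join(ids))
        return " ".join(parts)

    rows = []
    for s in range(1, partition.n_modules + 1):
        mod = hub_table[hub_table["module"] == s]
        connectors = mod.loc[mod["role"] == "connector hub", "node_id"]
        provincials = mod.loc[mod["role"] == "provincial hub", "node_id"]
        rows.append(
            {
                "module": s,
                "n_nodes": int((partition.labels == s).sum()),
                "n_connector_hubs": int(connectors.size),
                "n_provincial_hubs": int(provincials.size),
                "connector_hubs": _fmt(connectors),
                "provincial_hubs": _fmt(provincials),
            }
        )
    return pd.DataFrame(rows)
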