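"""End-to-end driver: time series -> FC -> metrics -> hubs -> statistics.

Stages run in a fixed order and every stochastic stage draws from a named
substream of the single top-level seed (see :func:`restconn.io.substream`),
so reruns are bit-reproducible and stage results do not depend on subject
ordering.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from restconn import community, connectome, metrics, stats
from restconn.io import PipelineConfig, substream, write_matrix, write_table
from restconn.synthetic import SyntheticCohort
from restconn.types import (
    ConnectivityMatrix,
    Partition,
    ThresholdedNetwork,
    TimeSeriesMatrix,
    ValidationError,
)

log = logging.getLogger("restconn")


@dataclass
class PipelineResult:
    """In-memory output tree of one full pipeline run."""

    config: PipelineConfig
    fc: list[ConnectivityMatrix]
    densities: np.ndarray
    auc_tables: dict[str, np.ndarray]  # measure -> (n_subjects, n_nodes)
    nodal_stats: pd.DataFrame
    nbs_result: stats.NBSResult
    behavior_stats: pd.DataFrame | None
    group_partitions: dict[str, Partition]
    hub_tables: dict[str, pd.DataFrame]
    module_summaries: dict[str, pd.DataFrame]
    global_metric_tables: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)


def subject_fc(subjects: list[TimeSeriesMatrix]) -> list[ConnectivityMatrix]:
    return [connectome.compute_fc(ts) for ts in subjects]


def nodal_measures_for_subject(
    cm: ConnectivityMatrix,
    densities: np.ndarray,
    config: PipelineConfig,
    seed: int,
    subject_key: str,
    fixed_partition: Partition | None = None,
) -> dict[str, np.ndarray]:
    """Per-density nodal WMZ/PC/PC_norm curves summarized to AUC.

    With ``config.partition_mode == "subject"`` each density gets the
    subject's own consensus partition; with ``"group"`` the supplied fixed
    partition is used throughout (cheaper, and appropriate when a shared
    group partition is the unit of interpretation).
    """
    curves = {m: np.zeros((densities.size, cm.n_nodes)) for m in ("wmz", "pc", "pc_norm")}
    for di, density in enumerate(densities):
        net = connectome.proportional_threshold(cm, float(density), config.mode)
        if fixed_partition is not None and config.partition_mode == "group":
            part = fixed_partition
        else:
            part, _ = community.consensus_partition(
                net,
                n_runs=config.louvain_runs,
                tau=config.tau,
                resolution=config.resolution,
                seed=substream(seed, "partition", subject_key, di),
            )
        curves["wmz"][di] = community.within_module_zscore(net, part)
        curves["pc"][di] = community.participation_coefficient(net, part)
        curves["pc_norm"][di] = community.normalized_participation_coefficient(
            net, part, n_null=config.pcnorm_nulls,
            iterations_per_edge=config.rewire_iterations,
            seed=substream(seed, "pcnorm", subject_key, di),
        )
    return {
        m: np.array([
            stats.auc_over_densities(densities, curves[m][:, node])
            for node in range(cm.n_nodes)
        ])
        for m in curves
    }


def nodal_auc_with_fixed_partition(
    fc: list[ConnectivityMatrix],
    densities: np.ndarray,
    partition: Partition,
    measures: tuple[str, ...] = ("pc", "wmz"),
    mode: str = "weighted",
) -> dict[str, np.ndarray]:
    """Per-subject nodal AUC tables under one shared module partition.

    The fast path for group-partition analyses and replicate simulations:
    no per-subject community detection and no PC-normalization nulls.
    Returns measure -> (n_subjects, n_nodes) AUC arrays.
    """
    n_nodes = fc[0].n_nodes
    out = {m: np.zeros((len(fc), n_nodes)) for m in measures}
    for i, cm in enumerate(fc):
        curves = {m: np.zeros((len(densities), n_nodes)) for m in measures}
        for di, density in enumerate(densities):
            net = connectome.proportional_threshold(cm, float(density), mode)
            if "pc" in measures:
                curves["pc"][di] = community.participation_coefficient(net, partition)
            if "wmz" in measures:
                curves["wmz"][di] = community.within_module_zscore(net, partition)
        for m in measures:
            out[m][i] = np.trapezoid(curves[m], np.asarray(densities), axis=0)
    return out


def group_hub_analysis(
    fc_by_group: dict[str, list[ConnectivityMatrix]],
    config: PipelineConfig,
    seed: int,
    parcel_table: pd.DataFrame | None = None,
) -> tuple[dict[str, Partition], dict[str, pd.DataFrame], dict[str, pd.DataFrame]]:
    """Group-averaged 10%-density hub detection per group."""
    partitions, hub_tables, summaries = {}, {}, {}
    for group in sorted(fc_by_group):
        net = connectome.group_average_fc(
            fc_by_group[group], density=config.group_density, mode=config.mode
        )
        part, _ = community.consensus_partition(
            net, n_runs=config.louvain_runs, tau=config.tau,
            resolution=config.resolution,
            seed=substream(seed, "group-partition", group),
        )
        wmz = community.within_module_zscore(net, part)
        pc = community.participation_coefficient(net, part)
        pc_norm = community.normalized_participation_coefficient(
            net, part, n_null=config.pcnorm_nulls,
            iterations_per_edge=config.rewire_iterations,
            seed=substream(seed, "group-pcnorm", group),
        )
        hubs = community.classify_hubs(wmz, pc_norm, part, pc=pc)
        partitions[group] = part
        hub_tables[group] = hubs
        summaries[group] = community.module_summary(part, hubs, parcel_table)
        log.info("group %s: %d modules, %d nodes, %d edges", group,
                 part.n_modules, net.n_nodes, net.n_edges)
    return partitions, hub_tables, summaries


def run_pipeline(
    cohort: SyntheticCohort | list[TimeSeriesMatrix],
    config: PipelineConfig | None = None,
    parcel_table: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
    design: pd.DataFrame | None = None,
) -> PipelineResult:
    """Execute connectome -> hubs -> nodal statistics on a cohort.

    ``cohort`` is either a :class:`SyntheticCohort` or a plain subject list
    (then ``design`` must be given). Order-invariant in subject ordering:
    every subject's stochastic work is seeded by its subject id, and group
    statistics use design-table alignment. Writes the output tree (TSV +
    provenance sidecar) when ``out_dir`` is given.
    """
    config = config or PipelineConfig()
    seed = config.seed
    if isinstance(cohort, SyntheticCohort):
        subjects, design = cohort.subjects, cohort.design
    else:
        subjects = cohort
        if design is None:
            raise ValidationError("design table required with a plain subject list")
    # canonicalize subject order so results are invariant to input ordering
    design = design.reset_index(drop=True)
    order = np.argsort(design["subject_id"].to_numpy(), kind="stable")
    design = design.iloc[order].reset_index(drop=True)
    subjects = [subjects[i] for i in order]
    densities = connectome.density_grid(
        config.density_start, config.density_stop, config.density_step
    )

    log.info("stage connectome: %d subjects, %d parcels",
             len(subjects), subjects[0].n_parcels)
    fc = subject_fc(subjects)

    fc_by_group: dict[str, list[ConnectivityMatrix]] = {}
    for cm, grp in zip(fc, design["group"]):
        fc_by_group.setdefault(grp, []).append(cm)
    group_partitions, hub_tables, summaries = group_hub_analysis(
        fc_by_group, config, seed, parcel_table
    )

    # fixed partition for "group" mode: consensus on the all-subject average
    pooled_net = connectome.group_average_fc(
        fc, density=config.group_density, mode=config.mode
    )
    pooled_partition, _ = community.consensus_partition(
        pooled_net, n_runs=config.louvain_runs, tau=config.tau,
        resolution=config.resolution, seed=substream(seed, "pooled-partition"),
    )

    log.info("stage nodal measures: %d densities, partition_mode=%s",
             densities.size, config.partition_mode)
    n_nodes = fc[0].n_nodes
    auc_tables = {m: np.zeros((len(fc), n_nodes)) for m in ("wmz", "pc", "pc_norm")}
    for cm, subject_id in zip(fc, design["subject_id"]):
        row = design.index[design["subject_id"] == subject_id][0]
        measures = nodal_measures_for_subject(
            cm, densities, config, seed, subject_id, fixed_partition=pooled_partition
        )
        for m in measures:
            auc_tables[m][row] = measures[m]

    global_table = None
    if config.compute_global_metrics:
        rows = []
        for cm, subject_id in zip(fc, design["subject_id"]):
            for density in densities:
                net = connectome.proportional_threshold(cm, float(density), config.mode)
                gm = metrics.global_metrics(
                    net, n_null=config.sw_nulls,
                    iterations_per_edge=config.rewire_iterations,
                    seed=substream(seed, "sw", subject_id, float(density)),
                )
                rows.append({"subject_id": subject_id, "density": density,
                             **gm.as_dict()})
        global_table = pd.DataFrame(rows)

    log.info("stage statistics: %d permutations nodal, %d NBS",
             config.nodal_perms, config.nbs_perms)
    groups = design["group"].to_numpy()
    ages = design["age"].to_numpy()
    nodal = stats.nodal_test_suite(
        auc_tables, groups, covariates=ages, n_perm=config.nodal_perms,
        q=config.alpha, seed=substream(seed, "nodal-perms"),
    )
    z_stack = np.stack([connectome.fisher_z(cm).values for cm in fc])
    nbs_result = stats.nbs(
        z_stack, groups, covariates=ages, t_init=config.t_init,
        n_perm=config.nbs_perms, seed=substream(seed, "nbs-perms"),
    )

    behavior = None
    if "score" in design.columns:
        have_score = design["score"].notna().to_numpy()
        covs = np.column_stack([
            ages[have_score],
            (groups[have_score] == sorted(set(groups))[0]).astype(float),
        ])
        behavior = stats.behavior_association_suite(
            {m: auc_tables[m][have_score] for m in auc_tables},
            design.loc[have_score, "score"].to_numpy(),
            covariates=covs, n_perm=config.behavior_perms, q=config.alpha,
            seed=substream(seed, "behavior-perms"),
        )

    result = PipelineResult(
        config=config, fc=fc, densities=densities, auc_tables=auc_tables,
        nodal_stats=nodal, nbs_result=nbs_result, behavior_stats=behavior,
        group_partitions=group_partitions, hub_tables=hub_tables,
        module_summaries=summaries, global_metric_tables=global_table,
        provenance={"config_hash": config.config_hash(), "seed": seed,
                    "n_subjects": len(fc), "n_nodes": n_nodes,
                    "version": "0.1.0"},
    )
    if out_dir is not None:
        write_output_tree(result, design, Path(out_dir))
    return result


def write_output_tree(result: PipelineResult, design: pd.DataFrame, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    (out / "fc").mkdir(exist_ok=True)
    for cm, subject_id in zip(result.fc, design["subject_id"]):
        write_matrix(out / "fc" / f"{subject_id}_fc.tsv", cm.values, cm.parcel_labels)
    for m, table in result.auc_tables.items():
        df = pd.DataFrame(table, columns=[f"node_{i + 1}" for i in range(table.shape[1])])
        df.insert(0, "subject_id", design["subject_id"])
        write_table(out / f"auc_{m}.tsv", df)
    write_table(out / "nodal_stats.tsv", result.nodal_stats)
    if result.behavior_stats is not None:
        write_table(out / "behavior_stats.tsv", result.behavior_stats)
    for group, hubs in result.hub_tables.items():
        write_table(out / f"hubs_{group}.tsv", hubs)
        write_table(out / f"module_summary_{group}.tsv", result.module_summaries[group])
        part = result.group_partitions[group]
        write_table(out / f"partition_{group}.tsv", pd.DataFrame(
            {"node_id": np.arange(1, part.n_nodes + 1), "module": part.labels}
        ))
    if result.global_metric_tables is not None:
        write_table(out / "global_metrics.tsv", result.global_metric_tables)
    nbs_rows = [
        {"component": i + 1, "size": s, "fwe_p": p, "direction": d,
         "edges": ";".join(f"{a + 1}-{b + 1}" for a, b in comp)}
        for i, (comp, s, p, d) in enumerate(zip(
            result.nbs_result.components, result.nbs_result.sizes,
            result.nbs_result.fwe_p, result.nbs_result.directions))
    ]
    write_table(out / "nbs_components.tsv", pd.DataFrame(
        nbs_rows, columns=["component", "size", "fwe_p", "direction", "edges"]
    ))
    (out / "provenance.json").write_text(json.dumps(result.provenance, indent=2))
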