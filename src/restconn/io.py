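"""Delimited-text I/O, configuration and seed derivation.

All artifacts are tab-separated text: square matrices carry parcel labels
as header row and index column; tables are plain TSV; configuration is
YAML and round-trips losslessly. Matrices are written at full float
precision (repr-exact round-trip).
"""

from __future__ import annotations

import hashlib
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from restconn.types import ValidationError


# ---------------------------------------------------------------------------
# matrices


def write_matrix(path: str | Path, values: np.ndarray, labels: list[str] | None = None) -> None:
    """Write a square matrix as TSV with label header row/column."""
    values = np.asarray(values, float)
    n = values.shape[0]
    if values.ndim != 2 or values.shape[1] != n:
        raise ValidationError("write_matrix expects a square matrix")
    if labels is None:
        labels = [f"parcel_{i + 1}" for i in range(n)]
    df = pd.DataFrame(values, index=labels, columns=labels)
    df.to_csv(path, sep="\t", float_format="%.17g", index_label="parcel")


def read_matrix(
    path: str | Path, require_symmetric: bool = True
) -> tuple[np.ndarray, list[str]]:
    """Read a labeled square TSV matrix; validates shape and symmetry.

    Errors carry the offending line number where possible.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    except (pd.errors.ParserError, ValueError) as err:
        raise ValidationError(f"{path}: malformed matrix file ({err})") from err
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        for line, row in enumerate(df.itertuples(index=False), start=2):
            if any(not isinstance(v, (int, float)) for v in row):
                raise ValidationError(f"{path}:{line}: non-numeric cell")
        raise ValidationError(f"{path}: non-numeric cells")
    n = values.shape[0]
    if values.shape[1] != n:
        raise ValidationError(f"{path}: matrix is {values.shape[0]}x{values.shape[1]}, not square")
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValidationError(f"{path}: row and column labels differ")
    if require_symmetric:
        asym = np.abs(values - values.T)
        if asym.max(initial=0.0) > 1e-9:
            i, j = np.unravel_index(np.argmax(asym), asym.shape)
            raise ValidationError(
                f"{path}:{i + 2}: asymmetry {asym[i, j]:.3g} at ({df.index[i]}, {df.columns[j]})"
            )
    return values, list(df.columns.astype(str))


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# parcel tables


def default_parcel_table(n_nodes: int) -> pd.DataFrame:
    """Placeholder atlas: 1-based ids, alternating hemispheres."""
    return pd.DataFrame(
        {
            "node_id": np.arange(1, n_nodes + 1),
            "label": [f"parcel_{i + 1}" for i in range(n_nodes)],
            "hemisphere": ["L" if i < n_nodes // 2 else "R" for i in range(n_nodes)],
            "functional_network": ["unassigned"] * n_nodes,
        }
    )


def validate_parcel_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"node_id", "label", "hemisphere", "functional_network"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"parcel table missing columns: {sorted(missing)}")
    ids = table["node_id"].to_numpy()
    if not np.array_equal(np.sort(ids), np.arange(1, ids.size + 1)):
        raise ValidationError("parcel node_ids must be unique and contiguous from 1")
    if not table["hemisphere"].isin(["L", "R"]).all():
        raise ValidationError("hemisphere must be L or R")
    return table


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters with study defaults."""

    density_start: float = 0.10
    density_stop: float = 0.40
    density_step: float = 0.01
    mode: str = "weighted"
    group_density: float = 0.10
    sw_nulls: int = 100
    rewire_iterations: int = 20
    pcnorm_nulls: int = 1000
    louvain_runs: int = 1000
    tau: float = 0.5
    resolution: float = 1.0
    nodal_perms: int = 20000
    nbs_perms: int = 10000
    behavior_perms: int = 20000
    t_init: float = 3.9856
    alpha: float = 0.05
    partition_mode: str = "subject"  # or "group"
    compute_global_metrics: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.sw_nulls, self.rewire_iterations, self.pcnorm_nulls,
            self.louvain_runs, self.nodal_perms, self.nbs_perms,
            self.behavior_perms,
        )
        if any(c < 1 for c in counts):
            raise ValidationError("all counts must be positive")
        for b in (self.density_start, self.density_stop, self.density_step,
                  self.group_density):
            if not (0 < b <= 1):
                raise ValidationError("density bounds must lie in (0, 1]")
        if self.partition_mode not in ("subject", "group"):
            raise ValidationError("partition_mode must be 'subject' or 'group'")

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        """Load from a YAML file path or a YAML text blob."""
        text = str(source)
        try:
            if Path(text).exists():
                text = Path(text).read_text()
        except OSError:  # not a pathname (e.g. raw YAML text)
            pass
        data = yaml.safe_load(text) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        """Stable digest of the full parameter set (changes iff any does)."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# seed substreams


def substream(seed: int, *names) -> np.random.SeedSequence:
    """Named, reproducible child stream of the top-level seed.

    Derivation: SeedSequence([seed, crc32(name) for each name part]). Every
    stochastic stage draws from its own named substream so stages can be
    re-run in isolation with identical results.
    """
    keys = [int(seed)] + [zlib.crc32(str(n).encode()) for n in names]
    return np.random.SeedSequence(keys)
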