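"""Readers and writers for the on-disk formats.

Everything tabular is TSV (tab-separated, header row, UTF-8, "." decimal);
trees are newick; reports and run configuration are JSON. Readers validate
eagerly and raise :class:`FormatError` naming the offending row or column.
Floats are written with 12 significant digits so that write-then-read
round-trips preserve values well beyond 10 significant digits.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .trees import SpeciesTree

logger = logging.getLogger("phylotx")

__all__ = [
    "FormatError",
    "ExpressionDataset",
    "RunConfig",
    "read_phyletic_matrix",
    "write_phyletic_matrix",
    "read_membership",
    "write_membership",
    "read_expression",
    "write_expression",
]

FLOAT_FMT = "%.12g"


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


# ---------------------------------------------------------------------------
# Expression data


@dataclass
class ExpressionDataset:
    """A genes x samples tpm matrix with timepoint/replicate metadata.

    ``values`` is a DataFrame indexed by gene id with one column per
    sample; ``meta`` is indexed by sample id with columns ``timepoint``
    (hours, non-negative) and ``replicate`` (small integer). Samples are
    kept ordered by (replicate, timepoint).
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dupes[:5]}")
        if self.meta.index.has_duplicates:
            dupes = self.meta.index[self.meta.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dupes[:5]}")
        missing = [s for s in self.values.columns if s not in self.meta.index]
        if missing:
            raise FormatError(f"samples missing from metadata: {missing[:5]}")
        if (self.meta["timepoint"] < 0).any():
            raise FormatError("negative timepoint in metadata")
        neg = self.values.lt(0)
        if neg.any().any():
            gene = self.values.index[neg.any(axis=1)][0]
            raise FormatError(f"negative tpm value at gene {gene!r}")
        order = self.meta.loc[list(self.values.columns)].sort_values(
            ["replicate", "timepoint"], kind="stable"
        )
        dup_tp = order.duplicated(subset=["replicate", "timepoint"])
        if dup_tp.any():
            raise FormatError(
                f"duplicate (replicate, timepoint) for sample {order.index[dup_tp][0]!r}"
            )
        self.meta = order
        self.values = self.values[order.index]

    # -- convenience accessors ---------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def replicates(self) -> list:
        return sorted(self.meta["replicate"].unique().tolist())

    def timepoints(self, replicate=None) -> np.ndarray:
        m = self.meta if replicate is None else self.meta[self.meta["replicate"] == replicate]
        return np.sort(m["timepoint"].unique())

    def replicate_matrix(self, replicate) -> pd.DataFrame:
        """Genes x timepoints matrix for one replicate, columns = hours."""
        m = self.meta[self.meta["replicate"] == replicate].sort_values("timepoint")
        sub = self.values[m.index]
        sub.columns = m["timepoint"].to_numpy()
        return sub

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionDataset":
        return ExpressionDataset(self.values.loc[list(gene_ids)].copy(), self.meta.copy())


def read_expression(matrix_path, metadata_path) -> ExpressionDataset:
    """Read a gene x sample tpm TSV plus a sample metadata TSV.

    The metadata must have columns sample_id, timepoint, replicate and
    cover every sample column of the matrix.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t")
    required = {"sample_id", "timepoint", "replicate"}
    if not required <= set(meta.columns):
        raise FormatError(
            f"metadata must have columns {sorted(required)}, got {list(meta.columns)}"
        )
    meta = meta.set_index("sample_id")
    if not np.issubdtype(values.to_numpy().dtype, np.number):
        bad = [c for c in values.columns if values[c].dtype == object]
        raise FormatError(f"non-numeric expression column(s): {bad[:5]}")
    return ExpressionDataset(values=values, meta=meta[["timepoint", "replicate"]])


def write_expression(data: ExpressionDataset, matrix_path, metadata_path) -> None:
    data.values.to_csv(matrix_path, sep="\t", index_label="gene_id", float_format=FLOAT_FMT)
    data.meta.to_csv(metadata_path, sep="\t", index_label="sample_id", float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# Phyletic presence/absence matrix


def read_phyletic_matrix(path, tree: SpeciesTree) -> pd.DataFrame:
    """Read a binary orthogroup x species TSV, validated against the tree.

    Every species column must be a tree leaf; every orthogroup must be
    present (1) in the focal species, since orthogroups are anchored on
    the focal proteome.
    """
    mat = pd.read_csv(path, sep="\t", index_col=0)
    return validate_phyletic_matrix(mat, tree)


def validate_phyletic_matrix(mat: pd.DataFrame, tree: SpeciesTree) -> pd.DataFrame:
    unknown = [s for s in mat.columns if s not in tree.leaf_names]
    if unknown:
        raise FormatError(f"species column(s) not in tree: {unknown}")
    if mat.index.has_duplicates:
        dupes = mat.index[mat.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate orthogroup ids: {dupes[:5]}")
    arr = mat.to_numpy()
    if not np.isin(arr, (0, 1)).all():
        i, j = np.argwhere(~np.isin(arr, (0, 1)))[0]
        raise FormatError(
            f"non-binary cell at orthogroup {mat.index[i]!r}, species {mat.columns[j]!r}"
        )
    if tree.focal not in mat.columns:
        raise FormatError(f"focal species column {tree.focal!r} missing")
    absent_focal = mat.index[mat[tree.focal] == 0].tolist()
    if absent_focal:
        raise FormatError(
            f"orthogroup(s) absent from the focal species: {absent_focal[:5]}"
        )
    missing_species = [s for s in tree.leaf_names if s not in mat.columns]
    if missing_species:
        logger.warning(
            "species in tree but absent from phyletic matrix (treated as "
            "all-absent): %s", missing_species,
        )
    return mat.astype(int)


def write_phyletic_matrix(mat: pd.DataFrame, path) -> None:
    mat.to_csv(path, sep="\t", index_label="orthogroup_id")


# ---------------------------------------------------------------------------
# Gene -> orthogroup membership


def read_membership(path, matrix: Optional[pd.DataFrame] = None) -> pd.Series:
    """Read the gene -> orthogroup table for the focal species.

    An empty orthogroup cell means the gene has no ortholog anywhere
    (it will be classified focal-specific). Returns a Series indexed by
    gene id with orthogroup id or NA.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "orthogroup_id"} <= set(df.columns):
        raise FormatError(
            f"membership table needs columns gene_id, orthogroup_id; got {list(df.columns)}"
        )
    if df["gene_id"].duplicated().any():
        dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise FormatError(f"duplicate gene ids in membership: {dupes[:5]}")
    member = df.set_index("gene_id")["orthogroup_id"]
    member = member.replace("", pd.NA)
    if matrix is not None:
        unknown = member.dropna()[~member.dropna().isin(matrix.index)]
        if len(unknown):
            raise FormatError(
                f"gene(s) mapped to unknown orthogroup: {unknown.head().to_dict()}"
            )
    return member


def write_membership(member: pd.Series, path) -> None:
    member.rename("orthogroup_id").to_csv(path, sep="\t", index_label="gene_id", na_rep="")


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Configuration shared by the pipeline stages.

    Defaults reproduce the analysis conditions: strict mean-tpm < 0.5
    low-expression filter, k-means consensus over k in 5..15 with 20
    seeds and consensus threshold 0.7, 1000 permutations for the
    hourglass test, and an early/mid/late split of 2/4/4 timepoints.
    """

    filter_threshold: float = 0.5
    k_grid: tuple = tuple(range(5, 16))
    n_base_runs: int = 20
    consensus_tau: float = 0.7
    min_cluster_size: int = 10
    n_permutations: int = 1000
    rng_seed: int = 0
    phase_counts: tuple = (2, 4, 4)
    replicate_shift_hours: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.consensus_tau <= 1:
            raise ValueError("consensus_tau must be in (0, 1]")
        if self.filter_threshold < 0:
            raise ValueError("filter_threshold must be >= 0")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be positive")
        if len(self.phase_counts) != 3 or any(c < 1 for c in self.phase_counts):
            raise ValueError("phase_counts must be three positive integers")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        raw["k_grid"] = tuple(raw.get("k_grid", cls.k_grid))
        raw["phase_counts"] = tuple(raw.get("phase_counts", cls.phase_counts))
        return cls(**raw)
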