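"""Dollo-parsimony gene-age (phylostratum) assignment.

Under Dollo parsimony a gene family is gained exactly once and may be
lost any number of times. For a presence/absence pattern that includes
the focal species, the unique most-parsimonious gain node is then the
last common ancestor of all species carrying the gene: placing the gain
any deeper adds losses, placing it shallower cannot cover all carriers.

Strata are numbered 1 (oldest, gain at the root: pan-eukaryotic origin)
through S (youngest, focal-species-specific). Genes with no orthogroup
at all are focal-specific by definition and get stratum S.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .trees import SpeciesTree, TreeError
from .io import FormatError

__all__ = [
    "infer_dollo_gain_node",
    "assign_orthogroup_strata",
    "assign_ages",
    "stratum_composition",
]


def infer_dollo_gain_node(present: Iterable[str], tree: SpeciesTree) -> int:
    """Most-parsimonious single-gain node for a presence pattern.

    Parameters
    ----------
    present
        Species names carrying the gene; must include the focal species.

    Returns
    -------
    int
        Stratum rank (1-based) of the gain node on the root-to-focal
        chain. The MRCA of a focal-containing set always lies on that
        chain.
    """
    present = set(present)
    if not present:
        raise TreeError("empty presence set")
    return tree.mrca_stratum(present)


def assign_orthogroup_strata(matrix: pd.DataFrame, tree: SpeciesTree) -> pd.Series:
    """Stratum rank for every orthogroup of a phyletic matrix.

    Vectorized over orthogroups: the gain stratum is the deepest node of
    the root-to-focal chain whose descendant leaf set covers all species
    carrying the orthogroup.
    """
    species = list(matrix.columns)
    S = tree.n_strata
    # covers[r, j]: is species j under stratum node r+1?
    covers = np.array(
        [[sp in tree.stratum_leafset(r) for sp in species] for r in range(1, S + 1)]
    )
    pres = matrix.to_numpy(dtype=np.int32)
    # violation[g, r]: some carrier of g lies outside stratum node r+1
    violation = (pres @ (~covers.T).astype(np.int32)) > 0
    deepest = np.where(~violation, np.arange(1, S + 1)[None, :], 0).max(axis=1)
    return pd.Series(deepest, index=matrix.index, name="stratum")


def assign_ages(
    matrix: pd.DataFrame, membership: pd.Series, tree: SpeciesTree
) -> pd.DataFrame:
    """Build the per-gene age table.

    Parameters
    ----------
    matrix
        Validated phyletic matrix (orthogroups x species).
    membership
        gene_id -> orthogroup_id (NA for genes with no ortholog
        anywhere, which are classified focal-specific, stratum S).

    Returns
    -------
    DataFrame indexed by gene_id with columns ``orthogroup_id``,
    ``stratum`` and ``gain_node_label``.
    """
    known = membership.dropna()
    unknown = known[~known.isin(matrix.index)]
    if len(unknown):
        raise FormatError(
            f"gene(s) mapped to orthogroup(s) absent from the phyletic matrix: "
            f"{unknown.head().to_dict()}"
        )
    og_strata = assign_orthogroup_strata(matrix, tree)
    S = tree.n_strata
    strata = membership.map(og_strata).astype("float").fillna(S).astype(int)
    labels = strata.map(lambda r: tree.stratum_label(int(r)))
    return pd.DataFrame(
        {
            "orthogroup_id": membership,
            "stratum": strata,
            "gain_node_label": labels,
        },
        index=membership.index.rename("gene_id"),
    )


def stratum_composition(ages: pd.DataFrame) -> pd.DataFrame:
    """Counts and fractions of genes per stratum.

    Returns a DataFrame indexed by stratum with columns ``count`` and
    ``fraction``; fractions sum to 1.
    """
    if len(ages) == 0:
        raise ValueError("empty age table")
    counts = ages["stratum"].value_counts().sort_index()
    return pd.DataFrame(
        {"count": counts, "fraction": counts / counts.sum()}
    ).rename_axis("stratum")


def write_age_table(ages: pd.DataFrame, path, youngest_is_one: bool = False) -> None:
    """Write the gene-age TSV.

    ``youngest_is_one`` flips the numbering so stratum 1 is the
    focal-specific (youngest) class, the convention used by some
    deposited tables; the default keeps 1 = oldest.
    """
    out = ages.copy()
    if youngest_is_one:
        S = int(ages["stratum"].max())
        out["stratum"] = S + 1 - out["stratum"]
    out.to_csv(path, sep="\t", index_label="gene_id", na_rep="")


def read_age_table(path) -> pd.DataFrame:
    ages = pd.read_csv(path, sep="\t", index_col="gene_id", dtype={"stratum": int})
    if "stratum" not in ages.columns:
        raise FormatError("age table needs a 'stratum' column")
    return ages
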