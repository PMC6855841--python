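"""Rooted species trees with a designated focal leaf.

The chain of ancestors from the root down to the focal leaf defines the
ranked phylostrata: rank 1 is the root (oldest, pan-eukaryotic origin) and
rank S is the focal leaf itself (focal-species-specific). A gene whose
orthogroup first appeared on the branch leading to stratum node r is
assigned age r.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy

__all__ = ["SpeciesTree", "read_species_tree", "TreeError"]


class TreeError(ValueError):
    """Raised for malformed trees or focal-leaf problems."""


@dataclass
class SpeciesTree:
    """A rooted species tree plus the root-to-focal stratum chain.

    Parameters
    ----------
    tree
        A rooted dendropy tree. The root must be bifurcating (a basal
        polytomy is taken as the signature of an unrooted tree and
        rejected; internal multifurcations elsewhere are fine).
    focal
        Taxon label of the focal species; must be a leaf.
    """

    tree: dendropy.Tree
    focal: str
    stratum_nodes: list = field(init=False, repr=False)
    leaf_names: list = field(init=False, repr=False)
    _stratum_leafsets: list = field(init=False, repr=False)

    def __post_init__(self) -> None:
        leaves = [lf.taxon.label for lf in self.tree.leaf_node_iter()]
        if len(set(leaves)) != len(leaves):
            dupes = sorted({x for x in leaves if leaves.count(x) > 1})
            raise TreeError(f"duplicate leaf labels: {dupes}")
        if self.focal not in leaves:
            raise TreeError(
                f"focal species {self.focal!r} is not a leaf of the tree; "
                f"available leaves: {sorted(leaves)}"
            )
        root = self.tree.seed_node
        if len(root.child_nodes()) > 2:
            raise TreeError(
                "tree root is a polytomy, which indicates an unrooted tree; "
                "provide a rooted (bifurcating-root) newick"
            )
        self.leaf_names = leaves
        focal_leaf = next(
            lf for lf in self.tree.leaf_node_iter() if lf.taxon.label == self.focal
        )
        # root -> ... -> focal leaf; the leaf itself is the youngest stratum
        chain = [focal_leaf]
        node = focal_leaf.parent_node
        while node is not None:
            chain.append(node)
            node = node.parent_node
        self.stratum_nodes = chain[::-1]
        self._stratum_leafsets = [
            frozenset(lf.taxon.label for lf in n.leaf_iter())
            for n in self.stratum_nodes
        ]

    @property
    def n_strata(self) -> int:
        return len(self.stratum_nodes)

    def stratum_label(self, rank: int) -> str:
        """Human-readable label for a stratum node (1-based rank)."""
        node = self.stratum_nodes[rank - 1]
        if node.is_leaf():
            return "focal-specific"
        if node.label:
            return node.label
        return f"node_rank{rank}"

    def stratum_leafset(self, rank: int) -> frozenset:
        """Leaves descending from the stratum node of the given rank."""
        return self._stratum_leafsets[rank - 1]

    def mrca_stratum(self, present: Iterable[str]) -> int:
        """Stratum rank of the MRCA of a focal-containing species set.

        The MRCA of any set containing the focal leaf lies on the
        root-to-focal chain, so it is identified as the deepest stratum
        node whose descendant leaf set still covers ``present``.
        """
        present = frozenset(present)
        if self.focal not in present:
            raise TreeError("presence set must contain the focal species")
        unknown = present - frozenset(self.leaf_names)
        if unknown:
            raise TreeError(f"species not in tree: {sorted(unknown)}")
        rank = 1
        for r in range(len(self.stratum_nodes), 0, -1):
            if present <= self._stratum_leafsets[r - 1]:
                rank = r
                break
        return rank

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def read_species_tree(path: str, focal_name: str) -> SpeciesTree:
    """Read a rooted newick species tree and set the focal leaf.

    Raises
    ------
    TreeError
        If the focal name is not a leaf (the message lists available
        leaves) or the tree has a basal polytomy (treated as unrooted).
    """
    tree = dendropy.Tree.get(path=path, schema="newick")
    return SpeciesTree(tree=tree, focal=focal_name)


def species_tree_from_string(newick: str, focal_name: str) -> SpeciesTree:
    """Build a :class:`SpeciesTree` from a newick string (convenience)."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    return SpeciesTree(tree=tree, focal=focal_name)
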