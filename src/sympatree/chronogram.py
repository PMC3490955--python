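"""Dated ultrametric trees (chronograms).

A chronogram is a rooted tree whose branch lengths are in units of absolute
time (here Myr), with all extant tips at the present (age 0) and every node
carrying an age, i.e. its time before present.  All downstream statistics --
branching times, age-range correlation node ages, clade crown ages -- are read
off these node ages, so ultrametricity is validated once, on construction.
"""
from __future__ import annotations

from typing import Iterable, Sequence

import dendropy

__all__ = ["Chronogram", "UltrametricityError"]


class UltrametricityError(ValueError):
    """Raised when root-to-tip path lengths disagree beyond tolerance."""


class Chronogram:
    """Rooted tree with node ages in Myr before present.

    Parameters
    ----------
    tree:
        A rooted ``dendropy.Tree`` with branch lengths in Myr.
    tol:
        Relative ultrametricity tolerance: the spread of root-to-tip depths
        may not exceed ``tol`` times the maximum depth.
    """

    def __init__(self, tree: dendropy.Tree, tol: float = 1e-6):
        tree.is_rooted = True
        self._tree = tree
        self.tol = float(tol)
        self._assign_ages()

    # ------------------------------------------------------------------
    # construction helpers
    # ------------------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str, tol: float = 1e-6) -> "Chronogram":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls(tree, tol=tol)

    @classmethod
    def from_path(cls, path: str, tol: float = 1e-6) -> "Chronogram":
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
        return cls(tree, tol=tol)

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    # ------------------------------------------------------------------
    def _assign_ages(self) -> None:
        root = self._tree.seed_node
        root.depth = 0.0
        for nd in self._tree.preorder_node_iter():
            if nd is root:
                continue
            nd.depth = nd.parent_node.depth + (nd.edge.length or 0.0)
        leaves = self._tree.leaf_nodes()
        if not leaves:
            raise ValueError("tree has no tips")
        depths = [lf.depth for lf in leaves]
        tmax = max(depths)
        if tmax <= 0:
            raise ValueError("tree has zero total depth (no branch lengths?)")
        worst = max(leaves, key=lambda lf: tmax - lf.depth)
        if (tmax - worst.depth) > self.tol * tmax:
            raise UltrametricityError(
                f"tree is not ultrametric: tip {worst.taxon.label!r} lies "
                f"{tmax - worst.depth:.6g} Myr above the present "
                f"(max depth {tmax:.6g}, tolerance {self.tol:g} relative)"
            )
        for nd in self._tree.preorder_node_iter():
            nd.age = 0.0 if nd.is_leaf() else max(tmax - nd.depth, 0.0)
        labels = [lf.taxon.label for lf in leaves]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate tip labels in tree")
        self._tip_labels = labels

    # ------------------------------------------------------------------
    # basic accessors
    # ------------------------------------------------------------------
    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        return list(self._tip_labels)

    @property
    def n_tips(self) -> int:
        return len(self._tip_labels)

    @property
    def crown_age(self) -> float:
        return self._tree.seed_node.age

    def internal_nodes(self, exclude_root: bool = False) -> list:
        out = [
            nd
            for nd in self._tree.preorder_node_iter()
            if not nd.is_leaf()
        ]
        if exclude_root:
            out = [nd for nd in out if nd.parent_node is not None]
        return out

    def is_binary(self) -> bool:
        return all(
            len(nd.child_nodes()) == 2
            for nd in self._tree.preorder_node_iter()
            if not nd.is_leaf()
        )

    def require_binary(self) -> None:
        for nd in self._tree.preorder_node_iter():
            k = len(nd.child_nodes())
            if k not in (0, 2):
                raise ValueError(
                    f"tree must be strictly bifurcating; found a node with "
                    f"{k} children"
                )

    @staticmethod
    def leaf_labels_under(node) -> list[str]:
        return [lf.taxon.label for lf in node.leaf_iter()]

    def mrca(self, labels: Iterable[str]):
        labels = list(labels)
        missing = set(labels) - set(self._tip_labels)
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")
        return self._tree.mrca(taxon_labels=labels)

    def terminal_branch_length(self, label: str) -> float:
        """Age of the node joining *label* to its sister lineage.

        For an ultrametric tree this equals the tip's terminal branch length
        and is the natural 'age of the species' for area-age regressions.
        """
        for lf in self._tree.leaf_node_iter():
            if lf.taxon.label == label:
                return lf.parent_node.age
        raise KeyError(f"tip {label!r} not in tree")

    def prune_to(self, keep: Sequence[str]) -> "Chronogram":
        """Induced chronogram on a subset of tips (branch lengths summed)."""
        keep = list(keep)
        missing = set(keep) - set(self._tip_labels)
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")
        if len(keep) < 2:
            raise ValueError("need at least 2 tips to keep")
        sub = self._tree.extract_tree_with_taxa_labels(labels=keep)
        return Chronogram(sub, tol=self.tol)

    def drop_tips(self, drop: Sequence[str]) -> "Chronogram":
        keep = [t for t in self._tip_labels if t not in set(drop)]
        return self.prune_to(keep)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<Chronogram {self.n_tips} tips, crown age "
            f"{self.crown_age:.3f} Myr>"
        )
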