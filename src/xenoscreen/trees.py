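"""Unrooted support-annotated trees.

Trees are stored as :class:`dendropy.Tree` objects but are always treated as
unrooted: the quantity of interest is the set of bipartitions (splits) of the
leaf set, each carrying a branch length and, after bootstrapping, an integer
support value in [0, 100].  Supports follow the PHYLIP/CONSENSE convention of
integer labels attached to internal nodes.

A split is represented as a frozenset of leaf labels, normalised to the side
that does *not* contain the lexicographically smallest leaf, so that the two
orientations of the same bipartition compare equal.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import dendropy

from .errors import DataError, FormatError

__all__ = ["Split", "SupportTree"]


@dataclass(frozen=True)
class Split:
    """One bipartition of a tree's leaf set.

    ``side`` is the normalised orientation (see module docstring); ``support``
    is None for unresampled trees.  A split is trivial when one side is a
    single leaf; trivial splits are present in every tree on the same leaf
    set, so they carry no phylogenetic information.
    """

    side: frozenset
    support: Optional[int]
    length: Optional[float]
    trivial: bool


class SupportTree:
    """An unrooted phylogenetic tree with branch lengths and split supports."""

    def __init__(self, tree: dendropy.Tree):
        tree.is_rooted = False
        self.tree = tree

    # ------------------------------------------------------------------ io

    @classmethod
    def from_newick(cls, text: str) -> "SupportTree":
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise FormatError(f"invalid Newick: {exc}") from exc
        st = cls(tree)
        # validate supports eagerly so bad files fail at the boundary
        for node in st._internal_nodes():
            _parse_support(node.label)
        labels = st.leaf_labels()
        if len(labels) != len(set(labels)):
            raise FormatError("duplicate leaf labels in Newick tree")
        return st

    def to_newick(self) -> str:
        """Serialise with branch lengths and internal support labels."""

        def render(node) -> str:
            if node.is_leaf():
                out = node.taxon.label if node.taxon else (node.label or "")
            else:
                inner = ",".join(render(c) for c in node.child_nodes())
                out = f"({inner})" + (node.label or "")
            if node.edge.length is not None and node is not self.tree.seed_node:
                out += f":{node.edge.length:.10g}"
            return out

        return render(self.tree.seed_node) + ";"

    # ------------------------------------------------------------ structure

    def leaf_labels(self) -> list:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def leaf_set(self) -> frozenset:
        return frozenset(self.leaf_labels())

    def _internal_nodes(self):
        for node in self.tree.preorder_node_iter():
            if node is not self.tree.seed_node and not node.is_leaf():
                yield node

    def normalise(self, side: frozenset) -> frozenset:
        """Return the canonical orientation of a split side."""
        leaves = self.leaf_set()
        ref = min(leaves)
        return frozenset(leaves - side) if ref in side else frozenset(side)

    def splits(self, include_trivial: bool = False) -> list:
        """All splits of the unrooted tree, deduplicated.

        A bifurcation at the (arbitrary) seed node produces the same split
        from both child edges; only one copy is returned.
        """
        leaves = self.leaf_set()
        n = len(leaves)
        seen = {}
        for node in self.tree.preorder_node_iter():
            if node is self.tree.seed_node:
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            k = len(side)
            if k == 0 or k == n:
                continue
            trivial = min(k, n - k) == 1
            if trivial and not include_trivial:
                continue
            key = self.normalise(side)
            support = _parse_support(node.label) if not node.is_leaf() else None
            if key in seen:
                prev = seen[key]
                if prev.support is None and support is not None:
                    seen[key] = Split(key, support, node.edge.length, trivial)
            else:
                seen[key] = Split(key, support, node.edge.length, trivial)
        return list(seen.values())

    def split_set(self, include_trivial: bool = False) -> set:
        return {s.side for s in self.splits(include_trivial=include_trivial)}

    def set_split_supports(self, supports: dict) -> None:
        """Attach integer supports (keyed by normalised split) to internal nodes."""
        for node in self._internal_nodes():
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            key = self.normalise(side)
            if key in supports:
                val = int(supports[key])
                if not 0 <= val <= 100:
                    raise DataError(f"support {val} outside [0, 100]")
                node.label = str(val)

    def clone(self) -> "SupportTree":
        return SupportTree(self.tree.clone(depth=1))

    def path_distance_matrix(self, labels: Sequence[str]):
        """Leaf-to-leaf path-length matrix in the order of ``labels``."""
        import numpy as np

        pdm = self.tree.phylogenetic_distance_matrix()
        tax = {t.label: t for t in self.tree.taxon_namespace}
        n = len(labels)
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = pdm.patristic_distance(tax[labels[i]], tax[labels[j]])
                out[i, j] = out[j, i] = d
        return out

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"SupportTree({len(self.leaf_labels())} leaves)"


def _parse_support(label) -> Optional[int]:
    if label is None or label == "":
        return None
    try:
        val = float(label)
    except ValueError:
        raise FormatError(f"internal node label {label!r} is not a support value")
    if val != int(val) or not 0 <= val <= 100:
        raise FormatError(f"support {label!r} outside integer range [0, 100]")
    return int(val)
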