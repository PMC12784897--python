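"""Rooted phylogeny wrapper.

Wraps a :class:`dendropy.Tree` and precomputes the two structures every
phylogenetic metric here consumes:

* an edge table — branch length plus the set of tips below each branch —
  which turns Faith PD and branch-sharing (a, b, c) computations into
  boolean matrix algebra, and
* the patristic (tip-to-tip path length) distance matrix for the
  abundance-weighted pairwise-distance metrics.

Ultrametricity (equal root-to-tip depth) is checked and reported, never
required: metrics are defined for any non-negative branch lengths.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = ["Phylogeny", "TreeError"]


class TreeError(ValueError):
    """The tree violates a structural requirement (e.g. missing branch lengths)."""


class Phylogeny:
    """A rooted tree with non-negative branch lengths over the species pool."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()
        self._build_tables()

    # -- construction -----------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
        return cls(tree)

    @classmethod
    def from_path(cls, path: str) -> "Phylogeny":
        tree = dendropy.Tree.get(path=path, schema="newick",
                                 preserve_underscores=True)
        return cls(tree)

    def _validate(self) -> None:
        root = self._tree.seed_node
        labels = []
        for node in self._tree.preorder_node_iter():
            if node is root:
                continue
            if node.edge.length is None:
                raise TreeError("tree has branches without lengths")
            if node.edge.length < 0:
                raise TreeError("negative branch length")
            if node.is_leaf():
                if node.taxon is None or not node.taxon.label:
                    raise TreeError("unlabeled tip")
                labels.append(node.taxon.label)
        if len(labels) != len(set(labels)):
            raise TreeError("duplicate tip labels")
        if len(labels) < 2:
            raise TreeError("tree must have at least 2 tips")
        if len(root.child_nodes()) > 2:
            warnings.warn(
                "basal polytomy: tree treated as rooted at the polytomy "
                "(arbitrary rooting)", stacklevel=3)

    def _build_tables(self) -> None:
        tips = [lf.taxon.label for lf in self._tree.leaf_node_iter()]
        self._tips = tips
        tip_index = {t: i for i, t in enumerate(tips)}
        self._tip_index = tip_index
        edges = []
        below = []
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            mask = np.zeros(len(tips), dtype=bool)
            for lf in node.leaf_iter():
                mask[tip_index[lf.taxon.label]] = True
            edges.append(float(node.edge.length))
            below.append(mask)
        self.edge_lengths = np.asarray(edges, dtype=float)
        #: boolean (n_edges, n_tips); entry (e, t) — tip t lies below edge e
        self.edge_below = np.vstack(below)
        # root-to-tip depths
        depths = {}
        for node in self._tree.preorder_node_iter():
            parent = node.parent_node
            d = 0.0 if parent is None else depths[parent] + float(node.edge.length)
            depths[node] = d
        self._depths = np.array(
            [depths[lf] for lf in self._tree.leaf_node_iter()], dtype=float)
        # patristic matrix: d(i,j) = depth_i + depth_j - 2 * depth(mrca)
        # computed from the edge table: shared depth = sum of lengths of edges
        # having BOTH tips below.
        both = (self.edge_below.astype(float).T @
                np.diag(self.edge_lengths) @ self.edge_below.astype(float))
        # both[i, j] = total length of edges below which i and j both sit
        self._patristic = self._depths[:, None] + self._depths[None, :] - 2.0 * both
        np.fill_diagonal(self._patristic, 0.0)

    # -- basic properties --------------------------------------------------
    @property
    def tips(self) -> list[str]:
        return list(self._tips)

    @property
    def n_tips(self) -> int:
        return len(self._tips)

    @property
    def total_length(self) -> float:
        return float(self.edge_lengths.sum())

    @property
    def height(self) -> float:
        return float(self._depths.max())

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        h = self.height
        if h == 0:
            return True
        return bool(np.ptp(self._depths) <= rtol * h)

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick").strip()

    def patristic_matrix(self, labels: Sequence[str] | None = None) -> np.ndarray:
        """Pairwise path-length distances, ordered by ``labels`` (default: all tips)."""
        if labels is None:
            return self._patristic.copy()
        idx = self.tip_indices(labels)
        return self._patristic[np.ix_(idx, idx)]

    def tip_indices(self, labels: Iterable[str]) -> np.ndarray:
        try:
            return np.array([self._tip_index[l] for l in labels], dtype=int)
        except KeyError as exc:
            raise TreeError(f"label not in tree: {exc.args[0]!r}") from None

    def prune_to(self, labels: Sequence[str]) -> "Phylogeny":
        """Restrict the tree to ``labels`` (suppressing unifurcations)."""
        keep = set(labels)
        missing = keep - set(self._tips)
        if missing:
            raise TreeError(f"cannot prune to absent tips: {sorted(missing)}")
        tree = self._tree.clone(depth=1)
        taxa = [t for t in tree.taxon_namespace if t.label in keep]
        tree.retain_taxa(taxa)
        return Phylogeny(tree)

    # -- edge-membership queries ------------------------------------------
    def community_edge_mask(self, labels: Iterable[str],
                            include_root: bool = True) -> np.ndarray:
        """Boolean mask over edges spanned by the community.

        With ``include_root`` the spanning subtree runs to the root (every
        edge with at least one community tip below it); otherwise edges
        above the community's MRCA are excluded (an edge must separate
        community tips from each other).
        """
        idx = self.tip_indices(labels)
        if idx.size == 0:
            raise TreeError("empty community")
        sub = self.edge_below[:, idx]
        any_below = sub.any(axis=1)
        if include_root:
            return any_below
        return any_below & ~sub.all(axis=1)
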