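"""Rooted phylogeny wrapper with deterministic internal-node identifiers.

``Phylogeny`` wraps a :class:`dendropy.Tree` and adds the accounting the
rest of the pipeline relies on: unique tip labels, non-negative branch
lengths, stable internal-node ids (existing labels are kept; unlabeled
internal nodes are named ``n<postorder-index>``), patristic distances,
Brownian trait covariance, and foreground-clade counting.
"""

from __future__ import annotations

import io
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd

from .errors import NewickParseError, ValidationError

__all__ = [
    "Phylogeny",
    "parse_newick",
    "count_foreground_clades",
    "validate_distance_matrix",
]


class Phylogeny:
    """A rooted tree with branch lengths in substitutions/site.

    Parameters
    ----------
    tree:
        A rooted :class:`dendropy.Tree`. Tip labels must be unique and every
        non-root branch length must be ``>= 0`` (missing lengths are treated
        as 0).
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._assign_node_ids()
        self._validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                rooting="force-rooted",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error types
            if "Duplicate taxon label" in str(exc):
                raise ValidationError(f"duplicate tip labels: {exc}") from exc
            raise NewickParseError(f"malformed Newick: {exc}") from exc
        return cls(tree)

    def _assign_node_ids(self) -> None:
        for idx, nd in enumerate(self._tree.postorder_node_iter()):
            if nd.is_leaf():
                nd._rs_id = nd.taxon.label if nd.taxon else nd.label
            else:
                nd._rs_id = nd.label if nd.label else f"n{idx}"
                nd.label = nd._rs_id
            if nd.edge.length is None:
                nd.edge.length = 0.0

    def _validate(self) -> None:
        tips = [nd._rs_id for nd in self._tree.leaf_node_iter()]
        if any(t is None for t in tips):
            raise ValidationError("unlabeled tip in tree")
        if len(set(tips)) != len(tips):
            dupes = sorted({t for t in tips if tips.count(t) > 1})
            raise ValidationError(f"duplicate tip labels: {dupes}")
        internal = [nd._rs_id for nd in self._tree.postorder_internal_node_iter()]
        if len(set(internal)) != len(internal):
            raise ValidationError("duplicate internal node ids")
        for nd in self._tree.postorder_node_iter():
            if nd.parent_node is not None and nd.edge.length < 0:
                raise ValidationError(
                    f"negative branch length {nd.edge.length} above node {nd._rs_id}"
                )

    # -- basic accessors ----------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        return [nd._rs_id for nd in self._tree.leaf_node_iter()]

    @property
    def internal_ids(self) -> list[str]:
        return [nd._rs_id for nd in self._tree.postorder_internal_node_iter()]

    @property
    def root_id(self) -> str:
        return self._tree.seed_node._rs_id

    def node(self, node_id: str) -> dendropy.Node:
        for nd in self._tree.postorder_node_iter():
            if nd._rs_id == node_id:
                return nd
        raise KeyError(node_id)

    def __len__(self) -> int:
        return len(self.tip_labels)

    # -- serialization ------------------------------------------------

    def to_newick(self) -> str:
        out = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".12g",
        )
        return out.strip() + "\n"

    # -- geometry -----------------------------------------------------

    def terminal_branch_lengths(self) -> pd.Series:
        """Length of the pendant edge above each tip."""
        data = {nd._rs_id: float(nd.edge.length) for nd in self._tree.leaf_node_iter()}
        return pd.Series(data, name="branch_length")

    def node_depths(self) -> dict[str, float]:
        """Root-to-node path length for every node (root depth 0)."""
        depths: dict[str, float] = {}
        for nd in self._tree.preorder_node_iter():
            if nd.parent_node is None:
                depths[nd._rs_id] = 0.0
            else:
                depths[nd._rs_id] = depths[nd.parent_node._rs_id] + float(nd.edge.length)
        return depths

    def tips_below(self, node_id: str) -> list[str]:
        return [lf._rs_id for lf in self.node(node_id).leaf_iter()]

    def patristic_distances(self) -> pd.DataFrame:
        """Symmetric tip-to-tip path-length matrix (zero diagonal)."""
        tips = self.tip_labels
        depths = self.node_depths()
        idx = {t: i for i, t in enumerate(tips)}
        n = len(tips)
        mrca_depth = np.zeros((n, n))
        # postorder accumulation: for each internal node, tip pairs whose
        # MRCA is exactly this node are pairs drawn from distinct children
        below: dict[int, list[int]] = {}
        for nd in self._tree.postorder_node_iter():
            if nd.is_leaf():
                below[id(nd)] = [idx[nd._rs_id]]
                continue
            kids = [below[id(ch)] for ch in nd.child_nodes()]
            d = depths[nd._rs_id]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for i in kids[a]:
                        mrca_depth[i, kids[b]] = d
                        mrca_depth[np.asarray(kids[b]), i] = d
            below[id(nd)] = [i for k in kids for i in k]
        tip_depth = np.array([depths[t] for t in tips])
        dist = tip_depth[:, None] + tip_depth[None, :] - 2.0 * mrca_depth
        np.fill_diagonal(dist, 0.0)
        return pd.DataFrame(dist, index=tips, columns=tips)

    def brownian_covariance(self) -> pd.DataFrame:
        """Brownian-motion trait covariance: C_ij = depth of MRCA(i, j)."""
        tips = self.tip_labels
        depths = self.node_depths()
        d = self.patristic_distances().to_numpy()
        tip_depth = np.array([depths[t] for t in tips])
        c = (tip_depth[:, None] + tip_depth[None, :] - d) / 2.0
        return pd.DataFrame(c, index=tips, columns=tips)


def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a validated :class:`Phylogeny`."""
    return Phylogeny.from_newick(text)


def count_foreground_clades(
    tree: Phylogeny,
    traits: Mapping[str, str],
    cls: str,
    exclude: Iterable[str] = (),
) -> int:
    """Number of maximal monophyletic clades whose tips are all of ``cls``.

    ``exclude`` drops tips (e.g. an outgroup) from the purity accounting
    entirely, so trait-change events are counted within the remaining taxa.
    """
    excluded = set(exclude)
    missing = [t for t in tree.tip_labels if t not in traits and t not in excluded]
    if missing:
        raise ValidationError(f"tips without trait class: {missing}")

    n_clades = 0
    pure: dict[int, bool | None] = {}  # None = no included tips below
    for nd in tree.dendropy_tree.postorder_node_iter():
        if nd.is_leaf():
            if nd._rs_id in excluded:
                pure[id(nd)] = None
            else:
                pure[id(nd)] = traits[nd._rs_id] == cls
        else:
            states = [pure[id(ch)] for ch in nd.child_nodes()]
            informative = [s for s in states if s is not None]
            if not informative:
                pure[id(nd)] = None
            else:
                pure[id(nd)] = all(informative)
    for nd in tree.dendropy_tree.postorder_node_iter():
        if pure[id(nd)]:
            parent = nd.parent_node
            if parent is None or not pure[id(parent)]:
                n_clades += 1
    return n_clades


def validate_distance_matrix(d: pd.DataFrame, tol: float = 1e-9) -> None:
    """Check symmetry, non-negativity and a zero diagonal."""
    if list(d.index) != list(d.columns):
        raise ValidationError("distance matrix index/columns differ")
    a = d.to_numpy(dtype=float)
    if not np.allclose(a, a.T, atol=tol):
        raise ValidationError("distance matrix is not symmetric")
    if (a < -tol).any():
        raise ValidationError("negative distances present")
    if not np.allclose(np.diag(a), 0.0, atol=tol):
        raise ValidationError("nonzero diagonal in distance matrix")
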