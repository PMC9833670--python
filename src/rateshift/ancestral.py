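"""Ancestral sequence reconstruction and tip-to-ancestor identity.

Two reconstructions are provided. Fitch parsimony operates on state
*sets* (bitmasks over {A,C,G,T}); tips with a gap or N at a column
contribute the full state set, and internal columns left ambiguous
(non-singleton sets) are excluded from identity comparisons. Marginal
maximum likelihood under Jukes-Cantor uses the whole tree and the branch
lengths and assigns an argmax state to essentially every column.

The identity stage defaults to the ML reconstruction. Bottom-up
parsimony sets only see the subtree below a node, and at shallow nodes
(two or three descendant tips) the ambiguous columns it must exclude are
exactly the columns carrying those tips' substitutions — the exclusion
is correlated with the quantity being measured, which erases and can
even invert the longevity signal there. The ML reconstruction has no
such exclusion artifact. Fitch remains available (``method="fitch"``)
because its state sets admit an exact brute-force oracle.

Percent identity of a tip to an ancestral node is the fraction of columns
where the node state is unambiguous, the tip base is a real nucleotide,
and the two agree. The per-node longevity ratio compares the mean
percent *difference* (1 - identity) of long-lived descendants to that of
short-lived descendants: values below 1 mean long-lived lineages sit
closer to the reconstructed ancestor, i.e. evolve more slowly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import Alignment, GAP
from .errors import UndefinedValueError, ValidationError
from .traits import TraitMap
from .tree import Phylogeny

__all__ = [
    "AncestralStates",
    "fitch_reconstruct",
    "ml_reconstruct",
    "reconstruct",
    "percent_identity",
    "identity_table",
    "node_ratio_table",
]

FULL_SET = np.uint8(0b1111)  # {A,C,G,T}
_POPCOUNT = np.array([bin(i).count("1") for i in range(16)], dtype=np.uint8)


@dataclass
class AncestralStates:
    """Per-node state-set bitmasks (bit i set = base i possible)."""

    node_masks: dict[str, np.ndarray]  # node id -> (n_columns,) uint8
    parsimony_score: int | None = None  # total Fitch score (fitch only)
    method: str = "fitch"

    def masks(self, node_id: str) -> np.ndarray:
        return self.node_masks[node_id]


def _tip_masks(aln: Alignment, label: str) -> np.ndarray:
    codes = aln.row(label)
    masks = np.where(codes < GAP, np.left_shift(1, codes, dtype=np.uint8), FULL_SET)
    return masks.astype(np.uint8)


def _check_tips(tree: Phylogeny, aln: Alignment) -> None:
    missing = [t for t in tree.tip_labels if t not in aln]
    if missing:
        raise ValidationError(f"tips missing from alignment: {missing}")


def fitch_reconstruct(tree: Phylogeny, aln: Alignment) -> AncestralStates:
    """Bottom-up Fitch pass: intersection of child sets when non-empty,
    union (and a parsimony-score increment) otherwise."""
    _check_tips(tree, aln)
    node_masks: dict[str, np.ndarray] = {}
    work: dict[int, np.ndarray] = {}
    score = np.zeros(aln.n_columns, dtype=np.int64)
    for nd in tree.dendropy_tree.postorder_node_iter():
        if nd.is_leaf():
            work[id(nd)] = _tip_masks(aln, nd._rs_id)
            continue
        children = [work[id(ch)] for ch in nd.child_nodes()]
        acc = children[0]
        for ch in children[1:]:
            inter = acc & ch
            union = acc | ch
            empty = inter == 0
            score += empty
            acc = np.where(empty, union, inter).astype(np.uint8)
        work[id(nd)] = acc
        node_masks[nd._rs_id] = acc
    return AncestralStates(node_masks, parsimony_score=int(score.sum()), method="fitch")


# -- ML (Jukes-Cantor) marginal reconstruction ------------------------


def _jc_transition(t: float) -> np.ndarray:
    e = np.exp(-4.0 * t / 3.0)
    p_same = 0.25 + 0.75 * e
    p_diff = 0.25 - 0.25 * e
    p = np.full((4, 4), p_diff)
    np.fill_diagonal(p, p_same)
    return p


def ml_reconstruct(tree: Phylogeny, aln: Alignment, tol: float = 1e-9) -> AncestralStates:
    """Marginal ML states under Jukes-Cantor with the tree's branch
    lengths; the state set holds every base within ``tol`` of the maximum
    posterior."""
    _check_tips(tree, aln)
    ncol = aln.n_columns
    below: dict[int, np.ndarray] = {}
    trans: dict[int, np.ndarray] = {}
    for nd in tree.dendropy_tree.postorder_node_iter():
        if nd.parent_node is not None:
            trans[id(nd)] = _jc_transition(float(nd.edge.length))
        if nd.is_leaf():
            masks = _tip_masks(aln, nd._rs_id)
            lik = ((masks[:, None] >> np.arange(4)) & 1).astype(float)
            below[id(nd)] = lik
        else:
            lik = np.ones((ncol, 4))
            for ch in nd.child_nodes():
                lik *= below[id(ch)] @ trans[id(ch)].T
            norm = lik.sum(axis=1, keepdims=True)
            below[id(nd)] = lik / np.where(norm > 0, norm, 1.0)

    above: dict[int, np.ndarray] = {}
    node_masks: dict[str, np.ndarray] = {}
    for nd in tree.dendropy_tree.preorder_node_iter():
        if nd.parent_node is None:
            above[id(nd)] = np.full((ncol, 4), 0.25)
        else:
            parent = nd.parent_node
            msg = above[id(parent)].copy()
            for sib in parent.child_nodes():
                if sib is nd:
                    continue
                msg *= below[id(sib)] @ trans[id(sib)].T
            msg = msg @ trans[id(nd)]
            norm = msg.sum(axis=1, keepdims=True)
            above[id(nd)] = msg / np.where(norm > 0, norm, 1.0)
        if not nd.is_leaf():
            post = above[id(nd)] * below[id(nd)]
            top = post.max(axis=1, keepdims=True)
            sets = post >= top - tol
            mask = (sets * (1 << np.arange(4))).sum(axis=1).astype(np.uint8)
            node_masks[nd._rs_id] = mask
    return AncestralStates(node_masks, parsimony_score=None, method="ml")


def reconstruct(tree: Phylogeny, aln: Alignment, method: str = "ml") -> AncestralStates:
    if method == "fitch":
        return fitch_reconstruct(tree, aln)
    if method == "ml":
        return ml_reconstruct(tree, aln)
    raise ValueError(f"unknown reconstruction method {method!r}")


# -- identity ---------------------------------------------------------


def percent_identity(tip_codes: np.ndarray, node_masks: np.ndarray) -> tuple[float, int]:
    """Fraction of comparable columns (unambiguous node state, real tip
    base) where tip and ancestor agree; returns (identity, n_compared)."""
    if tip_codes.shape != node_masks.shape:
        raise ValidationError("tip and node column counts differ")
    singleton = _POPCOUNT[node_masks] == 1
    comparable = singleton & (tip_codes < GAP)
    n = int(comparable.sum())
    if n == 0:
        raise UndefinedValueError("no comparable columns for identity")
    tip_mask = np.left_shift(1, tip_codes.astype(np.int32) % 4).astype(np.uint8)
    matches = int((comparable & (tip_mask == node_masks)).sum())
    return matches / n, n


def identity_table(
    tree: Phylogeny, aln: Alignment, states: AncestralStates
) -> pd.DataFrame:
    """Identity of every tip to every node ancestral to it.

    Columns: tip, node, identity, n_compared. Pairs with no comparable
    columns are omitted.
    """
    rows = []
    for leaf in tree.dendropy_tree.leaf_node_iter():
        codes = aln.row(leaf._rs_id)
        nd = leaf.parent_node
        while nd is not None:
            try:
                ident, n = percent_identity(codes, states.masks(nd._rs_id))
                rows.append(
                    {
                        "tip": leaf._rs_id,
                        "node": nd._rs_id,
                        "identity": ident,
                        "n_compared": n,
                    }
                )
            except UndefinedValueError:
                pass
            nd = nd.parent_node
    return pd.DataFrame(rows, columns=["tip", "node", "identity", "n_compared"])


def node_ratio_table(
    ids: pd.DataFrame, traits: TraitMap, tree: Phylogeny
) -> pd.DataFrame:
    """Per-node LONG/SHORT divergence ratio.

    For each internal node with at least one descendant tip of each class,
    computes the ratio of the mean percent difference (1 - identity) of
    long-lived descendants to that of short-lived descendants. Ratios
    below 1 indicate slower evolution (higher ancestral identity) in
    long-lived lineages. Nodes where either group mean difference is zero
    are omitted (undefined ratio).
    """
    out = []
    by_node = ids.groupby("node")
    for node_id, sub in by_node:
        sub = sub[sub["tip"].isin(traits.classes)]
        ll = sub[sub["tip"].map(traits.classes.get) == "LONG"]
        sl = sub[sub["tip"].map(traits.classes.get) == "SHORT"]
        if ll.empty or sl.empty:
            continue
        ll_id = float(ll["identity"].mean())
        sl_id = float(sl["identity"].mean())
        ll_diff = 1.0 - ll_id
        sl_diff = 1.0 - sl_id
        if ll_diff <= 0 or sl_diff <= 0:
            continue
        out.append(
            {
                "node": node_id,
                "n_long": len(ll),
                "n_short": len(sl),
                "mean_identity_long": ll_id,
                "mean_identity_short": sl_id,
                "ratio": ll_diff / sl_diff,
            }
        )
    df = pd.DataFrame(
        out,
        columns=[
            "node",
            "n_long",
            "n_short",
            "mean_identity_long",
            "mean_identity_short",
            "ratio",
        ],
    )
    return df
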