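"""Pairwise distances and least-squares branch lengths on a fixed topology.

Gene trees in this pipeline keep the species-tree topology; only branch
lengths are re-estimated per gene, from Jukes-Cantor corrected pairwise
distances, by non-negativity-constrained least squares (NNLS on the
edge/path incidence system, so negative estimates are clamped by the
active-set solver rather than post hoc).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .alignment import Alignment, GAP, N
from .errors import InsufficientDataError, UndefinedValueError
from .tree import Phylogeny

__all__ = ["JCDistance", "jc_distance", "jc_distance_matrix", "ls_branch_lengths"]

SATURATION = 0.75  # JC correction undefined at p_hat >= 3/4


@dataclass(frozen=True)
class JCDistance:
    distance: float  # nan when saturated
    p_hat: float
    n_compared: int


def _pair_stats(a: np.ndarray, b: np.ndarray) -> tuple[int, int]:
    usable = (a < GAP) & (b < GAP)
    n = int(usable.sum())
    diff = int(((a != b) & usable).sum())
    return diff, n


def jc_distance(a, b) -> JCDistance:
    """Jukes-Cantor corrected distance between two aligned sequences.

    Gap/N columns are pairwise-deleted. Saturated pairs (p_hat >= 0.75)
    return a NaN distance; zero comparable columns raise.
    """
    a = _as_codes(a)
    b = _as_codes(b)
    if a.shape != b.shape:
        raise UndefinedValueError("sequences differ in length")
    diff, n = _pair_stats(a, b)
    if n == 0:
        raise UndefinedValueError("no comparable (ungapped, non-N) columns")
    p = diff / n
    if p >= SATURATION:
        return JCDistance(float("nan"), p, n)
    d = -0.75 * np.log1p(-(4.0 / 3.0) * p)
    return JCDistance(float(d), p, n)


def _as_codes(seq) -> np.ndarray:
    if isinstance(seq, np.ndarray):
        return seq
    return Alignment.from_dict({"x": str(seq)}).codes[0]


def jc_distance_matrix(aln: Alignment) -> pd.DataFrame:
    """All-pairs JC matrix; saturated / incomparable pairs become NaN."""
    labs = aln.labels
    n = len(labs)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = jc_distance(aln.codes[i], aln.codes[j]).distance
            except UndefinedValueError:
                d = float("nan")
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=labs, columns=labs)


def ls_branch_lengths(
    topology: Phylogeny, d: pd.DataFrame
) -> tuple[Phylogeny, float]:
    """Fit non-negative branch lengths on a fixed topology to a distance
    matrix by least squares.

    Pairs with NaN distances are dropped. Returns the refitted tree and
    the residual sum of squares (0 iff the matrix is additive on the
    topology, up to numerical noise).
    """
    tips = [t for t in topology.tip_labels if t in d.index]
    fitted = Phylogeny(dendropy.Tree(topology.dendropy_tree))

    # edge columns: every node with a parent, keyed by child-node id.
    # With a bifurcating root only the SUM of the two root-child edges is
    # identifiable from tip-tip distances, so they share one column and
    # the fitted sum is split in proportion to the input topology's
    # lengths afterwards.
    nodes = [nd for nd in fitted.dendropy_tree.postorder_node_iter() if nd.parent_node]
    root_children = fitted.dendropy_tree.seed_node.child_nodes()
    merged_root = root_children if len(root_children) == 2 else []
    col: dict[str, int] = {}
    k = 0
    for nd in nodes:
        if merged_root:
            other = merged_root[1] if nd is merged_root[0] else merged_root[0]
            if nd in merged_root and other._rs_id in col:
                col[nd._rs_id] = col[other._rs_id]
                continue
        col[nd._rs_id] = k
        k += 1
    n_cols = k
    orig_len = {nd._rs_id: float(nd.edge.length) for nd in nodes}

    # tip membership below each edge
    below: dict[str, frozenset[str]] = {}
    for nd in fitted.dendropy_tree.postorder_node_iter():
        if nd.is_leaf():
            below[nd._rs_id] = frozenset([nd._rs_id])
        else:
            below[nd._rs_id] = frozenset().union(
                *(below[ch._rs_id] for ch in nd.child_nodes())
            )

    rows, targets, used_taxa = [], [], set()
    for i, ti in enumerate(tips):
        for tj in tips[i + 1 :]:
            dij = float(d.loc[ti, tj])
            if not np.isfinite(dij):
                continue
            row = np.zeros(n_cols)
            for nd in nodes:
                members = below[nd._rs_id]
                if (ti in members) != (tj in members):
                    row[col[nd._rs_id]] = 1.0
            rows.append(row)
            targets.append(dij)
            used_taxa.update((ti, tj))
    if len(used_taxa) < 3:
        raise InsufficientDataError(
            f"only {len(used_taxa)} taxa with usable distances (need >= 3)"
        )

    a = np.vstack(rows)
    y = np.asarray(targets)
    x, rnorm = nnls(a, y)
    for nd in nodes:
        nd.edge.length = float(x[col[nd._rs_id]])
    if merged_root:
        l1 = orig_len[merged_root[0]._rs_id]
        l2 = orig_len[merged_root[1]._rs_id]
        total = float(x[col[merged_root[0]._rs_id]])
        w = l1 / (l1 + l2) if (l1 + l2) > 0 else 0.5
        merged_root[0].edge.length = total * w
        merged_root[1].edge.length = total * (1.0 - w)
    return fitted, float(rnorm**2)
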