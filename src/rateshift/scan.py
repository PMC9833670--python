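"""Convergent rate-shift scan over gene trees on a shared species topology.

The statistic associates a gene's relative evolutionary rates on terminal
branches with the binary longevity trait. Per terminal branch, the raw
relative rate is the gene branch length divided by the species-tree
branch length; rates are then rank-normalized per branch across genes so
the score depends only on rank order (robust to gene-wise rate scale and
any monotone transform). The gene score is a phylogenetically weighted
two-sample U statistic over all SHORT x LONG tip pairs:

    U = sum_ij w_ij * s(R_short_i, R_long_j) / sum_ij w_ij

with s = 1 when the short-lived tip's rank exceeds the long-lived tip's,
0.5 on ties, 0 otherwise, and w_ij the rank of the patristic distance
between the pair among all cross-class pairs — distant pairs are closer
to phylogenetically independent contrasts and get more weight. U near 1
means acceleration in short-lived (foreground) lineages; near 0 means
foreground constraint. This is a self-contained, TRACCER-like statistic
(rank scoring, distance scaling, no ancestral-state assumption), recorded
as ``STATISTIC_VERSION`` in outputs.

Significance comes from a trait-permutation null that preserves both the
class sizes and the number of maximal foreground clades (trait changes
are clade-level events; ignoring the phylogenetic clustering of the trait
would make the null anti-conservative). The same permutation set is
reused for every gene so gene ranks are comparable and the control-curve
comparison is coherent. Empirical FDR follows the expected-over-observed
hit-count definition and reduces to Benjamini-Hochberg under the uniform
expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import RateshiftError, ValidationError
from .traits import SHORT, TraitMap
from .tree import Phylogeny, count_foreground_clades

__all__ = [
    "STATISTIC_VERSION",
    "gene_tree_table",
    "filter_gene_trees",
    "relative_rates",
    "convergence_score",
    "sample_assignments",
    "scan",
    "control_run",
    "empirical_fdr",
]

STATISTIC_VERSION = "traccer-like-rank-U/1.0"

MIN_LONG = 6
MIN_SHORT = 5
MIN_TOTAL = 12


def gene_tree_table(trees: dict[str, Phylogeny]) -> pd.DataFrame:
    """Collect per-gene terminal branch lengths into a genes x tips table
    (NaN where a tip is absent from a gene)."""
    rows = {g: t.terminal_branch_lengths() for g, t in trees.items()}
    return pd.DataFrame(rows).T.sort_index()


def filter_gene_trees(
    genes: pd.DataFrame,
    traits: TraitMap,
    min_long: int = MIN_LONG,
    min_short: int = MIN_SHORT,
    min_total: int = MIN_TOTAL,
) -> pd.DataFrame:
    """Drop genes represented in too few lineages to be informative:
    keep genes with >= 6 long-lived, >= 5 short-lived and >= 12 total
    tips present."""
    missing = [t for t in genes.columns if t not in traits]
    if missing:
        raise ValidationError(f"tips without trait class: {missing}")
    present = genes.notna()
    is_long = np.array([traits[t] == "LONG" for t in genes.columns])
    n_long = present.to_numpy()[:, is_long].sum(axis=1)
    n_short = present.to_numpy()[:, ~is_long].sum(axis=1)
    keep = (n_long >= min_long) & (n_short >= min_short) & (
        n_long + n_short >= min_total
    )
    return genes.loc[keep]


def relative_rates(genes: pd.DataFrame, species_tree: Phylogeny) -> pd.DataFrame:
    """Rank-normalized relative rates, genes x terminal branches.

    Raw rate = gene branch length / species-tree branch length; each
    branch's rates are converted to average ranks across genes and scaled
    into (0, 1]."""
    ref = species_tree.terminal_branch_lengths()
    cols = [t for t in genes.columns]
    zero = [t for t in cols if ref.get(t, 0.0) <= 0.0]
    if zero:
        raise ValidationError(f"species-tree terminal branch of length 0: {zero}")
    raw = genes / ref.loc[cols]
    ranks = pd.DataFrame(index=genes.index, columns=cols, dtype=float)
    for t in cols:
        col = raw[t]
        ok = col.notna()
        n = int(ok.sum())
        if n:
            ranks.loc[ok, t] = rankdata(col[ok].to_numpy()) / n
    return ranks


def _pair_weights(dist: np.ndarray) -> np.ndarray:
    """Rank-transform cross-class patristic distances (average ranks on
    ties); shape preserved."""
    flat = rankdata(dist.ravel())
    return flat.reshape(dist.shape)


def convergence_score(
    ranks: pd.Series, traits: TraitMap, dist: pd.DataFrame
) -> float:
    """Weighted cross-class pair score U for a single gene."""
    present = ranks.dropna()
    s_tips = [t for t in present.index if traits[t] == SHORT]
    l_tips = [t for t in present.index if traits[t] == "LONG"]
    if not s_tips or not l_tips:
        raise ValidationError("both classes required among present tips")
    w = _pair_weights(dist.loc[s_tips, l_tips].to_numpy())
    rs = present.loc[s_tips].to_numpy()[:, None]
    rl = present.loc[l_tips].to_numpy()[None, :]
    s = (rs > rl) + 0.5 * (rs == rl)
    return float((w * s).sum() / w.sum())


# -- permutation null -------------------------------------------------


def sample_assignments(
    tree: Phylogeny,
    traits: TraitMap,
    n_perm: int,
    seed: int | np.random.Generator,
    clade_tolerance_after: int = 1000,
    max_tries: int = 20000,
) -> np.ndarray:
    """Draw pseudo-trait assignments preserving class sizes and the
    number of maximal foreground (SHORT) clades.

    Returns a boolean matrix (n_perm x n_tips, tree tip order) that is
    True where the pseudo-assignment marks the tip SHORT. Exact clade
    matching is attempted first; after ``clade_tolerance_after``
    rejections per draw the tolerance widens to +-1.
    """
    rng = np.random.default_rng(seed)
    tips = tree.tip_labels
    n_short = len([t for t in tips if traits[t] == SHORT])
    target = count_foreground_clades(tree, traits, SHORT)
    out = np.zeros((n_perm, len(tips)), dtype=bool)
    for k in range(n_perm):
        for attempt in range(max_tries):
            chosen = rng.choice(len(tips), size=n_short, replace=False)
            mask = np.zeros(len(tips), dtype=bool)
            mask[chosen] = True
            cand = {t: (SHORT if mask[i] else "LONG") for i, t in enumerate(tips)}
            count = count_foreground_clades(tree, cand, SHORT)
            tol = 0 if attempt < clade_tolerance_after else 1
            if abs(count - target) <= tol:
                out[k] = mask
                break
        else:
            raise RateshiftError(
                "no clade-count-matched assignment found; relax clade matching"
            )
    return out


def _scores_for_assignments(
    ranks: pd.DataFrame, short_masks: np.ndarray, dist: pd.DataFrame
) -> np.ndarray:
    """U for every (assignment, gene); vectorized per tip-presence
    pattern."""
    tips = list(ranks.columns)
    r = ranks.to_numpy(dtype=float)
    present = ~np.isnan(r)
    d = dist.loc[tips, tips].to_numpy()
    n_assign = short_masks.shape[0]
    out = np.empty((n_assign, r.shape[0]))

    patterns: dict[bytes, list[int]] = {}
    for gi, row in enumerate(present):
        patterns.setdefault(row.tobytes(), []).append(gi)

    for key, gene_idx in patterns.items():
        pat = np.frombuffer(key, dtype=bool)
        pidx = np.flatnonzero(pat)
        sub = r[np.ix_(gene_idx, pidx)]
        for ai in range(n_assign):
            s_idx = pidx[short_masks[ai, pidx]]
            l_idx = pidx[~short_masks[ai, pidx]]
            if len(s_idx) == 0 or len(l_idx) == 0:
                out[ai, gene_idx] = np.nan
                continue
            w = _pair_weights(d[np.ix_(s_idx, l_idx)])
            rs = r[np.ix_(gene_idx, s_idx)]
            rl = r[np.ix_(gene_idx, l_idx)]
            s = (rs[:, :, None] > rl[:, None, :]) + 0.5 * (
                rs[:, :, None] == rl[:, None, :]
            )
            out[ai, gene_idx] = (w[None] * s).sum(axis=(1, 2)) / w.sum()
    return out


def empirical_fdr(pvals: pd.Series | np.ndarray, expected_model="uniform") -> np.ndarray:
    """Empirical FDR: expected hits at each threshold over observed hits,
    capped at 1 and made monotone nondecreasing in p.

    ``expected_model`` is either ``"uniform"`` (expected hits = p * N,
    Benjamini-Hochberg-equivalent) or an array of control p-values whose
    hit counts (rescaled to the observed N) give the expectation.
    """
    p = np.asarray(pd.Series(pvals), dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value vector")
    if (p <= 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    observed = np.arange(1, n + 1, dtype=float)
    # account for ties: at tied p, observed hits = count of p <= that value
    observed = np.searchsorted(sorted_p, sorted_p, side="right").astype(float)
    if isinstance(expected_model, str):
        if expected_model != "uniform":
            raise ValueError(f"unknown expectation model {expected_model!r}")
        expected = sorted_p * n
    else:
        ctrl = np.sort(np.asarray(expected_model, dtype=float))
        counts = np.searchsorted(ctrl, sorted_p, side="right")
        expected = counts * (n / ctrl.size)
    q_sorted = np.minimum(expected / observed, 1.0)
    # monotone in p: running minimum from the largest p downward
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    out = np.empty(n)
    out[order] = q_sorted
    return out


@dataclass
class ScanResult:
    """Per-gene convergence scan output plus the permutation ensemble."""

    genes: pd.DataFrame  # index gene; U, direction, p, q, n_long, n_short
    u_perm: np.ndarray  # (n_perm, n_genes)
    assignments: np.ndarray  # (n_perm, n_tips) SHORT masks
    statistic_version: str = STATISTIC_VERSION


def scan(
    genes: pd.DataFrame,
    traits: TraitMap,
    tree: Phylogeny,
    n_perm: int = 500,
    seed: int | np.random.Generator = 0,
    apply_filters: bool = True,
    fdr_expectation="uniform",
) -> ScanResult:
    """Full per-gene scan: filters, rank rates, U, permutation p, q."""
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    traits.check_against_tree(tree)
    if apply_filters:
        genes = filter_gene_trees(genes, traits)
    if genes.empty:
        raise ValidationError("no genes pass the lineage-count filters")
    genes = genes[tree.tip_labels]
    ranks = relative_rates(genes, tree)
    dist = tree.patristic_distances()

    tips = tree.tip_labels
    obs_mask = np.array([traits[t] == SHORT for t in tips])[None, :]
    u_obs = _scores_for_assignments(ranks, obs_mask, dist)[0]

    rng = np.random.default_rng(seed)
    assignments = sample_assignments(tree, traits, n_perm, rng)
    u_perm = _scores_for_assignments(ranks, assignments, dist)

    dev_obs = np.abs(u_obs - 0.5)
    dev_perm = np.abs(u_perm - 0.5)
    p = (1 + (dev_perm >= dev_obs[None, :]).sum(axis=0)) / (n_perm + 1)
    q = empirical_fdr(p, fdr_expectation)

    present = genes.notna().to_numpy()
    is_long = np.array([traits[t] == "LONG" for t in genes.columns])
    direction = np.where(
        u_obs > 0.5,
        "foreground-accelerated",
        np.where(u_obs < 0.5, "foreground-constrained", "none"),
    )
    table = pd.DataFrame(
        {
            "U": u_obs,
            "direction": direction,
            "p": p,
            "q": q,
            "n_long": present[:, is_long].sum(axis=1),
            "n_short": present[:, ~is_long].sum(axis=1),
        },
        index=genes.index,
    )
    return ScanResult(table, u_perm, assignments)


def control_run(
    genes: pd.DataFrame,
    traits: TraitMap,
    control_traits: TraitMap,
    tree: Phylogeny,
    n_perm: int = 500,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, float, ScanResult, ScanResult]:
    """Run the scan under the experimental and the trait-inverted control
    assignment and compare their cumulative p-value curves.

    Returns (curve table with columns x, F_exp, F_ctrl; maximum vertical
    displacement; experimental ScanResult; control ScanResult).
    """
    rng = np.random.default_rng(seed)
    exp = scan(genes, traits, tree, n_perm=n_perm, seed=rng.integers(2**31))
    ctrl = scan(genes, control_traits, tree, n_perm=n_perm, seed=rng.integers(2**31))
    grid = np.unique(
        np.concatenate([exp.genes["p"].to_numpy(), ctrl.genes["p"].to_numpy(), [1.0]])
    )
    f_exp = np.searchsorted(np.sort(exp.genes["p"]), grid, side="right") / len(exp.genes)
    f_ctrl = np.searchsorted(np.sort(ctrl.genes["p"]), grid, side="right") / len(
        ctrl.genes
    )
    curves = pd.DataFrame({"x": grid, "F_exp": f_exp, "F_ctrl": f_ctrl})
    displacement = float(np.max(np.abs(f_exp - f_ctrl)))
    return curves, displacement, exp, ctrl
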