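"""SUMSTAT gene-set enrichment with a random-set permutation null.

Term scores sum sqrt(-ln p) over member genes; the square root damps
single-gene outliers so a term must carry broad signal to score highly.
The null for a term of size k is the same score on random k-subsets of
the scored gene universe (competitive null, sampling without
replacement); empirical FDR uses the uniform expectation. Annotations can
be used directly or propagated through the term DAG (each gene annotated
to the ancestor closure of its direct terms); propagated terms overlap
heavily, so their q-values are extremely conservative and should be read
as non-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "AnnotationMap",
    "read_annotations",
    "read_term_dag",
    "propagate_annotations",
    "filter_terms",
    "sumstat_score",
    "sumstat_pvalues",
    "build_custom_set",
]

MIN_TERM_SIZE = 3
MAX_TERM_SIZE = 100


@dataclass
class AnnotationMap:
    """gene -> set of term ids, with a direct/propagated mode flag."""

    gene_terms: dict[str, set[str]]
    mode: str = "direct"

    def __post_init__(self):
        if self.mode not in ("direct", "propagated"):
            raise ValidationError(f"unknown annotation mode {self.mode!r}")
        self.gene_terms = {g: set(ts) for g, ts in self.gene_terms.items()}

    @property
    def terms(self) -> set[str]:
        out: set[str] = set()
        for ts in self.gene_terms.values():
            out |= ts
        return out

    def members(self, term: str, universe=None) -> set[str]:
        uni = None if universe is None else set(universe)
        return {
            g
            for g, ts in self.gene_terms.items()
            if term in ts and (uni is None or g in uni)
        }

    def term_sizes(self, universe=None) -> pd.Series:
        counts: dict[str, int] = {}
        uni = None if universe is None else set(universe)
        for g, ts in self.gene_terms.items():
            if uni is not None and g not in uni:
                continue
            for t in ts:
                counts[t] = counts.get(t, 0) + 1
        return pd.Series(counts, dtype=int).sort_index()


def read_annotations(path) -> AnnotationMap:
    """Tab-delimited (gene, term) pairs, '#' comments."""
    df = pd.read_csv(path, sep="\t", comment="#", names=None)
    cols = list(df.columns)
    if not {"gene", "term"}.issubset(cols):
        raise ValidationError("annotation TSV needs columns: gene, term")
    out: dict[str, set[str]] = {}
    for g, t in zip(df["gene"], df["term"]):
        out.setdefault(str(g), set()).add(str(t))
    return AnnotationMap(out, mode="direct")


def write_annotations(ann: AnnotationMap, path) -> None:
    rows = [
        {"gene": g, "term": t}
        for g, ts in sorted(ann.gene_terms.items())
        for t in sorted(ts)
    ]
    pd.DataFrame(rows, columns=["gene", "term"]).to_csv(path, sep="\t", index=False)


def read_term_dag(path) -> nx.DiGraph:
    """Edge list TSV (child, parent) -> child->parent DiGraph."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"child", "parent"}.issubset(df.columns):
        raise ValidationError("DAG TSV needs columns: child, parent")
    g = nx.DiGraph()
    g.add_edges_from(zip(df["child"].astype(str), df["parent"].astype(str)))
    return g


def write_term_dag(dag: nx.DiGraph, path) -> None:
    rows = [{"child": c, "parent": p} for c, p in sorted(dag.edges)]
    pd.DataFrame(rows, columns=["child", "parent"]).to_csv(path, sep="\t", index=False)


def propagate_annotations(ann: AnnotationMap, dag: nx.DiGraph) -> AnnotationMap:
    """Annotate every gene to the ancestor closure of its direct terms.

    Idempotent; only grows sets. Cycles in the term graph are rejected."""
    if not nx.is_directed_acyclic_graph(dag):
        cycle = nx.find_cycle(dag)
        raise ValidationError(f"term graph has a cycle through {cycle[0][0]!r}")
    closure: dict[str, set[str]] = {}

    def ancestors(term: str) -> set[str]:
        if term not in closure:
            closure[term] = (
                set(nx.descendants(dag, term)) if term in dag else set()
            )  # edges point child->parent, so graph descendants are ancestors
        return closure[term]

    out = {
        g: set(ts).union(*(ancestors(t) for t in ts)) if ts else set()
        for g, ts in ann.gene_terms.items()
    }
    return AnnotationMap(out, mode="propagated")


def filter_terms(
    ann: AnnotationMap,
    universe,
    min_size: int = MIN_TERM_SIZE,
    max_size: int = MAX_TERM_SIZE,
) -> AnnotationMap:
    """Keep terms with between 3 and 100 members (inclusive), counted
    over the scored universe only."""
    sizes = ann.term_sizes(universe)
    keep = set(sizes[(sizes >= min_size) & (sizes <= max_size)].index)
    out = {g: ts & keep for g, ts in ann.gene_terms.items()}
    return AnnotationMap({g: ts for g, ts in out.items() if ts}, mode=ann.mode)


def sumstat_score(pvals) -> float:
    """T = sum over genes of sqrt(-ln p)."""
    p = np.asarray(list(pvals), dtype=float)
    if (p <= 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in (0, 1]")
    return float(np.sqrt(-np.log(p)).sum())


def sumstat_pvalues(
    ann: AnnotationMap,
    gene_p: pd.Series,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Per-term SUMSTAT score, permutation p and empirical q.

    Terms are sized over the scored universe; the null redraws each
    term's size in random genes from that universe. Null score matrices
    are shared across terms of equal size.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    from .scan import empirical_fdr

    rng = np.random.default_rng(seed)
    universe = gene_p.index.to_list()
    scores = np.sqrt(-np.log(gene_p.to_numpy(dtype=float)))
    if not np.isfinite(scores).all():
        raise ValidationError("gene p-values must lie in (0, 1]")
    sizes = ann.term_sizes(universe)
    if sizes.empty:
        raise ValidationError("no annotated terms overlap the scored universe")
    if int(sizes.max()) > len(universe):
        raise ValidationError("largest term exceeds the scored universe")

    gene_idx = {g: i for i, g in enumerate(universe)}
    null_by_size: dict[int, np.ndarray] = {}
    for k in sorted(set(sizes)):
        # k-subsets without replacement via random-key partial sort
        keys = rng.random((n_perm, len(universe)))
        draws = np.argpartition(keys, k - 1, axis=1)[:, :k]
        null_by_size[k] = scores[draws].sum(axis=1)

    rows = []
    for term in sizes.index:
        members = ann.members(term, universe)
        t_obs = float(scores[[gene_idx[g] for g in members]].sum())
        null = null_by_size[len(members)]
        # tolerance so ties are counted as >= despite summation-order rounding
        tol = 1e-9 * max(1.0, abs(t_obs))
        p = float((1 + (null >= t_obs - tol).sum()) / (n_perm + 1))
        rows.append({"term": term, "n": len(members), "T": t_obs, "p": p})
    out = pd.DataFrame(rows).set_index("term")
    out["q"] = empirical_fdr(out["p"])
    return out


def build_custom_set(
    gene_results: pd.DataFrame,
    enrich: pd.DataFrame,
    ann: AnnotationMap,
    gene_q_max: float = 0.27,
    member_p_max: float = 0.1,
    term_q_max: float = 0.1,
) -> pd.DataFrame:
    """Custom longevity-network set: genes with scan q <= 0.27, plus
    genes with scan p < 0.1 inside enriched terms (q < 0.1); provenance
    recorded per gene.

    ``gene_results`` needs columns p and q (scan output); ``enrich``
    needs column q indexed by term; ``ann`` should be propagated-mode.
    """
    if ann.mode != "propagated":
        raise ValidationError("custom-set construction expects propagated annotations")
    top = set(gene_results.index[gene_results["q"] <= gene_q_max])
    good_terms = set(enrich.index[enrich["q"] < term_q_max])
    via_terms = {
        g
        for g in gene_results.index[gene_results["p"] < member_p_max]
        if ann.gene_terms.get(g, set()) & good_terms
    }
    rows = []
    for g in sorted(top | via_terms):
        prov = []
        if g in top:
            prov.append("top_scan_fdr")
        if g in via_terms:
            prov.append("enriched_term_member")
        rows.append({"gene": g, "provenance": "+".join(prov)})
    return pd.DataFrame(rows, columns=["gene", "provenance"])
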