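"""Synthetic phylogenomic data with the structure the pipeline assumes.

The generator emulates a rockfish-like study design: 23 ingroup lineages
plus one outgroup, a binary longevity trait arising in eight independent
short-lived clades, a genome-wide substitution-rate elevation on
short-lived terminal branches (multiplier ``alpha``), gene-specific
convergent accelerations (multiplier ``lam``) concentrated in planted
functional terms, and GWAS summary statistics whose causal genes carry
one enriched SNP. Everything is reproducible from (config, seed); gene-
level streams are keyed by (seed, gene index) so individual genes can be
regenerated independently.

Two fidelity levels are provided for gene trees:

* ``simulate_alignment`` evolves sequences under HKY with 4-category
  discrete-gamma site rates; branch lengths are then estimated from the
  data (Jukes-Cantor distances + constrained least squares).
* ``simulate_gene_trees`` skips sequences and draws per-branch observed
  substitution counts from a Poisson with mean (effective branch length
  x gene length), giving branch-length noise of the same order at a
  fraction of the cost. The scan consumes branch lengths, so this is the
  default path for scan-scale experiments.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
import random

import dendropy
import networkx as nx
import numpy as np
import pandas as pd
import yaml
from scipy.linalg import expm
from scipy.stats import gamma as gamma_dist

from .alignment import ALPHABET, Alignment
from .enrichment import AnnotationMap
from .errors import RateshiftError, ValidationError
from .gwas import OrthologMap
from .traits import LONG, SHORT, TraitMap
from .tree import Phylogeny, count_foreground_clades

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "rockfish_fixture",
    "control_traits",
    "simulate_tree_and_trait",
    "simulate_alignment",
    "simulate_gene_trees",
    "simulate_annotations",
    "simulate_gwas",
    "simulate_dataset",
    "concatenate",
]


# -- the rockfish fixture ---------------------------------------------
# Topology and branch lengths are a constructed test fixture: the trait
# flags follow the published long/short species lists, the short-lived
# ingroup species fall into eight maximal clades, and depths are typical
# of a young radiation captured at conserved elements. It is not a claim
# of published branch lengths.

_A = "((S_aleutianus:0.010,S_borealis:0.011):0.004,S_melanostomus:0.013):0.003"
_B = "(S_emphaeus:0.016,S_ruberrimus:0.009):0.004"
_C = "((S_glaucus:0.015,S_melanops:0.010):0.003,S_rufus:0.011):0.003"
_D = "(S_crameri:0.012,S_alutus:0.009):0.004"
_E = "((S_auriculatus:0.014,S_maliger:0.010):0.003,S_rastrelliger:0.015):0.003"
_F = "((S_hopkinsi:0.013,S_jordani:0.014):0.005,S_helvomaculatus:0.012):0.003"
_G = "((S_umbrosus:0.013,S_chlorostictus:0.012):0.004,S_pinniger:0.010):0.003"
_H = "(S_seminictus:0.015,S_diploproa:0.011):0.004"
_I = "(S_rubrivinctus:0.013,S_babcocki:0.010):0.004"
_INGROUP = (
    f"(({_A},{_B}):0.003,"
    f"(({_C},{_D}):0.002,"
    f"((({_E},{_F}):0.002,"
    f"(({_G},{_H}):0.002,{_I}):0.002):0.002)"
    f":0.002):0.002):0.004"
)
ROCKFISH_NEWICK = f"({_INGROUP},P_carolinus:0.060);"

LONG_SPECIES = [
    "S_borealis", "S_aleutianus", "S_crameri", "S_alutus", "S_ruberrimus",
    "S_melanostomus", "S_diploproa", "S_pinniger", "S_maliger", "S_melanops",
    "S_rufus", "S_babcocki", "S_helvomaculatus",
]
SHORT_SPECIES = [
    "S_emphaeus", "S_glaucus", "S_seminictus", "S_rastrelliger",
    "S_auriculatus", "S_jordani", "S_hopkinsi", "S_rubrivinctus",
    "S_umbrosus", "S_chlorostictus", "P_carolinus",
]
OUTGROUP = "P_carolinus"

# trait-inverted control assignment balanced for phylogenetic relatedness
CONTROL_LONG = [
    "S_diploproa", "S_maliger", "P_carolinus", "S_glaucus", "S_borealis",
    "S_umbrosus", "S_hopkinsi", "S_rubrivinctus", "S_rufus", "S_alutus",
    "S_seminictus", "S_auriculatus", "S_pinniger",
]
CONTROL_SHORT = [
    "S_chlorostictus", "S_helvomaculatus", "S_aleutianus", "S_babcocki",
    "S_melanostomus", "S_rastrelliger", "S_ruberrimus", "S_jordani",
    "S_emphaeus", "S_crameri", "S_melanops",
]

# plausible maximum lifespans (years); long-lived 80-205, short-lived 11-30
_LIFESPAN = {
    "S_aleutianus": 205, "S_borealis": 120, "S_ruberrimus": 147,
    "S_melanostomus": 100, "S_crameri": 97, "S_alutus": 103,
    "S_diploproa": 95, "S_pinniger": 84, "S_maliger": 95, "S_melanops": 86,
    "S_rufus": 100, "S_babcocki": 105, "S_helvomaculatus": 87,
    "S_emphaeus": 22, "S_glaucus": 15, "S_seminictus": 14,
    "S_rastrelliger": 18, "S_auriculatus": 25, "S_jordani": 30,
    "S_hopkinsi": 29, "S_rubrivinctus": 32, "S_umbrosus": 15,
    "S_chlorostictus": 31, "P_carolinus": 11,
}


def rockfish_fixture() -> tuple[Phylogeny, TraitMap]:
    tree = Phylogeny.from_newick(ROCKFISH_NEWICK)
    classes = {sp: LONG for sp in LONG_SPECIES}
    classes.update({sp: SHORT for sp in SHORT_SPECIES})
    return tree, TraitMap(classes, dict(_LIFESPAN))


def control_traits() -> TraitMap:
    classes = {sp: LONG for sp in CONTROL_LONG}
    classes.update({sp: SHORT for sp in CONTROL_SHORT})
    return TraitMap(classes)


# -- configuration ----------------------------------------------------


@dataclass
class SimulationConfig:
    """All generator knobs; the seed fully determines every output."""

    seed: int = 0
    tree: str = "fixture"  # fixture | birth-death
    n_tips: int = 24  # incl. 1 outgroup (birth-death mode)
    n_foreground_clades: int = 8
    tree_depth: float = 0.05  # root-to-tip, subs/site (birth-death mode)
    n_genes: int = 200
    gene_length: int = 20_000
    kappa: float = 2.0  # HKY transition/transversion
    gamma_shape: float = 0.5  # per-site rate heterogeneity
    base_freqs: tuple = (0.3, 0.2, 0.2, 0.3)  # A, C, G, T
    alpha: float = 1.1  # global SHORT terminal-branch multiplier
    lam: float = 2.0  # extra multiplier, planted genes on SHORT terminals
    n_planted_genes: int = 20
    gene_rate_sigma: float = 0.25  # lognormal gene-wide rate scatter
    branch_rate_shape: float = 8.0  # gamma gene-x-branch rate noise
    n_terms: int = 100
    term_size_range: tuple = (3, 100)
    n_planted_terms: int = 1
    planted_term_size: int = 15
    planted_term_frac: float = 0.8  # fraction of planted genes per planted term
    snps_per_gene: tuple = (5, 50)
    causal_beta_a: float = 0.2  # Beta(a, 1) minimum for causal genes
    gene_span_range: tuple = (20_000, 100_000)
    genes_per_chrom: int = 20

    def __post_init__(self):
        if self.alpha <= 0 or self.lam <= 0:
            raise ValidationError("rate multipliers must be > 0")
        if self.n_planted_genes > self.n_genes:
            raise ValidationError("planted genes exceed the gene universe")
        lo, hi = self.term_size_range
        if not (3 <= lo <= hi <= 100):
            raise ValidationError("term sizes must stay within [3, 100]")
        if not (3 <= self.planted_term_size <= 100):
            raise ValidationError("planted term size outside the [3, 100] window")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config fields: {sorted(unknown)}")
        for key in ("base_freqs", "term_size_range", "snps_per_gene", "gene_span_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        for key, val in data.items():
            if isinstance(val, tuple):
                data[key] = list(val)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _gene_rng(seed: int, gene_index: int, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, stream, gene_index])


# -- tree & trait -----------------------------------------------------


def simulate_tree_and_trait(
    cfg: SimulationConfig,
) -> tuple[Phylogeny, TraitMap]:
    if cfg.tree == "fixture":
        return rockfish_fixture()
    if cfg.tree != "birth-death":
        raise ValidationError(f"unknown tree mode {cfg.tree!r}")
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 101])
    from dendropy.simulate import treesim

    py_rng = random.Random(int(rng.integers(2**31)))
    bd = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=cfg.n_tips,
        rng=py_rng,
    )
    for i, leaf in enumerate(bd.leaf_node_iter()):
        leaf.taxon.label = f"sp{i:02d}"
    bd.seed_node.edge.length = 0.0  # drop the basal edge: depth is root-to-tip
    depth = max(
        leaf.distance_from_root() for leaf in bd.leaf_node_iter()
    )
    for nd in bd.postorder_node_iter():
        if nd.edge.length:
            nd.edge.length *= cfg.tree_depth / depth
    tree = Phylogeny(bd)
    traits = _paint_clades(tree, cfg.n_foreground_clades, rng)
    return tree, traits


def _paint_clades(
    tree: Phylogeny, k: int, rng: np.random.Generator, max_tries: int = 5000
) -> TraitMap:
    """Label tips so SHORT forms exactly k maximal clades."""
    nodes = list(tree.dendropy_tree.postorder_node_iter())
    tipsets = {}
    for nd in nodes:
        tipsets[id(nd)] = frozenset(
            lf._rs_id for lf in (nd.leaf_iter() if not nd.is_leaf() else [nd])
        )
    all_tips = set(tree.tip_labels)
    candidates = [tipsets[id(nd)] for nd in nodes if len(tipsets[id(nd)]) < len(all_tips)]
    for _ in range(max_tries):
        order = rng.permutation(len(candidates))
        chosen: list[frozenset] = []
        covered: set[str] = set()
        for idx in order:
            c = candidates[idx]
            if c & covered:
                continue
            if len(covered | c) >= len(all_tips) - 1:
                continue  # keep at least two LONG tips
            chosen.append(c)
            covered |= c
            if len(chosen) == k:
                break
        if len(chosen) < k:
            continue
        classes = {t: (SHORT if t in covered else LONG) for t in all_tips}
        if count_foreground_clades(tree, classes, SHORT) == k:
            return TraitMap(classes)
    raise RateshiftError(
        f"could not paint {k} foreground clades on a {len(all_tips)}-tip tree"
    )


# -- sequence evolution (HKY + discrete gamma) ------------------------


def _hky_rate_matrix(kappa: float, pi: np.ndarray) -> np.ndarray:
    q = np.zeros((4, 4))
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            q[i, j] = pi[j] * (kappa if (i, j) in transitions else 1.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -(pi * np.diag(q)).sum()  # expected rate under stationarity
    return q / mu


def _discrete_gamma_rates(shape: float, k: int = 4) -> np.ndarray:
    quantiles = (2 * np.arange(k) + 1) / (2 * k)
    rates = gamma_dist.ppf(quantiles, a=shape, scale=1.0 / shape)
    return rates / rates.mean()


def _sample_states(parent: np.ndarray, p: np.ndarray, rng) -> np.ndarray:
    cum = p.cumsum(axis=1)
    u = rng.random(parent.size)
    return (u[:, None] > cum[parent]).sum(axis=1).astype(np.int8)


def _branch_multiplier(
    nd, traits: TraitMap, alpha: float, lam: float, convergent: bool
) -> float:
    if nd.is_leaf() and traits[nd._rs_id] == SHORT:
        return alpha * (lam if convergent else 1.0)
    return 1.0


def simulate_alignment(
    cfg: SimulationConfig,
    tree: Phylogeny,
    traits: TraitMap,
    gene_class: str = "neutral",
    gene_index: int = 0,
    n_columns: int | None = None,
) -> Alignment:
    """Evolve one gene along the tree under HKY + 4-category gamma.

    Short-lived terminal branches are stretched by ``alpha`` (and by
    ``lam`` as well when ``gene_class="convergent"``). Deterministic
    given (config seed, gene_index).
    """
    if gene_class not in ("neutral", "convergent"):
        raise ValidationError(f"unknown gene class {gene_class!r}")
    rng = _gene_rng(cfg.seed, gene_index, stream=1)
    ncol = int(n_columns or cfg.gene_length)
    pi = np.asarray(cfg.base_freqs, dtype=float)
    pi = pi / pi.sum()
    q = _hky_rate_matrix(cfg.kappa, pi)
    cat_rates = _discrete_gamma_rates(cfg.gamma_shape)
    site_cat = rng.integers(len(cat_rates), size=ncol)

    states: dict[int, np.ndarray] = {}
    root = tree.dendropy_tree.seed_node
    states[id(root)] = rng.choice(4, size=ncol, p=pi).astype(np.int8)
    for nd in tree.dendropy_tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        mult = _branch_multiplier(nd, traits, cfg.alpha, cfg.lam, gene_class == "convergent")
        t = float(nd.edge.length) * mult
        parent_states = states[id(nd.parent_node)]
        child = np.empty(ncol, dtype=np.int8)
        for c, rate in enumerate(cat_rates):
            mask = site_cat == c
            if not mask.any():
                continue
            p = expm(q * (t * rate))
            child[mask] = _sample_states(parent_states[mask], p, rng)
        states[id(nd)] = child
    seqs = {
        lf._rs_id: "".join(ALPHABET[s] for s in states[id(lf)])
        for lf in tree.dendropy_tree.leaf_node_iter()
    }
    return Alignment.from_dict(seqs)


def concatenate(alignments: list[Alignment]) -> Alignment:
    """Column-wise concatenation over the shared taxon set."""
    if not alignments:
        raise ValidationError("nothing to concatenate")
    labels = alignments[0].labels
    for a in alignments[1:]:
        if set(a.labels) != set(labels):
            raise ValidationError("taxon sets differ across alignments")
    codes = np.hstack([a.codes[[a.labels.index(l) for l in labels]] for a in alignments])
    return Alignment(labels, codes)


# -- gene trees (Poisson substitution-count mode) ---------------------


def simulate_gene_trees(
    cfg: SimulationConfig,
    tree: Phylogeny,
    traits: TraitMap,
    planted: set[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene terminal branch lengths with planted convergent shifts.

    Each gene g has a lognormal genome-wide rate factor; each (gene,
    branch) draws a gamma rate-noise term; observed branch length =
    Poisson(effective length x gene_length) / gene_length. Returns the
    genes x tips table and the planted gene ids.
    """
    gene_ids = [f"g{i:04d}" for i in range(cfg.n_genes)]
    if planted is None:
        rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 7])
        planted_idx = rng.choice(cfg.n_genes, size=cfg.n_planted_genes, replace=False)
        planted = {gene_ids[i] for i in planted_idx}
    tips = tree.tip_labels
    base = tree.terminal_branch_lengths().loc[tips].to_numpy()
    is_short = np.array([traits[t] == SHORT for t in tips])

    rows = np.empty((cfg.n_genes, len(tips)))
    for gi, gene in enumerate(gene_ids):
        rng = _gene_rng(cfg.seed, gi, stream=2)
        gene_factor = float(np.exp(rng.normal(0.0, cfg.gene_rate_sigma)))
        mult = np.where(is_short, cfg.alpha, 1.0)
        if gene in planted:
            mult = mult * np.where(is_short, cfg.lam, 1.0)
        noise = rng.gamma(cfg.branch_rate_shape, 1.0 / cfg.branch_rate_shape, len(tips))
        eff = base * gene_factor * mult * noise
        counts = rng.poisson(eff * cfg.gene_length)
        rows[gi] = counts / cfg.gene_length
    table = pd.DataFrame(rows, index=gene_ids, columns=tips)
    return table, sorted(planted)


# -- annotations ------------------------------------------------------


def simulate_annotations(
    cfg: SimulationConfig,
    gene_ids: list[str],
    planted: list[str],
) -> tuple[AnnotationMap, nx.DiGraph, list[str]]:
    """Random term memberships plus planted terms enriched for planted
    genes, and a small child->parent DAG grouping terms under hubs."""
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 3])
    lo, hi = cfg.term_size_range
    hi = min(hi, len(gene_ids))
    gene_terms: dict[str, set[str]] = {g: set() for g in gene_ids}
    term_ids = []

    planted_terms = []
    for t in range(cfg.n_planted_terms):
        term = f"T_planted{t:02d}"
        size = cfg.planted_term_size
        n_from_planted = min(int(np.ceil(cfg.planted_term_frac * size)), len(planted))
        members = list(rng.choice(planted, size=n_from_planted, replace=False))
        others = [g for g in gene_ids if g not in members]
        members += list(rng.choice(others, size=size - n_from_planted, replace=False))
        for g in members:
            gene_terms[g].add(term)
        planted_terms.append(term)
        term_ids.append(term)

    for t in range(cfg.n_terms):
        term = f"T{t:04d}"
        size = int(rng.integers(lo, hi + 1))
        for g in rng.choice(gene_ids, size=size, replace=False):
            gene_terms[g].add(term)
        term_ids.append(term)

    dag = nx.DiGraph()
    hubs = [f"H{h:02d}" for h in range(max(1, len(term_ids) // 10))]
    for i, term in enumerate(term_ids):
        dag.add_edge(term, hubs[i % len(hubs)])
    for hub in hubs:
        dag.add_edge(hub, "ROOT")
    return AnnotationMap(gene_terms, mode="direct"), dag, planted_terms


# -- GWAS -------------------------------------------------------------


def simulate_gwas(
    cfg: SimulationConfig,
    human_genes: list[str],
    causal: set[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tile genes on synthetic chromosomes and emit SNP summary stats.

    Non-causal genes carry Uniform(0,1) SNP p-values; causal genes get
    one extra SNP with p ~ Beta(a, 1), a < 1. Gene bodies do not overlap
    (their 50 kb windows may).
    """
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 4])
    lo, hi = cfg.snps_per_gene
    span_lo, span_hi = cfg.gene_span_range
    gap = 120_000

    gene_rows, snp_rows = [], []
    snp_i = 0
    for i, gene in enumerate(human_genes):
        chrom = f"chr{i // cfg.genes_per_chrom + 1}"
        slot = i % cfg.genes_per_chrom
        start = slot * (span_hi + gap) + int(rng.integers(0, gap // 2))
        span = int(rng.integers(span_lo, span_hi + 1))
        end = start + span
        gene_rows.append({"chrom": chrom, "start": start, "end": end, "gene": gene})
        n_snps = int(rng.integers(lo, hi + 1))
        win_lo, win_hi = max(0, start - 50_000), end + 50_000
        for _ in range(n_snps):
            pos0 = int(rng.integers(win_lo, win_hi))
            snp_rows.append(
                {
                    "snp": f"rs{snp_i:07d}",
                    "chrom": chrom,
                    "pos": pos0 + 1,
                    "p": float(rng.uniform()),
                }
            )
            snp_i += 1
        if gene in causal:
            pos0 = int(rng.integers(start, end))
            snp_rows.append(
                {
                    "snp": f"rs{snp_i:07d}",
                    "chrom": chrom,
                    "pos": pos0 + 1,
                    "p": float(rng.beta(cfg.causal_beta_a, 1.0)),
                }
            )
            snp_i += 1
    snps = pd.DataFrame(snp_rows)
    snps["p"] = snps["p"].clip(lower=np.finfo(float).tiny)
    return snps, pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "gene"])


# -- full dataset -----------------------------------------------------


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    tree: Phylogeny
    traits: TraitMap
    gene_trees: pd.DataFrame  # genes x tips terminal branch lengths
    planted_genes: list[str]
    annotations: AnnotationMap
    term_dag: nx.DiGraph
    planted_terms: list[str]
    snps: pd.DataFrame
    gene_windows: pd.DataFrame
    orthologs: OrthologMap
    causal_genes: list[str] = field(default_factory=list)

    def truth_frame(self) -> pd.DataFrame:
        rows = [{"kind": "gene", "id": g} for g in self.planted_genes]
        rows += [{"kind": "term", "id": t} for t in self.planted_terms]
        rows += [{"kind": "causal_gene", "id": g} for g in self.causal_genes]
        return pd.DataFrame(rows, columns=["kind", "id"])

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "species_tree.nwk").write_text(self.tree.to_newick())
        self.traits.to_tsv(out / "traits.tsv")
        self.gene_trees.rename_axis("gene").to_csv(out / "gene_branch_lengths.tsv", sep="\t")
        from .enrichment import write_annotations, write_term_dag

        write_annotations(self.annotations, out / "annotations.tsv")
        write_term_dag(self.term_dag, out / "term_dag.tsv")
        self.snps.to_csv(out / "gwas_snps.tsv", sep="\t", index=False)
        self.gene_windows.to_csv(
            out / "gene_coords.bed", sep="\t", index=False, header=False
        )
        self.orthologs.table.to_csv(out / "orthologs.tsv", sep="\t", index=False)
        self.truth_frame().to_csv(out / "truth.tsv", sep="\t", index=False)
        self.config.to_yaml(out / "config.yaml")


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Generate every pipeline input from one config."""
    tree, traits = simulate_tree_and_trait(cfg)
    gene_trees, planted = simulate_gene_trees(cfg, tree, traits)
    gene_ids = list(gene_trees.index)
    ann, dag, planted_terms = simulate_annotations(cfg, gene_ids, planted)
    causal = planted  # the convergent genes are also the GWAS-causal set
    snps, windows = simulate_gwas(cfg, gene_ids, set(causal))
    return SimulatedDataset(
        config=cfg,
        tree=tree,
        traits=traits,
        gene_trees=gene_trees,
        planted_genes=planted,
        annotations=ann,
        term_dag=dag,
        planted_terms=planted_terms,
        snps=snps,
        gene_windows=windows,
        orthologs=OrthologMap.identity(gene_ids),
        causal_genes=list(causal),
    )
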