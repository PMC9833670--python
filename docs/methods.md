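# Methods

This note records the modeling decisions, default parameters, and numerical
choices behind the package, and the scope of the synthetic-data generator.

## Data model and assumptions

- **Species tree.** Rooted, branch lengths in substitutions/site, unique tip
  labels, non-negative lengths (missing treated as 0). Internal nodes get
  stable postorder ids (`n<idx>`) when unlabeled, so outputs are joinable
  across runs.
- **Longevity trait.** Binary LONG/SHORT per species, optionally with a
  maximum-lifespan value in years. The shipped 24-species rockfish fixture
  has 13 long-lived and 11 short-lived species; the short-lived state forms
  8 maximal clades within the ingroup (9 counting the short-lived outgroup).
  A control trait map with inverted assignments over matched subclades ships
  alongside it for negative-control runs.
- **Gene data.** Either per-gene terminal branch lengths (genes × tips
  table, NaN for missing tips) or nucleotide alignments. Genes are retained
  for the scan only if present in ≥ 6 long-lived and ≥ 5 short-lived species
  and ≥ 12 species total — below that the cross-class pair statistic is
  dominated by a handful of branches.

## Convergence scan

Relative rates `r_{g,t} = b_{g,t}/b_t` are rank-normalized per branch across
genes into `(0, 1]`. Rank normalization makes the statistic invariant to
gene-wide rate scale and to any strictly monotone transform of branch
lengths (tested), at the cost of discarding magnitude information — the
standard robustness/power trade for cross-gene comparability.

The gene statistic is the weighted cross-class pair score `U` described in
the README, with pair weights equal to the rank of the patristic distance
among all SHORT × LONG pairs. Weighting by distance rank rather than raw
distance keeps a single deep split from dominating the sum.

**Permutation null.** Pseudo-traits are drawn uniformly over assignments
with the observed SHORT count, rejected unless the number of maximal SHORT
clades matches the observed count (tolerance widens to ±1 after 1000
rejections; hard failure after 20 000). The same permutation set is shared
by all genes so per-gene p-values are comparable and control-curve
comparisons are coherent. Two-sided p-values use
`p = (1 + #{|U_perm − 0.5| ≥ |U_obs − 0.5|}) / (n_perm + 1)`.

**Empirical FDR.** `q(p) = E[hits ≤ p] / #{observed ≤ p}`, capped at 1,
made monotone by a reverse running minimum, tie-aware. With the uniform
expectation `E = p·N` this is exactly Benjamini–Hochberg (asserted against
`statsmodels.multipletests` in the tests); an array of control p-values can
replace the uniform expectation.

## Ancestral identity

Two reconstructions are implemented:

- **Fitch parsimony** on state-set bitmasks (gaps/N contribute the full
  {A,C,G,T} set). Kept because its state sets admit an exact brute-force
  oracle (exhaustive minimization over internal labelings, tested).
- **Marginal ML under Jukes–Cantor** (up–down algorithm with the tree's
  branch lengths), the **default** for the identity stage.

The default is ML for a measured reason: bottom-up parsimony state sets only
see the subtree below a node, and percent identity must exclude ambiguous
(non-singleton) columns. At shallow nodes the excluded columns are exactly
the columns carrying the descendants' substitutions, so the exclusion is
correlated with the quantity being measured; in simulations with uniform
short-lived acceleration this erases and can invert the node ratio at
1-vs-2-tip nodes, while ML shows the expected ratio (< 1) at every node and
defines more nodes (19 vs 12 on the fixture).

Percent identity counts only columns with a singleton node state and a real
tip base. The node ratio compares mean percent **difference**:
`ratio = mean(1 − id_LONG) / mean(1 − id_SHORT)`; nodes lacking a class or
with zero group difference are omitted rather than reported as 0/∞.

**PGLS.** Brownian covariance `C_ij = depth(MRCA(i,j))`, solved by GLS.
The reported `r2_pred` is a conditional leave-one-out R²: each tip is
predicted from all others via the fitted covariance (kriging), for both the
model and the intercept-only null, which penalizes covariates that add
nothing beyond phylogeny. The binary-trait test is a phylogenetic ANOVA
with the Brownian rate matched so the expected sample variance equals the
observed one, making the p-value affine-invariant (tested).

## Enrichment

Term score `T = Σ √(−ln p)`; the square root damps single-gene outliers so
a term must carry broad signal. Term sizes are restricted to [3, 100]
counted over the scored universe. The competitive null redraws each term's
size in random genes from the universe (null matrices shared across
equal-size terms; subsets drawn by random-key `argpartition`, which is
uniform over k-subsets). Annotation propagation follows the term DAG
(child→parent edges) to the ancestor closure; propagated terms overlap
heavily, so their q-values are conservative and non-independent.

The custom "longevity network" set is genes with scan q ≤ 0.27 plus genes
with scan p < 0.1 that belong to a propagated term with enrichment q < 0.1,
with per-gene provenance recorded.

Default `n_perm = 1999` for enrichment: the smallest attainable permutation
p is `1/(n_perm+1)`, and with ~100 tested terms the rank-1 q-value is about
`p·100`, so 999 permutations cannot resolve q < 0.1 even for a perfect term.

## GWAS set test

Gene windows are the gene body ± 50 kb (BED 0-based half-open; SNP
positions 1-based, converted internally). The gene p-value is the Šidák
top-SNP form `1 − (1 − p_min)^n`, computed as `−expm1(n·log1p(−p_min))` so
it is exact for tiny `p_min` and large `n`. Under the generator's LD-free
SNPs this corrected p is exactly uniform for null genes (tested by KS).

Ortholog mapping accepts curated ("annotated") pairs unconditionally and
alignment-based pairs only with `E < 1e−30` and identity > 40%; annotated
mappings win when both exist.

The set test is competitive SUMSTAT with nulls matched on set size **and**
each member's SNP-count decile. The matching guards against gene-length
confounding: any miscalibration of per-gene p that correlates with SNP
count would otherwise inflate set-level rejections. Note a limitation of
the demonstration: because the generator's SNPs are LD-free, null gene
p-values are exactly uniform regardless of SNP count, so an unmatched null
is *not* demonstrably miscalibrated on synthetic data — the matching's
benefit shows only under the real-data failure mode it is designed for.
Calibration under 100-fold SNP-count variation and power on a planted
causal set are both asserted in the acceptance tests.

## Generator scope and limits

Everything is deterministic given the config seed; per-gene streams use
`default_rng([seed, stream, gene_index])` so genes are independent and
individually reproducible.

- **Sequences**: HKY + 4-category discrete gamma along the tree
  (matrix-exponential transition probabilities per branch and category).
  Short-lived terminal branches are stretched by `alpha` (default 1.1), and
  additionally by `lam` for convergent genes.
- **Gene trees** (fast mode): observed length = Poisson(effective ·
  L)/L with a lognormal gene-wide factor (σ = 0.25) and gamma gene×branch
  noise (shape 8). This reproduces the sampling noise of branch-length
  estimation without per-gene sequence simulation; it does not model
  alignment error, GC bias, or incomplete lineage sorting.
- **Annotations**: random term sizes in [3, 100] plus planted terms with
  ≥ 80% planted-gene membership; terms grouped under hub parents in a small
  DAG.
- **GWAS**: genes tiled on synthetic chromosomes (bodies non-overlapping,
  windows may overlap), uniform SNP p-values, causal genes carrying one
  extra SNP with `p ~ Beta(a, 1)`, `a = 0.2`. No linkage disequilibrium.

Problem-size defaults (200 genes, 24 tips, 20 kb genes, 100 terms, 5–50
SNPs/gene) are this package's own choices, sized so the full pipeline runs
in seconds while leaving permutation tests enough resolution.

## Numerical choices

- Least-squares branch lengths use non-negative least squares on the
  edge/path incidence matrix; the two root-child edges of a bifurcating
  root are merged into one column (only their sum is identifiable from
  distances) and the fitted sum is split in proportion to the topology's
  lengths.
- Jukes–Cantor distances use pairwise deletion and flag saturation
  (p̂ ≥ 0.75) as NaN rather than extrapolating.
- Permutation-p comparisons `null ≥ observed` use a 1e−9 relative
  tolerance so exact ties are not lost to floating-point summation order.
- Empirical-FDR monotonicity uses a reverse cumulative minimum; ties in p
  are counted with `searchsorted(..., side="right")`.
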