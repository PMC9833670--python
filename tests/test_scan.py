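"""Convergence scan: filters, rank rates, U statistic, permutations, FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest
from statsmodels.stats.multitest import multipletests

from rateshift import TraitMap, ValidationError, parse_newick
from rateshift.scan import (
    STATISTIC_VERSION,
    control_run,
    convergence_score,
    empirical_fdr,
    filter_gene_trees,
    gene_tree_table,
    relative_rates,
    sample_assignments,
    scan,
)
from rateshift.simulate import SimulationConfig, simulate_gene_trees
from rateshift.tree import count_foreground_clades


def make_genes(traits, rows):
    return pd.DataFrame(rows).T.rename_axis(index="gene")


class TestFilters:
    def _frame(self, n_long_present, n_short_present):
        tips = [f"L{i}" for i in range(8)] + [f"S{i}" for i in range(8)]
        row = {}
        for i in range(8):
            row[f"L{i}"] = 0.1 if i < n_long_present else np.nan
            row[f"S{i}"] = 0.1 if i < n_short_present else np.nan
        traits = TraitMap(
            {f"L{i}": "LONG" for i in range(8)} | {f"S{i}": "SHORT" for i in range(8)}
        )
        return pd.DataFrame({"g": row}).T, traits

    @pytest.mark.parametrize(
        "n_long,n_short,kept",
        [
            (6, 6, True),  # 12 total, at both class minima
            (5, 6, False),  # below the long-lived minimum
            (6, 5, False),  # 11 total, below the total minimum
            (7, 5, True),  # 12 total, short-lived at its minimum
            (8, 4, False),  # below the short-lived minimum
            (8, 8, True),
        ],
    )
    def test_boundaries(self, n_long, n_short, kept):
        genes, traits = self._frame(n_long, n_short)
        out = filter_gene_trees(genes, traits)
        assert (len(out) == 1) == kept

    def test_unknown_tip_rejected(self):
        genes, traits = self._frame(8, 8)
        genes["mystery"] = 0.1
        with pytest.raises(ValidationError, match="without trait"):
            filter_gene_trees(genes, traits)


class TestRelativeRates:
    def test_ranks_scale_free_and_in_unit_interval(self):
        tree = parse_newick("((A:0.1,B:0.2):0.1,C:0.4);")
        genes = pd.DataFrame(
            {"A": [0.1, 0.2, 0.3], "B": [0.6, 0.4, 0.2], "C": [0.4, 0.8, 1.2]},
            index=["g1", "g2", "g3"],
        )
        r = relative_rates(genes, tree)
        # per-branch ranks: relative rate order is preserved, values k/n
        assert sorted(r["A"]) == [pytest.approx(v) for v in (1 / 3, 2 / 3, 1.0)]
        assert r.loc["g1", "A"] < r.loc["g2", "A"] < r.loc["g3", "A"]
        # gene-level scaling leaves ranks unchanged
        r2 = relative_rates(genes * 7.5, tree)
        assert np.allclose(r.to_numpy(), r2.to_numpy())

    def test_zero_species_branch_rejected(self):
        tree = parse_newick("((A:0.0,B:0.2):0.1,C:0.4);")
        genes = pd.DataFrame({"A": [0.1], "B": [0.1], "C": [0.1]}, index=["g"])
        with pytest.raises(ValidationError, match="length 0"):
            relative_rates(genes, tree)

    def test_monotone_transform_invariance_of_scores(self):
        """U depends only on rank order, so any strictly increasing
        per-branch transform of branch lengths leaves it unchanged."""
        tree = parse_newick("((A:0.1,B:0.2):0.1,(C:0.3,D:0.4):0.1);")
        traits = TraitMap({"A": "SHORT", "B": "LONG", "C": "SHORT", "D": "LONG"})
        rng = np.random.default_rng(0)
        genes = pd.DataFrame(
            rng.exponential(0.1, size=(20, 4)), columns=list("ABCD")
        )
        dist = tree.patristic_distances()
        u1 = [
            convergence_score(row, traits, dist)
            for _, row in relative_rates(genes, tree).iterrows()
        ]
        u2 = [
            convergence_score(row, traits, dist)
            for _, row in relative_rates(np.exp(genes) - 0.5, tree).iterrows()
        ]
        assert np.allclose(u1, u2)


class TestConvergenceScore:
    def _setup(self):
        tree = parse_newick("((A:0.1,B:0.2):0.1,(C:0.3,D:0.4):0.1);")
        traits = TraitMap({"A": "SHORT", "B": "LONG", "C": "SHORT", "D": "LONG"})
        return tree, traits

    def test_foreground_fastest_gives_one(self):
        tree, traits = self._setup()
        ranks = pd.Series({"A": 0.9, "C": 1.0, "B": 0.1, "D": 0.2})
        assert convergence_score(ranks, traits, tree.patristic_distances()) == 1.0

    def test_foreground_slowest_gives_zero(self):
        tree, traits = self._setup()
        ranks = pd.Series({"A": 0.1, "C": 0.2, "B": 0.9, "D": 1.0})
        assert convergence_score(ranks, traits, tree.patristic_distances()) == 0.0

    def test_all_tied_gives_half(self):
        tree, traits = self._setup()
        ranks = pd.Series({"A": 0.5, "B": 0.5, "C": 0.5, "D": 0.5})
        assert convergence_score(ranks, traits, tree.patristic_distances()) == 0.5

    def test_matches_brute_force_weighted_sum(self):
        """Hand-computed weighted pair sum on a 3x3 cross-class grid."""
        tree = parse_newick(
            "(((S1:0.1,L1:0.2):0.1,(S2:0.3,L2:0.1):0.2):0.1,(S3:0.2,L3:0.3):0.4);"
        )
        traits = TraitMap(
            {"S1": "SHORT", "S2": "SHORT", "S3": "SHORT", "L1": "LONG", "L2": "LONG", "L3": "LONG"}
        )
        rng = np.random.default_rng(3)
        ranks = pd.Series(rng.permutation(np.arange(1, 7) / 6.0), index=traits.tips_of("SHORT") + traits.tips_of("LONG"))
        dist = tree.patristic_distances()
        got = convergence_score(ranks, traits, dist)

        from scipy.stats import rankdata

        s_tips = ["S1", "S2", "S3"]
        l_tips = ["L1", "L2", "L3"]
        d = np.array([[dist.loc[s, l] for l in l_tips] for s in s_tips])
        w = rankdata(d.ravel()).reshape(3, 3)
        num = den = 0.0
        for i, s in enumerate(s_tips):
            for j, l in enumerate(l_tips):
                sc = 1.0 if ranks[s] > ranks[l] else (0.5 if ranks[s] == ranks[l] else 0.0)
                num += w[i, j] * sc
                den += w[i, j]
        assert got == pytest.approx(num / den)

    def test_antisymmetric_under_class_swap(self):
        tree, traits = self._setup()
        rng = np.random.default_rng(5)
        dist = tree.patristic_distances()
        for _ in range(10):
            ranks = pd.Series(rng.permutation(np.arange(1, 5) / 4.0), index=list("ABCD"))
            u = convergence_score(ranks, traits, dist)
            u_sw = convergence_score(ranks, traits.swapped(), dist)
            assert u + u_sw == pytest.approx(1.0)

    def test_single_class_rejected(self):
        tree, traits = self._setup()
        ranks = pd.Series({"A": 0.5, "C": 0.6})
        with pytest.raises(ValidationError, match="both classes"):
            convergence_score(ranks, traits, tree.patristic_distances())


class TestSampleAssignments:
    def test_preserves_class_size_and_clade_count(self, rockfish_tree, rockfish_traits):
        masks = sample_assignments(rockfish_tree, rockfish_traits, 50, seed=1)
        tips = rockfish_tree.tip_labels
        n_short = sum(rockfish_traits[t] == "SHORT" for t in tips)
        target = count_foreground_clades(rockfish_tree, rockfish_traits, "SHORT")
        assert masks.shape == (50, len(tips))
        for mask in masks:
            assert mask.sum() == n_short
            cand = {t: ("SHORT" if m else "LONG") for t, m in zip(tips, mask)}
            assert abs(count_foreground_clades(rockfish_tree, cand, "SHORT") - target) <= 1

    def test_deterministic_given_seed(self, rockfish_tree, rockfish_traits):
        a = sample_assignments(rockfish_tree, rockfish_traits, 20, seed=7)
        b = sample_assignments(rockfish_tree, rockfish_traits, 20, seed=7)
        assert np.array_equal(a, b)


class TestEmpiricalFdr:
    def test_textbook_example(self):
        # p = 0.01 with N = 4 -> expected 0.04 hits vs 1 observed, then
        # monotone smoothing against the larger p-values
        q = empirical_fdr(np.array([0.01, 0.2, 0.5, 1.0]))
        assert q[0] == pytest.approx(0.04)
        assert q[1] == pytest.approx(0.4)
        assert q[3] == pytest.approx(1.0)

    def test_capped_at_one_and_monotone(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.001, 1.0, size=200)
        q = empirical_fdr(p)
        assert (q <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_equals_benjamini_hochberg(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(1e-4, 1.0, size=500)
        q = empirical_fdr(p)
        bh = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, bh)

    def test_control_expectation(self):
        # control p-values all large -> no expected hits at small p
        obs = np.array([0.01, 0.5, 0.9])
        ctrl = np.array([0.4, 0.6, 0.8, 0.95])
        q = empirical_fdr(obs, ctrl)
        assert q[0] == 0.0

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValidationError):
            empirical_fdr(np.array([0.0, 0.5]))
        with pytest.raises(ValidationError):
            empirical_fdr(np.array([0.5, 1.5]))
        with pytest.raises(ValidationError):
            empirical_fdr(np.array([]))


class TestScan:
    def _null_genes(self, seed=11, n_genes=300):
        cfg = SimulationConfig(seed=seed, n_genes=n_genes, alpha=1.0, lam=1.0)
        from rateshift.simulate import simulate_tree_and_trait

        tree, traits = simulate_tree_and_trait(cfg)
        genes, _ = simulate_gene_trees(cfg, tree, traits)
        return genes, traits, tree

    def test_scan_output_shape_and_determinism(self):
        genes, traits, tree = self._null_genes(n_genes=60)
        r1 = scan(genes, traits, tree, n_perm=100, seed=5)
        r2 = scan(genes, traits, tree, n_perm=100, seed=5)
        assert list(r1.genes.columns) == ["U", "direction", "p", "q", "n_long", "n_short"]
        assert r1.statistic_version == STATISTIC_VERSION
        pd.testing.assert_frame_equal(r1.genes, r2.genes)
        assert ((r1.genes["p"] > 0) & (r1.genes["p"] <= 1)).all()

    def test_null_pvalues_uniform(self):
        genes, traits, tree = self._null_genes(seed=21)
        res = scan(genes, traits, tree, n_perm=300, seed=2)
        assert kstest(res.genes["p"], "uniform").pvalue > 0.01
        assert (res.genes["q"] <= 0.2).sum() <= 2

    def test_accelerated_genes_rank_high(self):
        cfg = SimulationConfig(seed=4, n_genes=200, alpha=1.0, lam=3.0, n_planted_genes=20)
        from rateshift.simulate import simulate_tree_and_trait

        tree, traits = simulate_tree_and_trait(cfg)
        genes, planted = simulate_gene_trees(cfg, tree, traits)
        res = scan(genes, traits, tree, n_perm=300, seed=9)
        dev = (res.genes["U"] - 0.5).abs().sort_values(ascending=False)
        top = set(dev.index[: len(res.genes) // 10])
        frac = len(top & set(planted)) / len(planted)
        assert frac >= 0.7
        assert (res.genes.loc[planted, "direction"] == "foreground-accelerated").mean() > 0.9

    def test_too_few_permutations_rejected(self):
        genes, traits, tree = self._null_genes(n_genes=30)
        with pytest.raises(ValidationError, match="n_perm"):
            scan(genes, traits, tree, n_perm=50)


class TestControlRun:
    def test_identical_traits_give_zero_displacement_structure(self):
        """Comparing the scan to itself under the same traits and seeds
        collapses the curves."""
        cfg = SimulationConfig(seed=8, n_genes=80, alpha=1.0, lam=1.0)
        from rateshift.simulate import simulate_tree_and_trait

        tree, traits = simulate_tree_and_trait(cfg)
        genes, _ = simulate_gene_trees(cfg, tree, traits)
        curves, disp, exp, ctrl = control_run(genes, traits, traits, tree, n_perm=100, seed=3)
        # same traits but independent permutation draws: curves stay close
        assert disp < 0.25
        assert (curves["x"].diff().dropna() > 0).all()
        assert curves["F_exp"].iloc[-1] == 1.0
        assert curves["F_ctrl"].iloc[-1] == 1.0

    def test_planted_signal_separates_experimental_from_control(self, rockfish):
        tree, traits = rockfish
        from rateshift.simulate import control_traits as control_map

        cfg = SimulationConfig(seed=12, n_genes=150, alpha=1.0, lam=3.0, n_planted_genes=30)
        genes, _ = simulate_gene_trees(cfg, tree, traits)
        curves, disp, exp, ctrl = control_run(
            genes, traits, control_map(), tree, n_perm=200, seed=6
        )
        # the experimental curve dominates at small p
        small = curves[curves["x"] <= 0.1]
        assert (small["F_exp"] >= small["F_ctrl"]).mean() > 0.8
        assert disp > 0.05
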