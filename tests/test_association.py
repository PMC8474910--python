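"""Association score, permutation null, tree-aware statistics, FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

import panphen as pp
from panphen.association import (
    fdr_adjust,
    pa_score,
    permutation_test,
    score_all,
    tree_null_scores,
    tree_statistics,
)
from panphen.evaluation import exhaustive_min_changes
from panphen.synthetic_data import (
    SimConfig,
    resolve_causal_genes,
    simulate_phenotypes,
    simulate_presence_absence,
    simulate_tree,
)

from conftest import pheno_from_dict, random_small_tree


class TestPaScore:
    def test_worked_example_clade_concordant_gene(self, toy_means):
        sigma = float(np.std([10, 10, 20, 20], ddof=1))
        score = pa_score(toy_means, {"A": 0, "B": 0, "C": 1, "D": 1}, n_g=1,
                         sigma=sigma)
        assert score == pytest.approx(1.7321, abs=1e-4)

    def test_balanced_split_with_equal_group_means_scores_zero(self, toy_means):
        score = pa_score(toy_means, {"A": 1, "B": 0, "C": 1, "D": 0}, n_g=2,
                         sigma=5.7735)
        assert score == 0.0

    def test_zero_sigma_is_degenerate_phenotype(self, toy_means):
        with pytest.raises(ValueError, match="degenerate phenotype"):
            pa_score(toy_means, {"A": 0, "B": 0, "C": 1, "D": 1}, 1, 0.0)

    def test_empty_group_rejected(self, toy_means):
        with pytest.raises(ValueError, match="non-empty"):
            pa_score(toy_means, {s: 1 for s in "ABCD"}, 1, 5.0)


class TestScoreAll:
    def test_gene_present_everywhere_excluded(self, toy_tree, toy_pheno):
        pa = pp.PAMatrix(
            pd.DataFrame(
                [[1, 1, 1, 1], [0, 0, 1, 1]],
                index=["core", "var"],
                columns=list("ABCD"),
            )
        )
        table = score_all(toy_tree, pa, toy_pheno)
        assert table.genes == ["var"]
        assert table.scores[0] == pytest.approx(1.7321, abs=1e-4)

    def test_replicate_order_within_strain_is_irrelevant(self, toy_tree):
        pa = pp.PAMatrix(
            pd.DataFrame([[0, 0, 1, 1]], index=["g"], columns=list("ABCD"))
        )
        p1 = pheno_from_dict({"A": [8, 12], "B": [10, 10], "C": [18, 22], "D": [20, 20]})
        p2 = pheno_from_dict({"A": [12, 8], "B": [10, 10], "C": [22, 18], "D": [20, 20]})
        t1, t2 = score_all(toy_tree, pa, p1), score_all(toy_tree, pa, p2)
        assert t1.scores == pytest.approx(t2.scores)

    def test_identical_presence_patterns_get_identical_scores(
        self, toy_tree, toy_pheno
    ):
        # genome-wide linkage: same history, same evidence, same score
        pa = pp.PAMatrix(
            pd.DataFrame(
                [[0, 0, 1, 1], [0, 0, 1, 1], [0, 1, 1, 0]],
                index=["opA", "opB", "other"],
                columns=list("ABCD"),
            )
        )
        table = score_all(toy_tree, pa, toy_pheno)
        by_gene = dict(zip(table.genes, table.scores))
        assert by_gene["opA"] == by_gene["opB"]

    def test_sigma_from_replicates_mode_changes_scale_not_ranking(
        self, toy_tree, toy_pheno
    ):
        pa = pp.PAMatrix(
            pd.DataFrame(
                [[0, 0, 1, 1], [1, 0, 0, 0]], index=["a", "b"], columns=list("ABCD")
            )
        )
        t1 = score_all(toy_tree, pa, toy_pheno, sigma_mode="strain-means")
        t2 = score_all(toy_tree, pa, toy_pheno, sigma_mode="replicates")
        assert t1.sigma != t2.sigma
        assert np.argsort(-np.abs(t1.scores)).tolist() == np.argsort(
            -np.abs(t2.scores)
        ).tolist()

    def test_n_g_matches_exhaustive_enumeration_end_to_end(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            tree = random_small_tree(rng)
            n = tree.n_tips
            patterns = rng.integers(0, 2, size=(5, n))
            keep = [i for i, p in enumerate(patterns) if 0 < p.sum() < n]
            pa = pp.PAMatrix(
                pd.DataFrame(
                    patterns[keep],
                    index=[f"g{i}" for i in keep],
                    columns=tree.tip_labels,
                )
            )
            if not len(pa.genes):
                continue
            pheno = pheno_from_dict(
                {lbl: list(rng.integers(10, 60, 3)) for lbl in tree.tip_labels}
            )
            table = score_all(tree, pa, pheno)
            for gene, n_g in zip(table.genes, table.n_g):
                pattern = dict(zip(pa.strains, pa.values.loc[gene]))
                assert n_g == exhaustive_min_changes(tree, pattern)

    def test_ranking_tie_break_is_lexicographic(self, toy_tree, toy_pheno):
        pa = pp.PAMatrix(
            pd.DataFrame(
                [[0, 0, 1, 1], [0, 0, 1, 1]], index=["zz", "aa"], columns=list("ABCD")
            )
        )
        frame = score_all(toy_tree, pa, toy_pheno).frame()
        assert frame["gene"].tolist() == ["aa", "zz"]


class TestPermutationTest:
    def test_observed_beating_every_permutation_hits_add_one_floor(self):
        # 16 strains, a huge effect on a balanced split: only 1 of the
        # C(16,8) = 12870 label splits reproduces the observed separation,
        # so 99 random permutations (fixed seed) contain none and
        # p = (1+0)/(1+99) = 0.01 exactly
        cfg = SimConfig(n_strains=16, seed=31)
        tree = simulate_tree(cfg)
        labels = tree.tip_labels
        pa = pp.PAMatrix(
            pd.DataFrame(
                [[1 if i < 8 else 0 for i in range(16)]],
                index=["g"], columns=labels,
            )
        )
        pheno = pheno_from_dict(
            {lbl: [1000 + i, 1000 + i] if i < 8 else [10 + i, 10 + i]
             for i, lbl in enumerate(labels)}
        )
        table = score_all(tree, pa, pheno)
        p = permutation_test(table, n_perm=99, seed=0)
        assert p[0] == pytest.approx(0.01)

    def test_permutation_p_matches_split_probability(self, toy_tree):
        # 4 strains, two far-separated mean pairs: 2 of the 6 distinct
        # splits are as extreme as the observed one, so p -> 1/3
        pa = pp.PAMatrix(
            pd.DataFrame([[0, 0, 1, 1]], index=["g"], columns=list("ABCD"))
        )
        pheno = pheno_from_dict(
            {"A": [10, 10], "B": [11, 11], "C": [500, 500], "D": [501, 501]}
        )
        table = score_all(toy_tree, pa, pheno)
        p = permutation_test(table, n_perm=1999, seed=0)
        assert p[0] >= 1 / 2000
        assert p[0] == pytest.approx(1 / 3, abs=0.04)

    def test_all_strain_means_equal_is_degenerate(self, toy_tree):
        pa = pp.PAMatrix(
            pd.DataFrame([[0, 0, 1, 1]], index=["g"], columns=list("ABCD"))
        )
        pheno = pheno_from_dict({s: [10, 10] for s in "ABCD"})
        with pytest.raises(ValueError, match="degenerate phenotype"):
            score_all(toy_tree, pa, pheno)

    def test_seed_reproducible(self, paperlike):
        table = score_all(paperlike["tree"], paperlike["pa"], paperlike["pheno"])
        p1 = permutation_test(table, n_perm=199, seed=5).copy()
        p2 = permutation_test(table, n_perm=199, seed=5)
        assert np.array_equal(p1, p2)

    def test_minimum_permutation_count_enforced(self, paperlike):
        table = score_all(paperlike["tree"], paperlike["pa"], paperlike["pheno"])
        with pytest.raises(ValueError, match=">= 99"):
            permutation_test(table, n_perm=50)


class TestTreeStatistics:
    def test_perfect_partition_gives_unit_terminal_correlation(
        self, toy_tree, toy_means
    ):
        presence = np.array([[0, 0, 1, 1]], dtype=np.int8)
        m = toy_tree.tip_values(toy_means)
        terminal, simultaneous, subsequent = tree_statistics(toy_tree, presence, m)
        assert terminal[0] == pytest.approx(1.0)
        assert simultaneous[0] > 0

    def test_constant_phenotype_zeroes_all_statistics(self, toy_tree):
        presence = np.array([[0, 1, 1, 0], [1, 0, 0, 0]], dtype=np.int8)
        m = np.full(4, 42.0)
        for stat in tree_statistics(toy_tree, presence, m):
            assert np.allclose(stat, 0.0)

    def test_null_simulated_genotypes_score_uniform_p(self, paperlike):
        # genes simulated under the same branch-placement null as the
        # reference distribution must get p-values without small-p excess
        tree, pa, pheno = paperlike["tree"], paperlike["pa"], paperlike["pheno"]
        table = score_all(tree, pa, pheno)
        frame = tree_null_scores(table, n_sims=199, seed=13)
        for col in ("terminal_p", "simultaneous_p", "subsequent_p"):
            p = frame[col].to_numpy()
            assert p.min() >= 1 / 200
            assert p.max() <= 1.0

    def test_causal_pathway_enriched_in_tree_null_p(self, paperlike):
        tree, pa, pheno = paperlike["tree"], paperlike["pa"], paperlike["pheno"]
        truth = paperlike["truth"]
        causal = set(truth.loc[truth.causal_beta > 0, "gene"])
        table = score_all(tree, pa, pheno)
        frame = tree_null_scores(table, n_sims=199, seed=13)
        sub = frame[frame.gene.isin(causal)]
        assert (sub["terminal_p"] < 0.05).all()

    def test_refuses_tiny_null_sample(self, paperlike):
        table = score_all(paperlike["tree"], paperlike["pa"], paperlike["pheno"])
        with pytest.raises(ValueError, match=">= 99"):
            tree_null_scores(table, n_sims=50)


class TestAffineInvariance:
    def test_affine_transform_preserves_scores_and_pvalues(
        self, toy_tree, toy_pheno
    ):
        pa = pp.PAMatrix(
            pd.DataFrame(
                [[0, 0, 1, 1], [1, 0, 0, 0]], index=["a", "b"], columns=list("ABCD")
            )
        )
        t1 = score_all(toy_tree, pa, toy_pheno)
        df = toy_pheno.df.copy()
        df["offspring"] = 3 * df["offspring"] + 7
        t2 = score_all(toy_tree, pa, pp.PhenotypeTable(df))
        assert np.abs(t1.scores) == pytest.approx(np.abs(t2.scores))
        permutation_test(t1, 99, seed=3)
        permutation_test(t2, 99, seed=3)
        assert np.array_equal(t1.perm_p, t2.perm_p)


class TestPowerMonotonicity:
    def test_mean_causal_score_nondecreasing_in_effect_size(self):
        betas = [0.0, 4.0, 8.0, 16.0]
        mean_scores = []
        for beta in betas:
            vals = []
            for s in range(5):
                cfg = SimConfig(n_strains=15, n_genes=200, replicates=8,
                                causal_genes=[(None, beta)], seed=100 + s)
                tree = simulate_tree(cfg)
                pa, _ = simulate_presence_absence(tree, cfg)
                causal = resolve_causal_genes(pa, cfg, tree)
                pheno = simulate_phenotypes(pa, cfg, causal)
                table = score_all(tree, pa, pheno)
                ci = table.genes.index(pa.genes[causal[0][0]])
                vals.append(abs(table.scores[ci]))
            mean_scores.append(np.mean(vals))
        assert all(b >= a for a, b in zip(mean_scores, mean_scores[1:]))


class TestFdrAdjust:
    def test_step_up_worked_example(self):
        assert fdr_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_and_degenerate_inputs(self):
        assert fdr_adjust([0.2]) == pytest.approx([0.2])
        assert fdr_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.0, 0.5])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=30))
    def test_matches_independent_bh_implementation(self, ps):
        ours = fdr_adjust(ps)
        theirs = multipletests(ps, method="fdr_bh")[1]
        assert np.allclose(ours, theirs)
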