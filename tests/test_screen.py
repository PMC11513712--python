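"""Screen scoring chain: normalization, L2FC, pseudo-genes, z, bootstrap, FDR."""

import numpy as np
import pandas as pd
import pytest

from moakit import screen as sc
from moakit import synthdata as sd
from moakit.errors import (
    AlignmentError,
    DegenerateNullError,
    InsufficientControlsError,
    InvalidInputError,
    NormalizationError,
)


class TestSizeFactors:
    def test_hand_median_of_ratios(self):
        counts = pd.DataFrame({"S1": [100, 200, 400], "S2": [200, 400, 800]})
        f = sc.size_factors(counts)
        assert f["S1"] == pytest.approx(1 / np.sqrt(2))
        assert f["S2"] == pytest.approx(np.sqrt(2))

    def test_identical_samples_equal_factors(self):
        counts = pd.DataFrame({"S1": [10, 20, 30], "S2": [10, 20, 30]})
        assert np.allclose(sc.size_factors(counts), 1.0)

    def test_single_sample_factor_one(self):
        counts = pd.DataFrame({"S1": [10, 20, 30]})
        assert sc.size_factors(counts)["S1"] == pytest.approx(1.0)

    def test_no_all_positive_guide(self):
        counts = pd.DataFrame({"S1": [0, 5], "S2": [5, 0]})
        with pytest.raises(NormalizationError):
            sc.size_factors(counts)


class TestGuideL2fc:
    def test_equal_counts_zero(self, toy_screen):
        _, _, gcm = toy_screen
        l2fc = sc.guide_l2fc(gcm, "untreated", "untreated")
        assert np.allclose(l2fc["l2fc"], 0.0)

    def test_hand_pseudocount_value(self):
        # 200 vs 50 with unit factors and c = 0.5
        assert np.log2(200.5 / 50.5) == pytest.approx(1.98926, abs=1e-4)
        counts = pd.DataFrame(
            {"num_r1": [200, 100], "den_r1": [50, 100]}, index=["g1", "g2"]
        )
        guides = pd.DataFrame(
            {"gene": ["A", "B"], "nontargeting": [False, False]}, index=counts.index
        )
        samples = pd.DataFrame(
            {"role": ["dead", "live"], "treatment": ["t", "t"], "replicate": [1, 1]},
            index=pd.Index(["num_r1", "den_r1"], name="sample"),
        )
        gcm = sc.GuideCountMatrix(counts, guides, samples)
        ones = pd.Series(1.0, index=counts.columns)
        l2fc = sc.guide_l2fc(gcm, "dead", "live", "t", factors=ones)
        assert l2fc.loc["g1", "l2fc"] == pytest.approx(np.log2(200.5 / 50.5))

    def test_zero_vs_zero_is_zero(self):
        counts = pd.DataFrame({"a_r1": [0, 100], "b_r1": [0, 100]}, index=["g1", "g2"])
        guides = pd.DataFrame(
            {"gene": ["A", "B"], "nontargeting": [False, False]}, index=counts.index
        )
        samples = pd.DataFrame(
            {"role": ["dead", "live"], "treatment": ["t", "t"], "replicate": [1, 1]},
            index=pd.Index(["a_r1", "b_r1"], name="sample"),
        )
        gcm = sc.GuideCountMatrix(counts, guides, samples)
        l2fc = sc.guide_l2fc(gcm, "dead", "live", "t")
        assert l2fc.loc["g1", "l2fc"] == pytest.approx(0.0)


class TestPseudoGenes:
    def test_142_controls_make_36_sets_of_four(self):
        ids = [f"NT_{i}" for i in range(142)]
        assignment = sc.assign_pseudogenes(ids, seed=0)
        assert len(assignment) == 36
        assert all(len(m) == 4 for m in assignment.sets.values())
        assert len(assignment.reused_ids) == 2

    def test_divisible_pool_no_reuse(self):
        assignment = sc.assign_pseudogenes([f"NT_{i}" for i in range(144)], seed=0)
        assert len(assignment) == 36
        assert not assignment.reused_ids
        flat = [g for m in assignment.sets.values() for g in m]
        assert len(set(flat)) == 144

    def test_seed_determinism(self):
        ids = [f"NT_{i}" for i in range(142)]
        a = sc.assign_pseudogenes(ids, seed=7)
        b = sc.assign_pseudogenes(ids, seed=7)
        assert a.sets == b.sets

    def test_too_few_controls(self):
        with pytest.raises(InsufficientControlsError):
            sc.assign_pseudogenes(["NT_1", "NT_2"], set_size=4)


class TestGeneScores:
    def _l2fc_frame(self, values, genes, nt=None):
        nt = nt or [False] * len(values)
        return pd.DataFrame(
            {"l2fc": values, "gene": genes, "nontargeting": nt},
            index=[f"g{i}" for i in range(len(values))],
        )

    def test_mean_aggregation(self):
        table = self._l2fc_frame([1.0, 1.0, 1.0, 1.0, 2.0, 0.0, 0.0, 0.0],
                                 ["A"] * 4 + ["B"] * 4)
        scores = sc.gene_scores(table)
        assert scores.loc["A", "fc"] == pytest.approx(1.0)
        assert scores.loc["B", "fc"] == pytest.approx(0.5)
        assert scores.loc["A", "n_guides"] == 4

    def test_pseudo_genes_share_code_path(self):
        table = self._l2fc_frame(
            [1.0, 2.0, 0.5, 1.5, 3.0, 3.0], ["A", "A", "NT", "NT", "NT", "NT"],
            [False, False, True, True, True, True],
        )
        pseudo = sc.PseudoGeneAssignment(
            sets={"PSEUDO_001": ["g2", "g3", "g4", "g5"]}, reused_ids=[], seed=0
        )
        scores = sc.gene_scores(table, pseudo)
        assert scores.loc["PSEUDO_001", "fc"] == pytest.approx((0.5 + 1.5 + 3 + 3) / 4)
        assert bool(scores.loc["PSEUDO_001", "is_pseudo"])


class TestZScores:
    def test_center_and_scale(self):
        pseudo = pd.Series([0.0, 1.0, -1.0, 2.0, -2.0])
        z = sc.zscore_genes(pd.Series({"A": pseudo.mean(), "B": 2.0}), pseudo)
        assert z["A"] == pytest.approx(0.0)
        assert z["B"] == pytest.approx((2.0 - pseudo.mean()) / pseudo.std(ddof=1))

    def test_location_invariance(self):
        pseudo = pd.Series([0.1, 0.5, -0.3, 0.2])
        genes = pd.Series({"A": 1.0, "B": -0.5})
        z1 = sc.zscore_genes(genes, pseudo)
        z2 = sc.zscore_genes(genes + 5.0, pseudo + 5.0)
        assert np.allclose(z1, z2)

    def test_degenerate_null(self):
        with pytest.raises(DegenerateNullError):
            sc.zscore_genes(pd.Series({"A": 1.0}), pd.Series([0.5, 0.5, 0.5]))


class TestBootstrap:
    def test_null_centered_gene_has_large_p(self):
        rng = np.random.default_rng(0)
        pool = rng.normal(0.0, 1.0, 500)
        table = pd.DataFrame({"fc": [0.0], "n_guides": [4]}, index=["A"])
        p = sc.bootstrap_pvalues(table, pool, 0.0, 0.5, B=10000, seed=1)
        assert p["A"] >= 0.95

    def test_minimum_attainable_p(self):
        rng = np.random.default_rng(0)
        pool = rng.normal(0.0, 0.1, 500)
        table = pd.DataFrame({"fc": [50.0], "n_guides": [4]}, index=["A"])
        p = sc.bootstrap_pvalues(table, pool, 0.0, 0.05, B=999, seed=1)
        assert p["A"] == pytest.approx(1.0 / 1000.0)

    def test_empty_pool_rejected(self):
        table = pd.DataFrame({"fc": [0.0], "n_guides": [4]}, index=["A"])
        with pytest.raises(InsufficientControlsError):
            sc.bootstrap_pvalues(table, np.array([]), 0.0, 1.0)


class TestBhFdr:
    def test_hand_example(self):
        q = sc.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_all_ones(self):
        assert np.allclose(sc.bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_single_p(self):
        assert sc.bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_nan_propagates_with_warning(self):
        with pytest.warns(UserWarning):
            q = sc.bh_fdr([0.01, np.nan])
        assert np.isnan(q[1])

    def test_monotone_nondecreasing_in_rank(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=50)
        q = sc.bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestCallHits:
    def _table(self, z, fdr):
        genes = [f"G{i}" for i in range(len(z))]
        return pd.DataFrame({"zl2fc": z, "fdr": fdr}, index=genes)

    def test_identical_tables_r2_one(self):
        t = self._table([3.0, -2.5, 0.1, 4.0], [0.01, 0.05, 0.9, 0.001])
        calls = sc.call_hits({"a": t, "b": t.copy()})
        assert calls.r_squared == pytest.approx(1.0)
        assert calls.intersection == {"G0", "G1", "G3"}

    def test_sign_split(self):
        t = self._table([3.0, -2.5, 0.1], [0.01, 0.05, 0.9])
        calls = sc.call_hits({"a": t, "b": t.copy()})
        assert calls.hits["a"]["positive"] == {"G0"}
        assert calls.hits["a"]["negative"] == {"G1"}

    def test_empty_hits_no_error(self):
        t = self._table([0.1, 0.2], [0.9, 0.8])
        calls = sc.call_hits({"a": t, "b": t.copy()})
        assert calls.intersection == set()
        assert np.isnan(calls.r_squared)

    def test_mismatched_universe(self):
        t1 = self._table([1.0, 2.0], [0.5, 0.5])
        t2 = t1.rename(index={"G1": "OTHER"})
        with pytest.raises(AlignmentError):
            sc.call_hits({"a": t1, "b": t2})


class TestKsQc:
    def test_identical_distributions(self):
        z = pd.Series(np.arange(30, dtype=float), index=[f"G{i}" for i in range(30)])
        # essentials drawn as every other gene: same distribution shape
        res = sc.ks_essential_qc(
            pd.concat([z, z.rename(lambda s: s + "e")]),
            [f"G{i}e" for i in range(30)],
        )
        assert res.d_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_disjoint_supports(self):
        z = pd.Series(
            [1.0, 2.0, 3.0] + [4.0, 5.0, 6.0] * 4,
            index=[f"G{i}" for i in range(15)],
        )
        with pytest.warns(UserWarning, match="underpowered"):
            res = sc.ks_essential_qc(z, ["G0", "G1", "G2"])
        assert res.d_statistic == pytest.approx(1.0)

    def test_planted_essentials_detected(self):
        truth = sd.ScreenTruth(n_genes=200, dispersion=0.05, seed=0)
        library = sd.gen_crispr_library(truth)
        gcm = sd.gen_screen_counts(library, truth, sd.default_screen_samples(("drug",)))
        results = sc.score_screen(gcm, B=200, seed=0)
        res = sc.ks_essential_qc(
            results.gene_table("untreated_vs_T0")["zl2fc"],
            sd.planted_essentials(library, truth),
        )
        assert res.p_value < 0.01
        assert res.essentials_depleted


class TestOracleEquivalence:
    """Every scoring stage on a 20-guide toy matrix must match an independent
    brute-force recomputation to 1e-12."""

    def _brute_force(self, gcm, seed):
        counts = gcm.counts
        # size factors
        factors = {}
        all_pos = [g for g in counts.index if (counts.loc[g] > 0).all()]
        for s in counts.columns:
            ratios = []
            for g in all_pos:
                gm = np.exp(np.mean([np.log(counts.loc[g, c]) for c in counts.columns]))
                ratios.append(counts.loc[g, s] / gm)
            factors[s] = float(np.median(ratios))
        gm_f = np.exp(np.mean([np.log(v) for v in factors.values()]))
        factors = {s: v / gm_f for s, v in factors.items()}
        # per-replicate l2fc, then average
        l2fc = {}
        for g in counts.index:
            vals = []
            for rep in (1, 2):
                n = counts.loc[g, f"drug_dead_r{rep}"] / factors[f"drug_dead_r{rep}"]
                d = counts.loc[g, f"drug_live_r{rep}"] / factors[f"drug_live_r{rep}"]
                vals.append(np.log2((n + 0.5) / (d + 0.5)))
            l2fc[g] = float(np.mean(vals))
        # gene FC and pseudo-genes
        pseudo = sc.assign_pseudogenes(gcm.nontargeting_ids, seed=seed)
        fc = {}
        for gene in sorted(set(gcm.guides["gene"]) - {sc.NONTARGETING}):
            members = gcm.guides.index[gcm.guides["gene"] == gene]
            fc[gene] = float(np.mean([l2fc[g] for g in members]))
        pseudo_fc = {
            name: float(np.mean([l2fc[g] for g in members]))
            for name, members in pseudo.sets.items()
        }
        mu = float(np.mean(list(pseudo_fc.values())))
        sdev = float(np.std(list(pseudo_fc.values()), ddof=1))
        z = {gene: (v - mu) / sdev for gene, v in fc.items()}
        return factors, l2fc, fc, z

    def test_stagewise_match(self):
        truth = sd.ScreenTruth(
            n_genes=3, n_nontargeting=8, depth=100.0, dispersion=0.5,
            essential_fraction=0.0, seed=11,
        )
        library = sd.gen_crispr_library(truth)  # 12 + 8 = 20 guides
        gcm = sd.gen_screen_counts(library, truth, sd.default_screen_samples(("drug",)))
        factors_bf, l2fc_bf, fc_bf, z_bf = self._brute_force(gcm, seed=5)

        factors = sc.size_factors(gcm.counts)
        for s, v in factors_bf.items():
            assert factors[s] == pytest.approx(v, abs=1e-12)
        l2fc = sc.guide_l2fc(gcm, "dead", "live", "drug", factors=factors)
        for g, v in l2fc_bf.items():
            assert l2fc.loc[g, "l2fc"] == pytest.approx(v, abs=1e-12)
        pseudo = sc.assign_pseudogenes(gcm.nontargeting_ids, seed=5)
        genes = sc.gene_scores(l2fc, pseudo)
        for gene, v in fc_bf.items():
            assert genes.loc[gene, "fc"] == pytest.approx(v, abs=1e-12)
        z = sc.zscore_genes(genes["fc"], genes.loc[genes["is_pseudo"], "fc"])
        for gene, v in z_bf.items():
            assert z[gene] == pytest.approx(v, abs=1e-12)
        # BH against a transparent step-up implementation
        p = np.array([0.02, 0.8, 0.04, 0.5])
        n = len(p)
        order = np.argsort(p)
        stepped = np.minimum.accumulate((p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
        expected = np.empty(n)
        expected[order] = np.minimum(stepped, 1.0)
        assert np.allclose(sc.bh_fdr(p), expected, atol=1e-12)


class TestScoreScreenPipeline:
    def test_planted_effect_recovery_rank_order(self):
        effects = {f"GENE{i:03d}": e for i, e in
                   zip(range(101, 113), [-4, -3, -2, -1, -0.5, -0.25, 0.25, 0.5, 1, 2, 3, 4])}
        truth = sd.ScreenTruth(n_genes=300, death_modifier_genes=effects, seed=2)
        library = sd.gen_crispr_library(truth)
        gcm = sd.gen_screen_counts(library, truth, sd.default_screen_samples(("drug",)))
        results = sc.score_screen(gcm, B=500, seed=2)
        table = results.gene_table("dead_vs_live_drug")
        from scipy.stats import spearmanr

        planted = list(effects)
        rho = spearmanr([effects[g] for g in planted], table.loc[planted, "zl2fc"]).statistic
        assert rho >= 0.95

    @pytest.fixture
    def noisy_screen(self):
        truth = sd.ScreenTruth(n_genes=50, dispersion=0.2, seed=6,
                               death_modifier_genes={"GENE01": 2.0})
        library = sd.gen_crispr_library(truth)
        return sd.gen_screen_counts(library, truth, sd.default_screen_samples(("drug",)))

    def test_pseudo_gene_null_self_consistency(self, noisy_screen):
        results = sc.score_screen(noisy_screen, B=200, seed=0)
        table = results.tables["dead_vs_live_drug"]
        pseudo_z = table.loc[table["is_pseudo"], "zl2fc"]
        assert pseudo_z.mean() == pytest.approx(0.0, abs=1e-12)
        assert pseudo_z.std(ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_determinism(self, noisy_screen):
        a = sc.score_screen(noisy_screen, B=100, seed=3).tables["dead_vs_live_drug"]
        b = sc.score_screen(noisy_screen, B=100, seed=3).tables["dead_vs_live_drug"]
        pd.testing.assert_frame_equal(a, b)

    def test_zero_noise_screen_null_is_degenerate(self):
        # with dispersion 0 every non-targeting guide has identical counts, so
        # the pseudo-gene null collapses and z-scoring must refuse
        truth = sd.ScreenTruth(n_genes=5, n_nontargeting=8, dispersion=0.0,
                               essential_fraction=0.0, seed=0)
        library = sd.gen_crispr_library(truth)
        gcm = sd.gen_screen_counts(library, truth, sd.default_screen_samples(("drug",)))
        with pytest.raises(DegenerateNullError):
            sc.score_screen(gcm, B=100, seed=0)

    def test_unknown_pool_rejected(self, toy_screen):
        _, _, gcm = toy_screen
        with pytest.raises(InvalidInputError):
            sc.score_screen(gcm, pool="everything")
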