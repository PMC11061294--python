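"""Tests of NB differential expression and modification-expression integration."""

import numpy as np
import pandas as pd
import pytest

from ct5hmc import (
    CohortConfig,
    NegativeBinomialDE,
    ValidationError,
    estimate_size_factors,
    fit_nb_de,
    hm_expression_correlation,
    module_score,
    normalize_log1p,
    promoter_genebody_odds,
    simulate_counts,
    simulate_samples,
)

from conftest import two_group_config


def de_cohort(n_genes=2000, n_up=100, n_down=100, seed=31, dispersion=0.1,
              baseline_mean=100.0, lfc=1.0):
    cfg = two_group_config(n_probes=10, n_genes=n_genes, seed=seed,
                           nb_dispersion=dispersion)
    sheet, comp = simulate_samples(cfg)
    genes = cfg.gene_ids()
    de_truth = pd.DataFrame({"TUM": np.zeros(n_genes)}, index=genes)
    de_truth.iloc[:n_up, 0] = lfc
    de_truth.iloc[n_up:n_up + n_down, 0] = -lfc
    counts = simulate_counts(cfg, sheet, de_truth=de_truth,
                             baseline=np.full(n_genes, baseline_mean))
    return cfg, sheet, comp, counts, genes


class TestSizeFactors:
    def test_doubled_sample(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        sf = estimate_size_factors(counts)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)

    def test_identical_samples_equal_factors(self):
        counts = pd.DataFrame({"a": [10, 20], "b": [10, 20], "c": [10, 20]})
        sf = estimate_size_factors(counts)
        assert np.allclose(sf, sf.iloc[0])

    def test_matches_median_of_ratios_oracle(self, rng):
        counts = pd.DataFrame(rng.poisson(50, size=(200, 6)) + 1)
        sf = estimate_size_factors(counts)
        logmat = np.log(counts.to_numpy(float))
        ref = logmat.mean(axis=1)
        oracle = np.exp(np.median(logmat - ref[:, None], axis=0))
        assert np.allclose(sf.to_numpy(), oracle, atol=1e-12)

    def test_scale_equivariance(self, rng):
        # scaling one sample's counts by c scales its factor relative to the
        # other samples by c (the pseudo-reference rescales with it)
        counts = pd.DataFrame(rng.poisson(50, size=(100, 4)) + 1)
        scaled = counts.copy()
        scaled.iloc[:, 0] = (scaled.iloc[:, 0] * 3).astype(int)
        a = estimate_size_factors(counts)
        b = estimate_size_factors(scaled)
        rel_a = a.iloc[0] / a.iloc[1]
        rel_b = b.iloc[0] / b.iloc[1]
        assert rel_b / rel_a == pytest.approx(3.0)

    def test_no_common_positive_gene_rejected(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValidationError, match="pseudo-reference"):
            estimate_size_factors(counts)


class TestNegativeBinomialDE:
    def test_planted_fold_change_recovered(self):
        _, sheet, _, counts, genes = de_cohort()
        res = fit_nb_de(counts, sheet, "TUM").set_index("gene_id")
        up, down = genes[:100], genes[100:200]
        assert abs(res.loc[up, "log2fc"].mean() - 1.0) <= 0.1
        assert abs(res.loc[down, "log2fc"].mean() + 1.0) <= 0.1

    def test_null_few_discoveries(self):
        # well-powered null regime: moderate dispersion, deep counts
        _, sheet, _, counts, genes = de_cohort(n_up=0, n_down=0, seed=77,
                                               dispersion=0.02, baseline_mean=500.0)
        res = fit_nb_de(counts, sheet, "TUM")
        assert res["log2fc"].abs().mean() <= 0.1
        assert (res["p_adj"] < 0.05).mean() <= 0.07

    def test_poisson_limit_matches_statsmodels(self):
        import statsmodels.api as sm

        _, sheet, _, counts, _ = de_cohort(n_genes=100, n_up=0, n_down=0,
                                           dispersion=1e-9, baseline_mean=500.0,
                                           seed=7)
        model = NegativeBinomialDE(dispersion=0.0)
        model.fit(counts, sheet, "TUM")
        x = model.design_.to_numpy()
        offset = np.log(model.size_factors_.loc[model.design_.index].to_numpy())
        for i in range(0, 100, 10):
            y = counts.iloc[i][model.design_.index].to_numpy()
            ref = sm.GLM(y, x, family=sm.families.Poisson(), offset=offset).fit()
            wald_ref = ref.params[1] / ref.bse[1]
            assert model.results_["wald"].iloc[i] == pytest.approx(wald_ref, rel=0.05)

    def test_agrees_with_pydeseq2_on_small_fixture(self):
        """Independent cross-check of fold changes against a reference NB fitter."""
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        _, sheet, _, counts, genes = de_cohort(n_genes=60, n_up=10, n_down=0,
                                               seed=13, baseline_mean=200.0)
        meta = pd.DataFrame({"condition": sheet["group"]})
        dds = DeseqDataSet(counts=counts.T, metadata=meta,
                           design="~condition", quiet=True)
        dds.deseq2()
        ds = DeseqStats(dds, contrast=["condition", "TUM", "NonTumor"], quiet=True)
        ds.summary()
        ref = ds.results_df["log2FoldChange"]
        mine = fit_nb_de(counts, sheet, "TUM", covariates=()).set_index("gene_id")["log2fc"]
        assert np.corrcoef(mine.loc[ref.index], ref)[0, 1] > 0.98
        assert abs((mine.loc[genes[:10]] - ref.loc[genes[:10]]).mean()) < 0.2

    def test_all_zero_gene_flagged_missing(self):
        _, sheet, _, counts, genes = de_cohort(n_genes=50, n_up=0, n_down=0, seed=5)
        counts.iloc[0] = 0
        res = fit_nb_de(counts, sheet, "TUM")
        assert np.isnan(res["log2fc"].iloc[0])

    def test_non_integer_counts_rejected(self, small_cohort):
        bad = small_cohort.counts.astype(float) + 0.5
        with pytest.raises(ValidationError):
            fit_nb_de(bad, small_cohort.sheet, "TUM")


class TestIntegration:
    def test_perfect_negative_correlation(self, tiny_annotation):
        dm = pd.DataFrame({"probe_id": ["cg0", "cg1", "cg3", "cg4"],
                           "coefficient": [-0.2, -0.1, 0.1, 0.2]})
        de = pd.DataFrame({"gene_id": ["GA", "GB", "GC"],
                           "log2fc": [1.0, -0.5, -1.0],
                           "p_adj": [0.01, 0.01, 0.01]})
        # remap: cg0->GA(-0.2,1.0) cg1->GA,GB cg3->GB cg4->GC
        out = hm_expression_correlation(dm, de, tiny_annotation)
        assert len(out["pairs"]) == 5
        assert out["all"]["defined"]

    def test_hand_computed_pearson(self, tiny_annotation):
        ann = tiny_annotation.copy()
        ann["genes"] = ["G1", "G2", "G3", "G4", "", ""]
        dm = pd.DataFrame({"probe_id": ["cg0", "cg1", "cg2", "cg3"],
                           "coefficient": [-0.2, -0.1, 0.1, 0.2]})
        de = pd.DataFrame({"gene_id": ["G1", "G2", "G3", "G4"],
                           "log2fc": [1.0, 0.5, -0.5, -1.0],
                           "p_adj": [0.01] * 4})
        out = hm_expression_correlation(dm, de, ann)
        assert out["all"]["r"] == pytest.approx(-1.0)

    def test_constant_vector_flagged(self, tiny_annotation):
        ann = tiny_annotation.copy()
        ann["genes"] = ["G1", "G2", "G3", "", "", ""]
        dm = pd.DataFrame({"probe_id": ["cg0", "cg1", "cg2"],
                           "coefficient": [-0.2, -0.1, 0.1]})
        de = pd.DataFrame({"gene_id": ["G1", "G2", "G3"],
                           "log2fc": [0.5, 0.5, 0.5], "p_adj": [0.01] * 3})
        out = hm_expression_correlation(dm, de, ann)
        assert not out["all"]["defined"]


class TestPromoterOdds:
    def make_hits(self, table, annotation):
        """Build a hit table realizing 2x2 counts (a,b,c,d) on promoter flags."""
        a, b, c, d = table
        ann = annotation.copy()
        probes_ctx = ["cg0", "cg1"]      # TSS-flagged probes
        probes_non = ["cg2", "cg4"]
        rows = []
        for _ in range(a):
            rows.append({"probe_id": probes_ctx[0], "expression_direction": "increased"})
        for _ in range(b):
            rows.append({"probe_id": probes_non[0], "expression_direction": "increased"})
        for _ in range(c):
            rows.append({"probe_id": probes_ctx[1], "expression_direction": "decreased"})
        for _ in range(d):
            rows.append({"probe_id": probes_non[1], "expression_direction": "decreased"})
        return pd.DataFrame(rows), ann

    def test_balanced_table_gives_or_one(self, tiny_annotation):
        hits, ann = self.make_hits((5, 5, 5, 5), tiny_annotation)
        out = promoter_genebody_odds(hits, ann)
        assert out["promoter"]["odds_ratio"] == pytest.approx(1.0)

    def test_cross_product_hand_example(self, tiny_annotation):
        hits, ann = self.make_hits((2, 8, 8, 2), tiny_annotation)
        out = promoter_genebody_odds(hits, ann)
        assert out["promoter"]["odds_ratio"] == pytest.approx(0.0625)
        assert out["promoter"]["table"] == (2, 8, 8, 2)

    def test_haldane_correction_on_zero_cell(self, tiny_annotation):
        hits, ann = self.make_hits((0, 10, 5, 5), tiny_annotation)
        out = promoter_genebody_odds(hits, ann)
        assert out["promoter"]["odds_ratio"] == pytest.approx(
            (0.5 * 5.5) / (10.5 * 5.5), abs=1e-6)

    def test_empty_direction_group_rejected(self, tiny_annotation):
        hits = pd.DataFrame({"probe_id": ["cg0"], "expression_direction": ["increased"]})
        with pytest.raises(ValidationError):
            promoter_genebody_odds(hits, tiny_annotation)


class TestModuleScore:
    def make_expression(self, rng, n_cells=300, n_genes=600):
        genes = [f"G{i:04d}" for i in range(n_genes)]
        return pd.DataFrame(rng.normal(2.0, 1.0, size=(n_cells, n_genes)),
                            index=[f"C{i}" for i in range(n_cells)], columns=genes)

    def test_background_set_scores_near_zero(self, rng):
        expr = self.make_expression(rng)
        gene_set = list(rng.choice(expr.columns, 40, replace=False))
        res = module_score(expr, gene_set, seed=1)
        assert abs(res["scores"].mean()) <= 0.05

    def test_planted_shift_recovered(self, rng):
        expr = self.make_expression(rng)
        gene_set = list(rng.choice(expr.columns, 40, replace=False))
        expr.loc[expr.index[:150], gene_set] += 1.0
        meta = pd.DataFrame({"cell_type": "NEU",
                             "group": ["TUM"] * 150 + ["NT"] * 150},
                            index=expr.index)
        res = module_score(expr, gene_set, cell_meta=meta, seed=1)
        shifted = res["scores"].iloc[:150].mean()
        rest = res["scores"].iloc[150:].mean()
        assert shifted - rest == pytest.approx(1.0, abs=0.1)
        assert res["group_comparisons"]["NEU"]["p"] < 1e-6

    def test_deterministic_and_order_invariant(self, rng):
        expr = self.make_expression(rng, n_cells=50, n_genes=200)
        gene_set = list(rng.choice(expr.columns, 20, replace=False))
        a = module_score(expr, gene_set, seed=7)["scores"]
        b = module_score(expr, list(reversed(gene_set)), seed=7)["scores"]
        assert np.allclose(a, b)

    def test_degenerate_modes_rejected(self, rng):
        expr = self.make_expression(rng, n_cells=20, n_genes=100)
        with pytest.raises(ValidationError):
            module_score(expr, ["not_a_gene"], seed=0)
        from ct5hmc import ModuleScorer
        with pytest.raises(ValidationError):
            ModuleScorer(n_ctrl=0).fit(expr)


def test_normalize_log1p_depth_invariance(rng):
    counts = pd.DataFrame(rng.poisson(20, size=(50, 4)) + 1)
    doubled = counts * 2
    a = normalize_log1p(counts)
    b = normalize_log1p(doubled)
    assert np.allclose(a, b)
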