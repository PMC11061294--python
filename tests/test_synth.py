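"""Tests of the synthetic cohort generator: determinism, ranges, ground truth."""

import numpy as np
import pandas as pd
import pytest

from ct5hmc import (
    CohortConfig,
    ConfigurationError,
    ValidationError,
    make_truth_table,
    plant_effects,
    render_measurements,
    simulate_annotation,
    simulate_cohort,
    simulate_counts,
    simulate_nuclei,
    simulate_reference_profiles,
    simulate_samples,
)

from conftest import two_group_config


class TestReferenceProfiles:
    def test_prevalence_ratio_tracks_config(self):
        prof = simulate_reference_profiles(CohortConfig(n_probes=10_000, seed=1))
        ratio = prof["5hmC"].mean().mean() / prof["5mC"].mean().mean()
        assert 0.048 <= ratio <= 0.072  # within 20% of 6%

    def test_vanishing_ratio_limit(self):
        prof = simulate_reference_profiles(
            CohortConfig(n_probes=1000, hmc_to_mc_ratio=1e-9, seed=1)
        )
        assert prof["5hmC"].to_numpy().max() < 1e-6
        total = prof["5mC"].to_numpy() + prof["5hmC"].to_numpy()
        assert (total <= 1 + 1e-12).all()

    def test_simplex_constraint(self):
        prof = simulate_reference_profiles(CohortConfig(n_probes=3000, seed=5))
        m, h = prof["5mC"].to_numpy(), prof["5hmC"].to_numpy()
        assert (m >= 0).all() and (h >= 0).all() and (m + h <= 1 + 1e-12).all()

    def test_deterministic_given_seed(self):
        cfg = CohortConfig(n_probes=500, seed=9)
        a = simulate_reference_profiles(cfg)
        b = simulate_reference_profiles(cfg)
        pd.testing.assert_frame_equal(a["5mC"], b["5mC"])
        pd.testing.assert_frame_equal(a["5hmC"], b["5hmC"])

    @pytest.mark.parametrize(
        "field,value",
        [("n_probes", 0), ("hmc_to_mc_ratio", 0.0), ("hmc_to_mc_ratio", 1.5),
         ("measurement_precision", -1.0), ("nb_dispersion", 0.0)],
    )
    def test_invalid_config_names_field(self, field, value):
        with pytest.raises(ConfigurationError, match=field.split("_")[0]):
            simulate_reference_profiles(CohortConfig(**{field: value}))


class TestSamples:
    def test_compositions_on_simplex(self):
        _, comp = simulate_samples(two_group_config())
        sums = comp.to_numpy().sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)
        assert (comp.to_numpy() >= 0).all()

    def test_concentration_limit_equal_shares(self):
        cfg = CohortConfig(
            cell_types=("A", "B"),
            groups={"g1": 10, "g2": 10},
            dirichlet_concentrations={"g1": (1e6, 1e6), "g2": (1e6, 1e6)},
        )
        _, comp = simulate_samples(cfg)
        assert np.allclose(comp.to_numpy(), 0.5, atol=1e-2)

    def test_single_cell_type_composition_is_one(self):
        cfg = CohortConfig(
            cell_types=("only",),
            groups={"g1": 5, "g2": 5},
            dirichlet_concentrations={"g1": (1.0,), "g2": (1.0,)},
        )
        _, comp = simulate_samples(cfg)
        assert (comp.to_numpy() == 1.0).all()

    def test_sample_counts_respected(self):
        sheet, comp = simulate_samples(two_group_config())
        assert len(sheet) == 20 and len(comp) == 20

    def test_single_group_rejected(self):
        cfg = CohortConfig(groups={"only": 5},
                           dirichlet_concentrations={"only": (1, 1, 1, 1, 1, 1)})
        with pytest.raises(ConfigurationError):
            simulate_samples(cfg)


class TestPlantEffects:
    def test_empty_truth_leaves_profiles_unchanged(self):
        cfg = two_group_config(n_probes=100)
        prof = simulate_reference_profiles(cfg)
        out, report = plant_effects(make_truth_table([]), prof, ["NonTumor", "TUM"])
        pd.testing.assert_frame_equal(out["TUM"]["5hmC"], prof["5hmC"])
        assert report.empty

    def test_clipping_reported(self):
        prof = {
            "5mC": pd.DataFrame({"A": [0.3]}, index=pd.Index(["p1"], name="probe_id")),
            "5hmC": pd.DataFrame({"A": [0.2]}, index=pd.Index(["p1"], name="probe_id")),
        }
        truth = make_truth_table(
            [{"probe_id": "p1", "cell_type": "A", "group": "g",
              "delta_5hmC": -0.3, "delta_5mC": 0.0}]
        )
        out, report = plant_effects(truth, prof, ["g"])
        assert out["g"]["5hmC"].at["p1", "A"] == 0.0
        assert len(report) == 1 and report.iloc[0]["realized"] == -0.2

    def test_in_range_delta_is_exact(self):
        prof = {
            "5mC": pd.DataFrame({"A": [0.3]}, index=pd.Index(["p1"], name="probe_id")),
            "5hmC": pd.DataFrame({"A": [0.1]}, index=pd.Index(["p1"], name="probe_id")),
        }
        truth = make_truth_table(
            [{"probe_id": "p1", "cell_type": "A", "group": "g",
              "delta_5hmC": 0.2, "delta_5mC": 0.0}]
        )
        out, report = plant_effects(truth, prof, ["g"])
        assert out["g"]["5hmC"].at["p1", "A"] == pytest.approx(0.3)
        assert out["g"]["5mC"].at["p1", "A"] == pytest.approx(0.3)
        assert report.empty

    def test_unknown_probe_rejected(self):
        cfg = two_group_config(n_probes=10)
        prof = simulate_reference_profiles(cfg)
        truth = make_truth_table(
            [{"probe_id": "nope", "cell_type": "bulk", "group": "TUM",
              "delta_5hmC": 0.1, "delta_5mC": 0.0}]
        )
        with pytest.raises(ValidationError):
            plant_effects(truth, prof, ["NonTumor", "TUM"])

    def test_duplicate_truth_entries_rejected(self):
        rec = {"probe_id": "p", "cell_type": "A", "group": "g",
               "delta_5hmC": 0.1, "delta_5mC": 0.0}
        with pytest.raises(ValidationError):
            make_truth_table([rec, rec])


class TestRenderMeasurements:
    def test_degenerate_mixture_matches_single_cell_type(self):
        cfg = CohortConfig(
            n_probes=50, cell_types=("A", "B"),
            groups={"g1": 2, "g2": 2},
            dirichlet_concentrations={"g1": (1, 1), "g2": (1, 1)},
            measurement_precision=1e9,
        )
        prof = simulate_reference_profiles(cfg)
        sheet, _ = simulate_samples(cfg)
        comp = pd.DataFrame(
            [[1.0, 0.0]] * 4, index=sheet.index, columns=["A", "B"]
        )
        out = render_measurements(
            {g: prof for g in ("g1", "g2")}, comp, sheet, cfg
        )
        expected = prof["5mC"]["A"].to_numpy()
        assert np.allclose(out["true_m"].to_numpy()[:, 0], expected)

    def test_noise_free_limit(self):
        cfg = two_group_config(n_probes=200, measurement_precision=1e9)
        co = simulate_cohort(cfg)
        assert np.allclose(
            co.bs.to_numpy(),
            np.clip(co.true_m.to_numpy() + co.true_h.to_numpy(), 1e-6, 1 - 1e-6),
            atol=1e-3,
        )

    def test_mixture_arithmetic(self):
        idx = pd.Index(["p1"], name="probe_id")
        prof = {
            "5mC": pd.DataFrame({"A": [0.2], "B": [0.6]}, index=idx),
            "5hmC": pd.DataFrame({"A": [0.0], "B": [0.0]}, index=idx),
        }
        sheet = pd.DataFrame({"group": ["g"]}, index=pd.Index(["s1"], name="sample_id"))
        comp = pd.DataFrame([[0.5, 0.5]], index=sheet.index, columns=["A", "B"])
        cfg = CohortConfig(n_probes=1, cell_types=("A", "B"),
                           groups={"g": 1, "h": 1},
                           dirichlet_concentrations={"g": (1, 1), "h": (1, 1)})
        out = render_measurements({"g": prof}, comp, sheet, cfg)
        assert out["true_m"].iat[0, 0] == pytest.approx(0.4)

    def test_off_simplex_composition_rejected(self):
        cfg = two_group_config(n_probes=20)
        co = simulate_cohort(cfg)
        bad = co.composition * 1.1
        with pytest.raises(ValidationError, match="composition"):
            render_measurements(co.group_profiles, bad, co.sheet, cfg)

    def test_outputs_in_unit_interval(self, small_cohort):
        for mat in (small_cohort.bs, small_cohort.ox):
            v = mat.to_numpy()
            assert (v >= 0).all() and (v <= 1).all()


class TestCounts:
    def test_null_groups_similar_means(self):
        cfg = two_group_config(n_genes=500, seed=3)
        sheet, _ = simulate_samples(cfg)
        counts = simulate_counts(cfg, sheet, baseline=np.full(500, 100.0))
        tum = counts[sheet.index[sheet.group == "TUM"]].to_numpy().mean()
        nt = counts[sheet.index[sheet.group == "NonTumor"]].to_numpy().mean()
        assert abs(tum / nt - 1) < 0.05

    def test_poisson_limit_variance_over_mean(self):
        cfg = two_group_config(n_genes=5000, nb_dispersion=1e-9, seed=42)
        sheet, _ = simulate_samples(cfg)
        counts = simulate_counts(cfg, sheet, baseline=np.full(5000, 50.0))
        v = counts.to_numpy().var(axis=1, ddof=1) / counts.to_numpy().mean(axis=1)
        assert abs(np.mean(v) - 1.0) < 0.05

    def test_size_factor_doubles_counts(self):
        cfg = two_group_config(n_genes=2000, seed=8)
        sheet, _ = simulate_samples(cfg)
        sf = pd.Series(1.0, index=sheet.index)
        sf.iloc[0] = 2.0
        counts = simulate_counts(cfg, sheet, baseline=np.full(2000, 100.0),
                                 size_factors=sf)
        ratio = counts.iloc[:, 0].mean() / counts.iloc[:, 1].mean()
        assert abs(ratio - 2.0) < 0.15


class TestNuclei:
    def test_zero_error_rates_calls_match_truth(self):
        rec = simulate_nuclei(200, ["S1", "S2", "S3"], seed=1)
        assert (rec["hto_call"] == rec["true_sample"]).all()
        assert (rec["genotype_call"] == rec["true_sample"]).all()

    def test_requested_count(self):
        assert len(simulate_nuclei(100, ["S1", "S2"], seed=2)) == 100

    def test_doublet_rate_one(self):
        rec = simulate_nuclei(50, ["S1", "S2"], {"hto_doublet": 1.0}, seed=3)
        assert (rec["hto_call"] == "Doublet").all()


class TestAnnotation:
    def test_context_probability_extremes(self):
        cfg = two_group_config(n_probes=300)
        probs = dict(cfg.context_probs)
        probs["DHS"] = 0.0
        probs["gene_body"] = 1.0
        ann = simulate_annotation(two_group_config(n_probes=300, context_probs=probs))
        assert ann["DHS"].sum() == 0
        assert ann["gene_body"].sum() == 300

    def test_deterministic(self):
        cfg = two_group_config(n_probes=100)
        pd.testing.assert_frame_equal(simulate_annotation(cfg), simulate_annotation(cfg))


class TestPlantedEffectRecovery:
    def test_bs_minus_ox_converges_to_planted_bulk_delta(self):
        """Averaging BS - oxBS over affected samples recovers the bulk-level delta."""
        from conftest import plant_bulk_effects

        cfg = two_group_config(n_probes=2000, measurement_precision=2000.0,
                               groups={"NonTumor": 30, "TUM": 30}, seed=17)
        truth, probes = plant_bulk_effects(cfg, 100, 0.2, seed=2)
        co = simulate_cohort(cfg, truth=truth)
        tum = co.sheet.index[co.sheet.group == "TUM"]
        nt = co.sheet.index[co.sheet.group == "NonTumor"]
        diff = (co.bs - co.ox)
        observed = (diff.loc[probes, tum].mean(axis=1)
                    - diff.loc[probes, nt].mean(axis=1)).mean()
        assert observed == pytest.approx(0.2, abs=0.02)


def test_full_cohort_determinism():
    cfg = two_group_config(n_probes=150, n_genes=50)
    a, b = simulate_cohort(cfg), simulate_cohort(cfg)
    pd.testing.assert_frame_equal(a.bs, b.bs)
    pd.testing.assert_frame_equal(a.counts, b.counts)
    pd.testing.assert_frame_equal(a.annotation, b.annotation)
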