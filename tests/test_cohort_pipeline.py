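"""Cohort loading, derived indices, summary, stratification, full analysis, CLI."""

import json

import numpy as np
import pandas as pd
import pytest

from metavol import (
    AnalysisConfig,
    CohortAnalysis,
    CohortGenParams,
    dichotomize_and_compare,
    derive_indices,
    generate_cohort,
    load_cohort,
    run_full_analysis,
    summarize_cohort,
    reference_cohort,
)
from metavol.cli import main as cli_main


class TestLoadCohort:
    def test_well_formed_file_loads_all_rows(self, tmp_path, simulated_cohort):
        df, _ = simulated_cohort
        path = tmp_path / "c.csv"
        df.head(3).to_csv(path, index=False)
        loaded = load_cohort(path)
        assert len(loaded) == 3

    def test_row_violating_count_invariant_rejected_with_diagnostic(
        self, tmp_path, simulated_cohort
    ):
        df, _ = simulated_cohort
        bad = df.head(4).copy()
        bad.loc[1, "lymphocytes_per_mm3"] = bad.loc[1, "wbc_per_mm3"] + 500
        path = tmp_path / "c.csv"
        bad.to_csv(path, index=False)
        loaded = load_cohort(path)
        assert len(loaded) == 3
        rejected = loaded.attrs["rejected_rows"]
        assert len(rejected) == 1
        assert "lymphocytes_per_mm3 > wbc_per_mm3" in rejected[0]["problems"]

    def test_missing_required_column_fails(self, tmp_path, simulated_cohort):
        df, _ = simulated_cohort
        path = tmp_path / "c.csv"
        df.drop(columns=["hi2"]).to_csv(path, index=False)
        with pytest.raises(ValueError, match="hi2"):
            load_cohort(path)

    def test_unknown_column_warns_but_loads(self, tmp_path, simulated_cohort):
        df, _ = simulated_cohort
        extra = df.head(3).copy()
        extra["mystery"] = 1
        path = tmp_path / "c.csv"
        extra.to_csv(path, index=False)
        with pytest.warns(UserWarning, match="mystery"):
            loaded = load_cohort(path)
        assert len(loaded) == 3


class TestDerivedIndices:
    def make(self, **kw):
        base = dict(
            neutrophils_per_mm3=6000.0, lymphocytes_per_mm3=1500.0,
            wbc_per_mm3=8800.0, platelets_per_mm3=300000.0, albumin_g_per_dl=3.5,
        )
        base.update(kw)
        return pd.DataFrame([base])

    def test_nlr(self):
        out = derive_indices(self.make())
        assert out["nlr"].iloc[0] == pytest.approx(4.0)

    def test_dnlr(self):
        out = derive_indices(self.make(neutrophils_per_mm3=5800.0))
        assert out["dnlr"].iloc[0] == pytest.approx(5800.0 / 3000.0, abs=1e-3)

    def test_pni_standard_scale(self):
        out = derive_indices(self.make(lymphocytes_per_mm3=1300.0))
        assert out["pni"].iloc[0] == pytest.approx(35.0 + 6.5)

    def test_sii(self):
        out = derive_indices(self.make())
        assert out["sii"].iloc[0] == pytest.approx(300000.0 * 6000.0 / 1500.0)

    def test_zero_denominator_gives_missing_not_infinite(self):
        out = derive_indices(self.make(lymphocytes_per_mm3=0.0))
        assert np.isnan(out["nlr"].iloc[0])
        assert np.isnan(out["sii"].iloc[0])


class TestSummarizeCohort:
    def test_reference_margins_reproduced_exactly(self, reference_cohort):
        from metavol.fixtures import load_demographics

        summary = summarize_cohort(reference_cohort).set_index(["variable", "category"])
        expected = load_demographics()
        # every row of the packaged demographic table present in the summary
        checked = 0
        for _, row in expected.iterrows():
            key = (row["variable"], row["category"])
            if key not in summary.index:
                continue  # complement categories are implied by their pair
            got = summary.loc[key]
            assert got["count"] == row["count"], key
            assert got["percent"] == pytest.approx(row["percent"], abs=0.05), key
            checked += 1
        assert checked >= 20

    def test_mortality_rate_among_relapsed(self, reference_cohort):
        summary = summarize_cohort(reference_cohort)
        row = summary[summary["variable"] == "mortality_in_relapsed"].iloc[0]
        assert row["count"] == 21 and row["denominator"] == 29
        assert row["percent"] == 72.4

    def test_missing_values_reduce_denominator(self, reference_cohort):
        summary = summarize_cohort(reference_cohort)
        ki67 = summary[summary["variable"] == "ki67"].iloc[0]
        assert ki67["denominator"] == 58
        assert ki67["count"] == 37 and ki67["percent"] == 63.8

    def test_all_male_toy_cohort(self, simulated_cohort):
        df, _ = simulated_cohort
        toy = df.head(10).copy()
        toy["sex"] = "M"
        summary = summarize_cohort(toy).set_index(["variable", "category"])
        assert summary.loc[("sex", "male"), "percent"] == 100.0

    def test_percentages_consistent_with_counts(self, simulated_cohort):
        df, _ = simulated_cohort
        summary = summarize_cohort(df)
        for _, row in summary.iterrows():
            assert row["percent"] == pytest.approx(
                round(100.0 * row["count"] / row["denominator"], 1)
            )


class TestDichotomize:
    def test_strong_effect_gives_significant_logrank(self):
        df, _ = generate_cohort(CohortGenParams(n=2000, seed=4))
        comp = dichotomize_and_compare(df, "suvmax_liver", 22.0, "low_positive", "OS")
        assert comp.estimable
        assert comp.logrank_p < 0.05
        # low liver SUVmax carries the mortality excess
        assert comp.mean_low.mean_months < comp.mean_high.mean_months

    def test_cutoff_below_all_values_not_estimable(self, simulated_cohort):
        df, _ = simulated_cohort
        comp = dichotomize_and_compare(df, "suvmax_liver", -1.0, "low_positive", "OS")
        assert not comp.estimable
        assert np.isnan(comp.logrank_p)

    def test_permuted_outcomes_calibrated_null(self, simulated_cohort, rng):
        # permuting (time, event) jointly severs the marker-outcome link
        df, _ = simulated_cohort
        sub = df.head(150).copy()
        nonsig = 0
        for _ in range(100):
            perm = rng.permutation(len(sub))
            sub["death"] = sub["death"].to_numpy()[perm]
            sub["os_months"] = sub["os_months"].to_numpy()[perm]
            comp = dichotomize_and_compare(sub, "suvmax_liver", 22.0,
                                           "low_positive", "OS")
            nonsig += comp.logrank_p > 0.05
        assert nonsig >= 90


@pytest.fixture(scope="module")
def fitted():
    df, _ = generate_cohort(CohortGenParams(n=600, seed=9))
    return CohortAnalysis(df).fit()


class TestFullAnalysis:
    def test_no_stage_errors_on_clean_cohort(self, fitted):
        assert fitted.report.errors == []

    def test_effect_directions_match_generating_model(self, fitted):
        logi = fitted.report.logistic_tables["OS"]
        uni = logi[logi["model"] == "univariate"].set_index("variable")
        assert uni.loc["suvmax_liver", "odds_ratio"] > 1  # low liver SUV -> death
        assert uni.loc["hi2", "odds_ratio"] > 1           # high HI2 -> death

    def test_multivariate_block_contains_significant_markers(self, fitted):
        logi = fitted.report.logistic_tables["OS"]
        multi = logi[logi["model"] == "multivariate"]
        assert {"suvmax_liver", "hi2"} <= set(multi["variable"])

    def test_roc_recovers_generating_cutoffs_within_grid_step(self):
        df, _ = generate_cohort(CohortGenParams(n=2000, seed=13))
        rep = run_full_analysis(df)
        roc_os = rep.roc_tables["OS"].set_index("variable")
        # liver SUVmax is integer-valued, so one grid step is 1 unit
        assert abs(roc_os.loc["suvmax_liver", "best_cutoff"] - 22.0) <= 1.0
        roc_rfs = rep.roc_tables["RFS"].set_index("variable")
        assert roc_rfs.loc["hi2", "auc"] > 0.5

    def test_report_json_round_trip_and_determinism(self, fitted):
        df, _ = generate_cohort(CohortGenParams(n=200, seed=21))
        r1 = run_full_analysis(df)
        r2 = run_full_analysis(df)
        assert r1.to_json() == r2.to_json()
        parsed = json.loads(r1.to_json())
        assert set(parsed) >= {"cohort_summary", "roc", "km", "logistic"}

    def test_null_cohort_false_positive_rate(self, null_cohort_params):
        markers = {"suvmax_liver": 0, "hi2": 0, "ldh_u_per_l": 0}
        n_seeds = 100
        for seed in range(n_seeds):
            df, _ = generate_cohort(null_cohort_params(150, seed=seed))
            rep = run_full_analysis(df)
            logi = rep.logistic_tables["OS"]
            uni = logi[logi["model"] == "univariate"].set_index("variable")
            for m in markers:
                if uni.loc[m, "converged"] and uni.loc[m, "p"] < 0.05:
                    markers[m] += 1
        for m, hits in markers.items():
            assert hits <= 0.10 * n_seeds, f"{m}: {hits} false positives"


class TestConfig:
    def test_flat_yaml_round_trip(self, tmp_path):
        cfg_file = tmp_path / "cfg.yaml"
        cfg_file.write_text(
            "marker_os_suvmax_liver: '20,low_positive'\n"
            "marker_os_hi2: '70,high_positive'\n"
            "alpha: 0.01\n"
        )
        cfg = AnalysisConfig.from_file(cfg_file)
        assert cfg.alpha == 0.01
        assert cfg.markers["OS"][0].value == 20.0
        assert cfg.markers["OS"][0].direction == "low_positive"


class TestCLI:
    def test_simulate_deterministic(self, tmp_path):
        out1, out2 = tmp_path / "r1", tmp_path / "r2"
        assert cli_main(["simulate", "--n", "100", "--seed", "7",
                         "--out", str(out1)]) == 0
        assert cli_main(["simulate", "--n", "100", "--seed", "7",
                         "--out", str(out2)]) == 0
        assert (out1 / "cohort.csv").read_bytes() == (out2 / "cohort.csv").read_bytes()

    def test_quantify_phantom(self, tmp_path, graded_phantom):
        volume, lesion, liver, truth = graded_phantom
        volume.to_nifti(tmp_path / "v.nii.gz")
        lesion.to_nifti(tmp_path / "l.nii.gz")
        liver.to_nifti(tmp_path / "h.nii.gz")
        out = tmp_path / "metrics.tsv"
        rc = cli_main([
            "quantify", "--volume", str(tmp_path / "v.nii.gz"),
            "--lesion", str(tmp_path / "l.nii.gz"),
            "--liver", str(tmp_path / "h.nii.gz"), "--out", str(out),
        ])
        assert rc == 0
        row = pd.read_csv(out, sep="\t").iloc[0]
        assert row["HI2"] == pytest.approx(truth.analytic_hi2, abs=1.0)
        assert row["suvmax_liver"] == pytest.approx(2.3)

    def test_analyze_writes_valid_json_report(self, tmp_path):
        sim = tmp_path / "sim"
        cli_main(["simulate", "--n", "150", "--seed", "3", "--out", str(sim)])
        rep = tmp_path / "rep"
        rc = cli_main(["analyze", "--cohort", str(sim / "cohort.csv"),
                       "--out", str(rep)])
        assert rc == 0
        report = json.loads((rep / "report.json").read_text())
        assert report["errors"] == []

    def test_fixtures_demographics_prints_male_row(self, capsys):
        assert cli_main(["fixtures", "--table", "demographics"]) == 0
        out = capsys.readouterr().out
        assert "male,41,58.6" in out

    def test_bad_arguments_nonzero_exit(self):
        assert cli_main(["quantify"]) != 0


class TestFixtures:
    def test_bundle_and_checksums_stable(self):
        from metavol.fixtures import fixture_checksums, package_fixtures

        bundle = package_fixtures()
        assert bundle["demographics"].shape[0] > 30
        t2 = bundle["mortality_categorical"].set_index(["variable", "category"])
        assert t2.loc[("relapse", "yes"), "mortality_pos_count"] == 21
        assert t2.loc[("relapse", "yes"), "mortality_neg_pct"] == 16.3
        t3 = bundle["mortality_logistic"].set_index("variable")
        assert t3.loc["suvmax_liver", "or_univariate"] == 8.000
        assert t3.loc["suvmax_liver", "ci_low_univariate"] == 2.080
        assert t3.loc["suvmax_liver", "ci_high_univariate"] == 30.763
        assert fixture_checksums() == fixture_checksums()

    def test_survival_summary_headline_numbers(self):
        from metavol.fixtures import load_survival_summary

        s = load_survival_summary()
        assert s["mean_os_months"] == 71.6 and s["mean_os_se"] == 7.4
        assert s["roc_mortality"]["suvmax_liver"]["auc"] == 0.726
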