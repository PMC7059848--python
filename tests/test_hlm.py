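import os
import shutil
import subprocess
import tempfile

import numpy as np
import pandas as pd
import pytest

from artispace.config import ModelConfig
from artispace.errors import FitError, IntegrityError
from artispace.hlm import assemble_dataset, build_design, descriptives, fit_hlm
from artispace.synth import CohortGenSpec, generate_cohort


def features_from(records):
    return records[["participant_id", "pair_id", "area_px"]].assign(
        articulation_time_s=records["duration"]
    )


def manifest_from(records):
    return records[["participant_id", "pair_id", "gender", "country", "age", "cr", "aq"]].assign(
        duration=records["duration"]
    )


class TestAssemble:
    def test_study_sized_cohort_joins_to_170_records(self):
        records, truth = generate_cohort(CohortGenSpec(seed=1))
        out = assemble_dataset(features_from(records), manifest_from(records))
        assert len(out) == 170
        assert truth["n_pairs"] == 85

    def test_duplicate_participant_rejected(self):
        records, _ = generate_cohort(CohortGenSpec(seed=1))
        manifest = manifest_from(records)
        dup = pd.concat([manifest, manifest.iloc[[0]]], ignore_index=True)
        with pytest.raises(IntegrityError, match="duplicate"):
            assemble_dataset(features_from(records), dup)

    def test_missing_feature_row_rejected(self):
        records, _ = generate_cohort(CohortGenSpec(seed=1))
        with pytest.raises(IntegrityError, match="without feature"):
            assemble_dataset(features_from(records).iloc[1:], manifest_from(records))

    def test_mixed_gender_pair_rejected(self):
        records, _ = generate_cohort(CohortGenSpec(seed=1))
        records = records.copy()
        records.loc[0, "gender"] = "male" if records.loc[1, "gender"] == "female" else "female"
        with pytest.raises(IntegrityError, match="gender"):
            assemble_dataset(features_from(records), manifest_from(records))

    def test_missing_aq_rows_kept_and_flagged(self):
        records, _ = generate_cohort(CohortGenSpec(n_missing_aq_pairs=4, seed=2))
        out = assemble_dataset(features_from(records), manifest_from(records))
        assert len(out) == 170
        assert out["aq_missing"].sum() == 8


class TestFit:
    def test_noiseless_cohort_recovers_generating_coefficients(self):
        records, truth = generate_cohort(CohortGenSpec(sd_pair=0.0, sd_resid=1e-6, seed=5))
        res = fit_hlm(records)
        beta_true = np.array(list(truth["betas"].values()))
        assert np.max(np.abs(res.fixed_effects["estimate"].values - beta_true)) < 1e-3

    def test_var_pair_profiled_at_zero_equals_ols(self):
        records, _ = generate_cohort(CohortGenSpec(sd_pair=0.0, sd_resid=50.0, seed=0))
        res = fit_hlm(records, ModelConfig(var_pair=0.0))
        X, _, _ = build_design(records)
        ols = np.linalg.lstsq(X, records["area_px"].to_numpy(float), rcond=None)[0]
        assert np.max(np.abs(res.fixed_effects["estimate"].values - ols)) < 1e-6
        n, p = X.shape
        assert np.allclose(res.fixed_effects["df"], n - p)

    def test_estimates_are_gls_at_fitted_variances(self):
        # independent oracle: generalized least squares on the pair-blocked
        # covariance built from the fitted variance components
        records, _ = generate_cohort(CohortGenSpec(seed=3))
        res = fit_hlm(records)
        X, _, _ = build_design(records)
        y = records["area_px"].to_numpy(float)
        pair = pd.factorize(records["pair_id"])[0]
        V = res.var_resid * np.eye(len(y)) + res.var_pair * (
            pair[:, None] == pair[None, :]
        ).astype(float)
        Vi = np.linalg.inv(V)
        gls = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        assert np.max(np.abs(res.fixed_effects["estimate"].values - gls)) < 1e-6

    def test_permutation_invariance(self):
        records, _ = generate_cohort(CohortGenSpec(seed=4))
        res1 = fit_hlm(records)
        shuffled = records.sample(frac=1.0, random_state=17).reset_index(drop=True)
        res2 = fit_hlm(shuffled)
        assert np.allclose(
            res1.fixed_effects["estimate"].values,
            res2.fixed_effects["estimate"].values,
            atol=1e-6,
        )
        assert np.allclose(res1.fixed_effects["df"].values, res2.fixed_effects["df"].values, rtol=1e-4)

    def test_location_equivariance(self):
        records, _ = generate_cohort(CohortGenSpec(seed=6))
        res1 = fit_hlm(records)
        shifted = records.copy()
        shifted["area_px"] += 250.0
        res2 = fit_hlm(shifted)
        delta = res2.fixed_effects["estimate"].values - res1.fixed_effects["estimate"].values
        assert delta[0] == pytest.approx(250.0, abs=1e-5)
        assert np.max(np.abs(delta[1:])) < 1e-5

    def test_singular_design_names_collinear_columns(self):
        records, _ = generate_cohort(CohortGenSpec(seed=7))
        records = records.copy()
        records["age"] = 25.0  # constant -> collinear with intercept after centering
        with pytest.raises(FitError, match="age|collinear|singular"):
            fit_hlm(records)

    def test_too_few_pairs_rejected(self):
        records, _ = generate_cohort(CohortGenSpec(n_pairs={"UK": (1, 1)}, seed=8))
        with pytest.raises(FitError, match="pairs"):
            fit_hlm(records)

    def test_missing_aq_dropped_listwise_with_count(self):
        records, _ = generate_cohort(CohortGenSpec(n_missing_aq_pairs=4, seed=9))
        res = fit_hlm(records)
        assert res.n_obs == 170 - 8
        assert res.fit_meta["n_dropped_missing"] == 8

    def test_confidence_intervals_bracket_estimates(self):
        records, _ = generate_cohort(CohortGenSpec(seed=10))
        res = fit_hlm(records)
        fe = res.fixed_effects
        assert np.all(fe["ci_lo"] <= fe["estimate"])
        assert np.all(fe["estimate"] <= fe["ci_hi"])
        assert np.all((fe["p"] > 0) & (fe["p"] <= 1))
        assert np.all(fe["df"] > 0)
        assert res.fit_meta["method"] == "REML"


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
class TestAgainstLmerTest:
    def test_matches_lmertest_estimates_se_and_satterthwaite_df(self):
        records, _ = generate_cohort(CohortGenSpec(seed=42))
        res = fit_hlm(records)
        X, _, _ = build_design(records)
        d = pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])
        d["y"] = records["area_px"].values
        d["pair"] = records["pair_id"].values
        with tempfile.TemporaryDirectory() as td:
            data_csv = os.path.join(td, "d.csv")
            out_csv = os.path.join(td, "out.csv")
            d.to_csv(data_csv, index=False)
            rcode = f"""
suppressMessages(library(lmerTest))
d <- read.csv("{data_csv}")
m <- lmer(y ~ 0 + x0+x1+x2+x3+x4+x5+x6+x7 + (1|pair), data=d, REML=TRUE)
co <- as.data.frame(summary(m)$coefficients)
vc <- as.data.frame(VarCorr(m))$vcov
co$vc_pair <- vc[1]; co$vc_resid <- vc[2]
write.csv(co, "{out_csv}")
"""
            subprocess.run(["Rscript", "-e", rcode], check=True, capture_output=True)
            r = pd.read_csv(out_csv)
        fe = res.fixed_effects
        assert np.max(np.abs(r["Estimate"].values - fe["estimate"].values)) < 1e-4
        assert np.max(np.abs(r["Std. Error"].values / fe["se"].values - 1)) < 1e-3
        assert np.max(np.abs(r["df"].values / fe["df"].values - 1)) < 0.02
        assert res.var_pair == pytest.approx(r["vc_pair"][0], rel=1e-3, abs=0.05)
        assert res.var_resid == pytest.approx(r["vc_resid"][0], rel=1e-3)


class TestDescriptives:
    def test_hand_computed_cells(self):
        records = pd.DataFrame(
            {
                "participant_id": ["a", "b", "c", "d"],
                "pair_id": ["p1", "p1", "p2", "p2"],
                "gender": ["female", "female", "male", "male"],
                "country": ["India", "India", "India", "India"],
                "cr": [4, 6, 8, 10],
                "aq": [20.0, np.nan, 10.0, 14.0],
                "area_px": [200.0, 220.0, 300.0, 320.0],
            }
        )
        desc = descriptives(records).set_index(["country", "group", "measure"])
        assert desc.loc[("India", "female", "CR"), "mean"] == 5.0
        assert desc.loc[("India", "total", "CR"), "n"] == 4
        assert desc.loc[("India", "female", "AQ"), "n"] == 1  # one missing AQ excluded
        assert np.isnan(desc.loc[("India", "female", "AQ"), "sd"])  # single value
        assert desc.loc[("India", "total", "Articulation space"), "mean"] == pytest.approx(260.0)
        assert desc.loc[("India", "male", "Articulation space"), "sd"] == pytest.approx(
            np.std([300.0, 320.0], ddof=1)
        )

    def test_cohort_sample_means_near_programmed_truth(self):
        records, truth = generate_cohort(CohortGenSpec(seed=13))
        desc = descriptives(records).set_index(["country", "group", "measure"])
        # intercept is the grand mean under centered coding; SE of a country
        # mean is roughly sqrt((sd_pair^2+sd_resid^2)/n)
        for country in ("India", "Italy", "UK"):
            cell = desc.loc[(country, "total", "Articulation space")]
            se = np.sqrt((truth["sd_pair"] ** 2 + truth["sd_resid"] ** 2) / cell["n"])
            expected = truth["betas"]["intercept"] + {
                "India": truth["betas"]["country_india"] * 2 / 3
                - truth["betas"]["country_uk"] / 3,
                "Italy": -truth["betas"]["country_india"] / 3
                - truth["betas"]["country_uk"] / 3,
                "UK": truth["betas"]["country_uk"] * 2 / 3
                - truth["betas"]["country_india"] / 3,
            }[country]
            assert abs(cell["mean"] - expected) < 4 * se + 15.0  # gender imbalance slack
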