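"""Mixed-effects layer: contrasts, Type III F-tests, effect patterns."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from sdtms.errors import DataQualityError
from sdtms.stats import (
    cohen_d,
    fit_lme_rmt,
    fit_lme_scalar,
    placebo_differences,
    sdtc_rheobase_relationship,
)
from sdtms.synthetic import DrugEffect, SimulationConfig, simulate_rmt_table

CONDS = ("placebo", "carbamazepine", "lacosamide")


def scalar_table(values_by_cond, n_subj=13, subject_sd=0.0, noise_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    subj_fx = subject_sd * rng.standard_normal(n_subj)
    rows = []
    for i in range(n_subj):
        for cond in CONDS:
            rows.append(
                {
                    "subject_id": f"S{i:02d}",
                    "condition": cond,
                    "value": values_by_cond[cond] + subj_fx[i] + noise_sd * rng.standard_normal(),
                }
            )
    return pd.DataFrame(rows)


class TestCohenD:
    def test_zero_estimate(self):
        assert cohen_d(0.0, 3.0) == 0.0

    def test_unit_ratio(self):
        assert cohen_d(2.5, 2.5) == 1.0

    def test_non_positive_sd_rejected(self):
        with pytest.raises(DataQualityError):
            cohen_d(1.0, 0.0)


class TestScalarModel:
    def test_identical_conditions_give_null_contrasts(self):
        tab = scalar_table(
            {c: 500.0 for c in CONDS}, subject_sd=80.0, noise_sd=1e-3, seed=1
        )
        res = fit_lme_scalar(tab, "value")
        for e in res.effects:
            assert abs(e.estimate) < 1e-2
        assert res.anova_row("condition").F < 1.0

    def test_recovers_known_condition_shift(self):
        # SDTC lowered by 70 under one condition: the placebo-referenced
        # contrast recovers -70 within Monte-Carlo tolerance
        ests = []
        for seed in range(30):
            tab = scalar_table(
                {"placebo": 550.0, "carbamazepine": 550.0, "lacosamide": 480.0},
                subject_sd=120.0,
                noise_sd=30.0,
                seed=seed,
            )
            res = fit_lme_scalar(tab, "value")
            ests.append(res.effect("lacosamide").estimate)
        assert np.median(ests) == pytest.approx(-70.0, abs=15.0)

    def test_reported_df_follow_residual_rule(self):
        tab = scalar_table({c: 500.0 for c in CONDS}, subject_sd=50.0, noise_sd=10.0)
        res = fit_lme_scalar(tab, "value")
        # 39 observations - 3 fixed-effect columns
        assert all(e.df == 36 for e in res.effects)
        assert res.anova[0].df_den == 36

    def test_t_equals_estimate_over_se_and_p_in_range(self):
        tab = scalar_table(
            {"placebo": 500.0, "carbamazepine": 530.0, "lacosamide": 460.0},
            subject_sd=60.0,
            noise_sd=25.0,
            seed=3,
        )
        res = fit_lme_scalar(tab, "value")
        for e in res.effects:
            assert e.t == pytest.approx(e.estimate / e.se, abs=1e-6)
            assert 0.0 < e.p <= 1.0
        assert res.anova_row("condition").F >= 0.0

    def test_incomplete_subject_dropped_with_warning(self):
        tab = scalar_table({c: 500.0 for c in CONDS}, subject_sd=50.0, noise_sd=10.0)
        tab = tab.drop(index=[0])
        with pytest.warns(UserWarning, match="missing cells"):
            res = fit_lme_scalar(tab, "value")
        assert res.n_obs == 36

    def test_agrees_with_lmer_reml_oracle(self, tmp_path):
        # independent route: lme4/lmerTest REML fit of the same model
        tab = scalar_table(
            {"placebo": 500.0, "carbamazepine": 540.0, "lacosamide": 470.0},
            subject_sd=90.0,
            noise_sd=35.0,
            seed=11,
        )
        res = fit_lme_scalar(tab, "value")
        csv = tmp_path / "tab.csv"
        tab.to_csv(csv, index=False)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            d$condition <- relevel(factor(d$condition), ref = "placebo")
            m <- lmer(value ~ condition + (1 | subject_id), data = d, REML = TRUE)
            cf <- summary(m)$coefficients
            cat(cf["conditioncarbamazepine", 1], cf["conditioncarbamazepine", 2],
                cf["conditionlacosamide", 1], cf["conditionlacosamide", 2],
                sigma(m), sep = ",")
            """
        )
        rscript = tmp_path / "fit.R"
        rscript.write_text(script)
        out = subprocess.run(
            ["Rscript", "--vanilla", str(rscript)], capture_output=True, text=True
        )
        assert out.returncode == 0, out.stderr
        cbz_est, cbz_se, lcs_est, lcs_se, sigma = map(float, out.stdout.split(","))
        assert res.effect("carbamazepine").estimate == pytest.approx(cbz_est, abs=1e-4)
        assert res.effect("carbamazepine").se == pytest.approx(cbz_se, rel=1e-3)
        assert res.effect("lacosamide").estimate == pytest.approx(lcs_est, abs=1e-4)
        assert res.effect("lacosamide").se == pytest.approx(lcs_se, rel=1e-3)
        assert res.residual_sd == pytest.approx(sigma, rel=1e-3)


class TestRmtModel:
    def test_null_cohorts_keep_contrasts_within_two_se(self, null_effects):
        # zero drug effects: both drug contrasts within +/-2 SE of 0 in
        # >= 90% of seeded runs
        inside = 0
        n = 60
        for i in range(n):
            cfg = SimulationConfig(seed=20_000 + i, drug_effects=null_effects)
            rmt = simulate_rmt_table(cfg, measurement_sd_pct_mso=1.0)
            res = fit_lme_rmt(rmt, random_slope=True)
            ok = all(
                abs(e.estimate) <= 2.0 * e.se
                for e in res.effects
                if e.term in ("condition[carbamazepine]", "condition[lacosamide]")
            )
            inside += ok
        assert inside / n >= 0.90

    def test_recovers_additive_threshold_shift(self):
        # +2 %MSO at all widths: reference-width contrast estimates 2
        fx = {
            "placebo": DrugEffect(),
            "carbamazepine": DrugEffect(),
            "lacosamide": DrugEffect(threshold_additive_pct_mso=2.0),
        }
        ests = []
        for i in range(60):
            cfg = SimulationConfig(seed=30_000 + i, drug_effects=fx)
            rmt = simulate_rmt_table(cfg, measurement_sd_pct_mso=1.0)
            res = fit_lme_rmt(rmt)
            ests.append(res.effect("condition[lacosamide]").estimate)
        assert np.median(ests) == pytest.approx(2.0, abs=0.5)

    def test_rmt_model_df_and_anova_rows(self, null_effects):
        cfg = SimulationConfig(seed=5, drug_effects=null_effects)
        rmt = simulate_rmt_table(cfg, measurement_sd_pct_mso=1.0)
        res = fit_lme_rmt(rmt)
        # full balanced design: 117 observations - 9 fixed-effect columns
        assert res.anova[0].df_den == 108
        effects = {a.effect: a for a in res.anova}
        assert set(effects) == {"condition", "pulse_width", "condition x pulse_width"}
        assert effects["condition"].df_num == 2
        assert effects["condition x pulse_width"].df_num == 4

    def test_width_main_effect_dominates(self, null_effects):
        # thresholds fall steeply with pulse width: that F must be huge
        cfg = SimulationConfig(seed=6, drug_effects=null_effects)
        rmt = simulate_rmt_table(cfg, measurement_sd_pct_mso=1.0)
        res = fit_lme_rmt(rmt, random_slope=True)
        assert res.anova_row("pulse_width").F > 100.0

    def test_condition_label_permutation_invariance(self, null_effects):
        cfg = SimulationConfig(seed=8, drug_effects=null_effects)
        rmt = simulate_rmt_table(cfg, measurement_sd_pct_mso=1.0)
        swapped = rmt.copy()
        swapped["condition"] = swapped["condition"].map(
            {"placebo": "placebo", "carbamazepine": "lacosamide", "lacosamide": "carbamazepine"}
        )
        f0 = fit_lme_rmt(rmt).anova_row("condition").F
        f1 = fit_lme_rmt(swapped).anova_row("condition").F
        assert f0 == pytest.approx(f1, rel=1e-6)


class TestPlaceboDifferences:
    @staticmethod
    def exact_rmt_table(drug_effects):
        cfg = SimulationConfig(seed=40, drug_effects=drug_effects)
        return simulate_rmt_table(cfg, measurement_sd_pct_mso=1e-9)

    def test_drug_identical_to_placebo_gives_zero_differences(self, null_effects):
        diffs, _ = placebo_differences(self.exact_rmt_table(null_effects))
        assert np.allclose(diffs["diff_rmt_io"], 0.0, atol=1e-6)

    def test_multiplicative_effect_grows_toward_short_widths(self):
        fx = {
            "placebo": DrugEffect(),
            "carbamazepine": DrugEffect(threshold_scale=1.15),
            "lacosamide": DrugEffect(),
        }
        diffs, _ = placebo_differences(self.exact_rmt_table(fx))
        mean = (
            diffs[diffs.condition == "carbamazepine"]
            .groupby("pulse_width_us")["diff_rmt_io"]
            .mean()
        )
        assert mean[30] > mean[60] > mean[120] > 0
        assert mean[30] / mean[120] > 3.0

    def test_flat_effect_is_width_independent(self):
        fx = {
            "placebo": DrugEffect(),
            "carbamazepine": DrugEffect(),
            "lacosamide": DrugEffect(threshold_additive_pct_mso=2.0),
        }
        diffs, _ = placebo_differences(self.exact_rmt_table(fx))
        mean = (
            diffs[diffs.condition == "lacosamide"]
            .groupby("pulse_width_us")["diff_rmt_io"]
            .mean()
        )
        assert mean.max() / mean.min() < 1.5

    def test_interaction_tested_on_differences(self):
        fx = {
            "placebo": DrugEffect(),
            "carbamazepine": DrugEffect(threshold_scale=1.15),
            "lacosamide": DrugEffect(threshold_additive_pct_mso=2.0),
        }
        cfg = SimulationConfig(seed=41, drug_effects=fx)
        diffs, model = placebo_differences(simulate_rmt_table(cfg, measurement_sd_pct_mso=0.5))
        # 78 observations - 6 fixed-effect columns
        row = model.anova_row("condition x pulse_width")
        assert row.df_den == 72
        assert row.p < 0.05


class TestSdtcRheobaseRelationship:
    def test_collinear_input_recovers_slope(self):
        rng = np.random.default_rng(2)
        rows = []
        for i in range(13):
            for cond in CONDS:
                rb = rng.uniform(2.0, 6.0)
                rows.append(
                    {
                        "subject_id": f"S{i:02d}",
                        "condition": cond,
                        "rheobase_pct_mso": rb,
                        "sdtc_us": 1000.0 - 46.0 * rb + 1e-3 * rng.standard_normal(),
                    }
                )
        fits = pd.DataFrame(rows)
        slopes, model = sdtc_rheobase_relationship(fits)
        assert np.allclose(slopes["slope_us_per_pct"], -46.0, atol=1e-2)
        assert (slopes["r_squared"] > 0.999).all()
        assert model.effect("rheobase_pct_mso").estimate == pytest.approx(-46.0, abs=0.1)
        # residual rule: 39 observations - 6 fixed-effect columns
        assert model.effect("rheobase_pct_mso").df == 33

    def test_condition_slope_offsets_recovered(self):
        rng = np.random.default_rng(9)
        rows = []
        slopes_true = {"placebo": -46.0, "carbamazepine": -60.0, "lacosamide": -25.0}
        for i in range(13):
            for cond in CONDS:
                rb = rng.uniform(2.0, 6.0)
                rows.append(
                    {
                        "subject_id": f"S{i:02d}",
                        "condition": cond,
                        "rheobase_pct_mso": rb,
                        "sdtc_us": 800.0 + slopes_true[cond] * rb + 5.0 * rng.standard_normal(),
                    }
                )
        _, model = sdtc_rheobase_relationship(pd.DataFrame(rows))
        lcs = model.effect("rheobase_pct_mso:condition[lacosamide]")
        cbz = model.effect("rheobase_pct_mso:condition[carbamazepine]")
        assert lcs.estimate == pytest.approx(21.0, abs=6.0)
        assert cbz.estimate == pytest.approx(-14.0, abs=6.0)

    def test_degenerate_rheobase_variance_errors(self):
        fits = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(6)] * 3,
                "condition": sorted(CONDS * 6),
                "rheobase_pct_mso": [3.0] * 18,
                "sdtc_us": np.arange(18.0) + 400.0,
            }
        )
        with pytest.raises(DataQualityError):
            sdtc_rheobase_relationship(fits)
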