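"""Evaluation contracts: clinical Cox model, cross-validated report
invariants, calibration behaviour, and the onset-age stratification."""

import numpy as np
import pandas as pd
import pytest

from metacvd.evaluation import (CLINICAL_COVARIATES, calibrate,
                                evaluate_models, fit_clinical_model,
                                stratify)
from metacvd.meta import assign_folds
from metacvd.phenotypes import SurvivalCohort
from metacvd.survival import CoxError


def _synth_cohort(n=4000, seed=0, betas=None, base_rate=0.12,
                  score_beta=0.0, interaction=0.0):
    """Exponential survival data over a clinical covariate table.

    ``interaction`` adds score effect per decade of onset age below 55.
    Returns (cohort, score) where score carries ``score_beta`` log-HR.
    """
    rng = np.random.default_rng(seed)
    age = np.clip(rng.normal(60, 8, n), 35, 79)
    cov = {
        "age_at_onset": age,
        "sex": (rng.random(n) < 0.6).astype(float),
        "bmi": rng.normal(30, 4.5, n),
        "smoking": (rng.random(n) < 0.57).astype(float),
        "hypertension": (rng.random(n) < 0.8).astype(float),
        "tc": rng.normal(5.9, 1.3, n),
        "ldl_c": rng.normal(3.9, 0.8, n),
        "hdl_c": rng.normal(1.2, 0.3, n),
        "tg": rng.normal(2.3, 1.3, n),
        "lipid_med": (rng.random(n) < 0.54).astype(float),
        "glucose": rng.normal(6.6, 2.0, n),
    }
    for j in range(1, 11):
        cov[f"pc{j}"] = rng.standard_normal(n)
    betas = betas or {}
    lp = np.zeros(n)
    for k, b in betas.items():
        lp += b * (cov[k] - np.mean(cov[k]))
    score = rng.standard_normal(n)
    eff = score_beta + interaction * (55.0 - age) / 10.0
    lp = lp + eff * score
    t = rng.exponential(np.exp(-lp) / base_rate)
    cmax = 12.0
    times = np.ceil(np.minimum(t, cmax) * 365.25)
    events = (t <= cmax).astype(int)
    df = pd.DataFrame(cov, index=pd.Index([f"P{i}" for i in range(n)],
                                          name="person_id"))
    df.insert(0, "t2d_onset_date", pd.Timestamp("2005-01-01"))
    df.insert(1, "cvd_onset_date", pd.NaT)
    df.insert(2, "death_date", pd.NaT)
    df.insert(3, "event", events)
    df.insert(4, "follow_up_days", times)
    cohort = SurvivalCohort(table=df,
                            censor_date=pd.Timestamp("2021-02-05"),
                            min_follow_up_days=1)
    return cohort, score


class TestClinicalModel:
    def test_null_effects_cis_cover_zero(self):
        cohort, _ = _synth_cohort(n=8000, seed=1)
        fit, lp = fit_clinical_model(cohort)
        lo, hi = fit.conf_int[:, 0], fit.conf_int[:, 1]
        covered = (lo <= 0) & (0 <= hi)
        assert covered.mean() > 0.8  # ~95% each; allow one miss
        assert len(lp) == cohort.n

    def test_parameter_recovery_smoking(self):
        b = float(np.log(1.5))
        cohort, _ = _synth_cohort(n=10000, seed=2, betas={"smoking": b})
        fit, _ = fit_clinical_model(cohort)
        i = fit.names.index("smoking")
        assert fit.conf_int[i, 0] <= b <= fit.conf_int[i, 1]

    def test_single_sex_cohort_rejected(self):
        cohort, _ = _synth_cohort(n=500, seed=3)
        cohort.table["sex"] = 1.0
        with pytest.raises(CoxError, match="constant covariate: sex"):
            fit_clinical_model(cohort)

    def test_missing_covariate_named(self):
        cohort, _ = _synth_cohort(n=200, seed=4)
        cohort.table.drop(columns=["glucose"], inplace=True)
        with pytest.raises(KeyError, match="glucose"):
            fit_clinical_model(cohort)


class TestEvaluateModels:
    def test_null_score(self):
        cohort, score = _synth_cohort(n=4000, seed=5, score_beta=0.0)
        folds = assign_folds(cohort.events, 5, seed=0)
        rep = evaluate_models({"null": score}, cohort, folds)
        m = rep.models["null"]
        assert m.hr_ci[0] < 1.0 < m.hr_ci[1]
        assert abs(m.auc - 0.5) < 0.04

    def test_headline_equals_fold_means(self):
        cohort, score = _synth_cohort(n=3000, seed=6, score_beta=0.25)
        folds = assign_folds(cohort.events, 5, seed=1)
        rep = evaluate_models({"s": score}, cohort, folds)
        m = rep.models["s"]
        assert m.hr == pytest.approx(m.fold_hr.mean())
        assert m.auc == pytest.approx(m.fold_auc.mean())
        assert np.allclose(m.decile_rates, m.fold_decile_rates.mean(axis=0))

    def test_informative_score_detected(self):
        cohort, score = _synth_cohort(n=6000, seed=7, score_beta=0.3)
        folds = assign_folds(cohort.events, 5, seed=2)
        rep = evaluate_models({"s": score}, cohort, folds)
        m = rep.models["s"]
        assert m.hr_ci[0] > 1.0
        assert m.auc > 0.55
        assert m.decile_rates[-1] > m.decile_rates[0]

    def test_nested_model_dominance(self):
        # score + covariates cannot be meaningfully worse than covariates
        cohort, score = _synth_cohort(
            n=6000, seed=8, score_beta=0.3,
            betas={"age_at_onset": np.log(1.04)})
        folds = assign_folds(cohort.events, 5, seed=3)
        rep = evaluate_models({"s": score}, cohort, folds)
        m = rep.models["s"]
        assert m.auc_full >= m.auc - 0.01

    def test_small_test_fold_rejected(self):
        cohort, score = _synth_cohort(n=40, seed=9)
        folds = assign_folds(cohort.events, 5, seed=4)
        with pytest.raises(ValueError, match="fewer than"):
            evaluate_models({"s": score}, cohort, folds, min_test_n=10)

    def test_json_serialization(self, tmp_path):
        cohort, score = _synth_cohort(n=2000, seed=10, score_beta=0.2)
        folds = assign_folds(cohort.events, 5, seed=5)
        rep = evaluate_models({"s": score}, cohort, folds)
        text = rep.to_json(tmp_path / "r.json")
        import json
        payload = json.loads(text)
        assert "s" in payload["models"]
        assert payload["models"]["s"]["headline"]["AUC"] == pytest.approx(
            rep.models["s"].auc)


class TestCalibrate:
    def test_well_specified_slope_near_one(self):
        cohort, score = _synth_cohort(n=12000, seed=11, score_beta=0.4,
                                      base_rate=0.03)
        res = calibrate(score, cohort)
        assert 0.8 < res.slope < 1.2
        assert not res.degenerate
        # predicted and observed deciles track each other
        assert np.corrcoef(res.table["mean_predicted"],
                           res.table["observed"])[0, 1] > 0.7

    def test_constant_score_degenerate(self):
        cohort, _ = _synth_cohort(n=500, seed=12)
        res = calibrate(np.zeros(cohort.n), cohort)
        assert res.degenerate

    def test_artificially_doubled_risk_detected(self):
        # doubling the fitted log-hazard over-disperses predicted risks:
        # the recalibration slope drops below 1
        import dataclasses

        from metacvd.survival import CoxPH
        cohort, score = _synth_cohort(n=12000, seed=13, score_beta=0.4,
                                      base_rate=0.03)
        z = (score - score.mean()) / score.std()
        honest_fit = CoxPH(cohort.times, cohort.events, z[:, None],
                           names=["score"]).fit()
        doubled = dataclasses.replace(honest_fit,
                                      params=2 * honest_fit.params)
        honest = calibrate(score, cohort, risk_fit=honest_fit)
        inflated = calibrate(score, cohort, risk_fit=doubled)
        assert inflated.slope < 1.0
        assert inflated.slope < honest.slope


class TestStratify:
    def test_proportions_partition(self):
        cohort, score = _synth_cohort(n=4000, seed=14, score_beta=0.3,
                                      betas={"bmi": 0.03})
        _, clin = fit_clinical_model(cohort)
        rep = stratify(score, clin.to_numpy(), cohort)
        sums = rep.proportions.sum(axis=1)
        assert np.allclose(sums, 100.0)

    def test_identical_incidence_gives_zero_arr(self):
        cohort, score = _synth_cohort(n=2000, seed=15)
        # deterministic outcomes independent of age group: equalize by
        # construction — every 5th person an event
        cohort.table["event"] = (np.arange(cohort.n) % 5 == 0).astype(int)
        age = cohort.table["age_at_onset"].to_numpy()
        # force alternating assignment so group incidences are identical
        order = np.argsort(np.argsort(score))
        cohort.table["event"] = (order % 5 == 0).astype(int)
        clin = np.linspace(-1, 1, cohort.n)
        rep = stratify(score, clin, cohort)
        # high-PRS and remaining each mix deciles evenly across age groups;
        # incidences are close, ARRs near zero
        assert rep.arr["arr_high_prs"] < 0.05
        assert rep.arr["arr_remaining"] < 0.05

    def test_interaction_raises_early_onset_auc(self):
        cohort, score = _synth_cohort(n=12000, seed=16, score_beta=0.15,
                                      interaction=0.2)
        clin = np.linspace(-1, 1, cohort.n)
        rep = stratify(score, clin, cohort)
        assert rep.group_hr.loc["early", "AUC"] > rep.group_hr.loc[
            "late", "AUC"]
        assert rep.group_hr.loc["early", "HR_per_SD"] > rep.group_hr.loc[
            "late", "HR_per_SD"]

    def test_empty_group_rejected(self):
        cohort, score = _synth_cohort(n=500, seed=17)
        clin = np.zeros(cohort.n) + np.linspace(0, 1, cohort.n)
        with pytest.raises(ValueError, match="empty onset-age group"):
            stratify(score, clin, cohort, age_cut=20.0)

    def test_stratification_independent_of_adjustment(self):
        cohort, score = _synth_cohort(n=3000, seed=18, score_beta=0.3)
        clin = np.linspace(-1, 1, cohort.n)
        full = stratify(score, clin, cohort)
        reduced = stratify(score, clin, cohort,
                           adjustment=["age_at_onset", "sex"])
        pd.testing.assert_frame_equal(full.proportions, reduced.proportions)
        assert full.arr == reduced.arr
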