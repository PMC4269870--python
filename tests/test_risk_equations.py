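import numpy as np
import pandas as pd
import pytest

from chfcea import risk_equations as re_
from chfcea.synthetic_trial import (
    CohortConfig,
    TruthParams,
    admission_frame,
    generate_cohort,
    simulate_followup,
    survival_frame,
)


# ---------------------------------------------------------------------------
# parametric survival
# ---------------------------------------------------------------------------

class TestPredictSurvival:
    def test_survival_at_time_zero_is_one(self, trial):
        m = re_.fit_parametric_survival(survival_frame(trial), "gompertz", ["treat"])
        assert re_.predict_survival(m, None, 0.0) == 1.0

    def test_gompertz_closed_form_hand_value(self):
        m = re_.SurvivalModel("gompertz", (0.01, 0.1), {}, 0, 0, 0,
                              np.eye(2), [], True, 0, 0)
        # S(12) = exp(-0.1 * (e^{1.2} - 1))
        assert re_.predict_survival(m, None, 12.0) == pytest.approx(0.7929, abs=2e-4)

    def test_hazard_ratio_acts_as_survival_power(self):
        assert re_.apply_hazard_ratio(0.8, 0.90) == pytest.approx(0.8**0.90)
        assert re_.apply_hazard_ratio(0.8, 0.90) == pytest.approx(0.8181, abs=1e-4)

    def test_negative_time_rejected(self, trial):
        m = re_.fit_parametric_survival(survival_frame(trial), "exponential")
        with pytest.raises(ValueError):
            re_.predict_survival(m, None, np.array([-1.0]))

    def test_curves_non_increasing_and_bounded(self, trial):
        t = np.linspace(0, 600, 200)
        for dist in ("gompertz", "exponential", "weibull"):
            m = re_.fit_parametric_survival(survival_frame(trial), dist, ["treat"])
            s = re_.predict_survival(m, {"treat": 1}, t)
            assert np.all(np.diff(s) <= 1e-12)
            assert np.all((s >= 0) & (s <= 1))


def test_gompertz_shape_zero_limit_is_exponential():
    lam = 0.01
    m = re_.SurvivalModel("gompertz", (lam, 1e-8), {}, 0, 0, 0, np.eye(2), [], True, 0, 0)
    t = np.linspace(0.0, 600.0, 601)
    assert np.max(np.abs(re_.predict_survival(m, None, t) - np.exp(-lam * t))) < 1e-6


def test_no_events_raises():
    df = pd.DataFrame({"time": np.ones(50), "event": np.zeros(50)})
    with pytest.raises(re_.FittingError):
        re_.fit_parametric_survival(df, "exponential")


def test_exponential_truth_recovered_within_3_se():
    truth = TruthParams(gompertz_shape=0.0, log_hr_treatment=0.0)
    truth.gompertz_shape = 1e-15  # exponential limit of the Gompertz process
    cohort = generate_cohort(CohortConfig(n_patients=20_000, seed=61))
    trial = simulate_followup(cohort, truth, seed=62)
    m = re_.fit_parametric_survival(survival_frame(trial), "exponential")
    log_rate_hat = np.log(m.baseline_params[0])
    se = np.sqrt(m.vcov[0, 0])
    assert abs(log_rate_hat - np.log(truth.gompertz_rate)) < 3 * se


def test_treatment_hr_recovered_from_shift_like_cohort(trial, truth):
    m = re_.fit_parametric_survival(survival_frame(trial), "gompertz", ["treat"])
    hr = float(np.exp(m.coefficients["treat"]))
    se = np.sqrt(m.vcov[2, 2])
    assert abs(m.coefficients["treat"] - truth.log_hr_treatment) < 3 * se
    assert 0.80 < hr < 1.0


def test_mle_beats_truth_loglik_on_own_data(trial, truth):
    """At the optimum the fitted log-likelihood is >= the truth's."""
    surv = survival_frame(trial)
    m = re_.fit_parametric_survival(surv, "gompertz", ["treat"])
    t = surv["time"].to_numpy(float)
    d = surv["event"].to_numpy(float)
    X = surv[["treat"]].to_numpy(float)
    theta_truth = np.array([np.log(truth.gompertz_rate), truth.gompertz_shape,
                            truth.log_hr_treatment])
    nll_truth, _ = re_._negloglik_and_grad(theta_truth, "gompertz", t, d, X)
    assert m.loglik >= -nll_truth - 1e-6


def test_aic_identity_and_fit_agrees_with_lifelines(trial):
    """Cross-check the in-house exponential/Weibull MLE against lifelines."""
    from lifelines import ExponentialFitter, WeibullFitter

    surv = survival_frame(trial)
    m_exp = re_.fit_parametric_survival(surv, "exponential")
    assert m_exp.aic == pytest.approx(-2 * m_exp.loglik + 2 * 1)
    ef = ExponentialFitter().fit(surv["time"], surv["event"])
    assert m_exp.baseline_params[0] == pytest.approx(1.0 / ef.lambda_, rel=1e-4)

    m_wei = re_.fit_parametric_survival(surv, "weibull")
    wf = WeibullFitter().fit(surv["time"], surv["event"])
    assert m_wei.baseline_params[1] == pytest.approx(wf.rho_, rel=1e-3)
    assert m_wei.baseline_params[0] == pytest.approx(wf.lambda_**-wf.rho_, rel=1e-3)


class TestSelectDistribution:
    def test_gompertz_truth_ranked_first_in_most_seeds(self):
        wins = 0
        n_seeds = 8
        for seed in range(n_seeds):
            cohort = generate_cohort(CohortConfig(n_patients=10_000, seed=100 + seed))
            trial = simulate_followup(cohort, TruthParams(gompertz_shape=0.03), seed=200 + seed)
            surv = survival_frame(trial)
            models = [re_.fit_parametric_survival(surv, d)
                      for d in ("gompertz", "exponential", "weibull")]
            ranking = re_.select_distribution(models)
            wins += ranking.iloc[0]["distribution"] == "gompertz"
        assert wins >= 0.8 * n_seeds

    def test_exponential_truth_nested_aic_property(self):
        truth = TruthParams(gompertz_shape=1e-15)
        cohort = generate_cohort(CohortConfig(n_patients=10_000, seed=71))
        t = simulate_followup(cohort, truth, seed=72)
        surv = survival_frame(t)
        m_exp = re_.fit_parametric_survival(surv, "exponential")
        m_gom = re_.fit_parametric_survival(surv, "gompertz")
        assert m_exp.aic <= m_gom.aic + 2.0 + 1e-6

    def test_tie_keeps_original_order(self, trial):
        m = re_.fit_parametric_survival(survival_frame(trial), "gompertz")
        ranking = re_.select_distribution([m, m])
        assert list(ranking["rank"]) == [1, 2]

    def test_different_datasets_rejected(self, trial):
        surv = survival_frame(trial)
        m1 = re_.fit_parametric_survival(surv, "gompertz")
        m2 = re_.fit_parametric_survival(surv.iloc[: len(surv) // 2], "gompertz")
        with pytest.raises(ValueError):
            re_.select_distribution([m1, m2])


class TestKaplanMeier:
    def test_hand_product_limit_two_deaths(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [1, 1]})
        kmf = re_.kaplan_meier(df)
        s = kmf.survival_function_at_times([0.5, 1.0, 2.0]).to_numpy()
        assert s == pytest.approx([1.0, 0.5, 0.0])

    def test_all_censored_gives_unit_survival(self):
        df = pd.DataFrame({"time": [3.0, 5.0, 9.0], "event": [0, 0, 0]})
        kmf = re_.kaplan_meier(df)
        assert kmf.survival_function_at_times([9.0]).iloc[0] == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(re_.FittingError):
            re_.kaplan_meier(pd.DataFrame({"time": [], "event": []}))

    def test_agrees_with_exponential_on_memoryless_toy_data(self):
        # at the MLE, the exponential survival passes through the KM curve
        df = pd.DataFrame({"time": [1.0, 1.0, 1.0, 1.0], "event": [1, 0, 0, 0]})
        m = re_.fit_parametric_survival(df, "exponential")
        assert m.baseline_params[0] == pytest.approx(1.0 / 4.0)


# ---------------------------------------------------------------------------
# Poisson admissions
# ---------------------------------------------------------------------------

class TestPoissonRate:
    def test_closed_form_single_arm_mle(self):
        df = pd.DataFrame({"n_admissions": [10] + [0] * 9,
                           "exposure_months": [10.0] * 10})
        m = re_.fit_poisson_rate(df)
        assert m.rate() == pytest.approx(0.10)

    def test_rate_ratio_recovered(self, trial, truth):
        m = re_.fit_poisson_rate(admission_frame(trial), ["treat"])
        se = np.sqrt(m.vcov[1, 1])
        assert abs(m.coefficients["treat"] - truth.log_rr_treatment) < 3 * se
        assert 0.75 < m.rate_ratio < 0.92

    def test_zero_exposure_rejected(self):
        df = pd.DataFrame({"n_admissions": [1], "exposure_months": [0.0]})
        with pytest.raises(re_.FittingError):
            re_.fit_poisson_rate(df)

    def test_separation_flagged_non_estimable(self):
        df = pd.DataFrame({"n_admissions": [5, 4, 0, 0],
                           "exposure_months": [10.0] * 4,
                           "treat": [0, 0, 1, 1]})
        m = re_.fit_poisson_rate(df, ["treat"])
        assert m.non_estimable


# ---------------------------------------------------------------------------
# NYHA proportional odds
# ---------------------------------------------------------------------------

class TestNYHAModel:
    def test_locf_freezes_distribution_after_trial(self, trial):
        nm = re_.fit_nyha_model(trial.nyha_obs)
        p29 = re_.predict_nyha(nm, "soc", 29.0)
        for t in (30.0, 40.0, 120.0):
            assert re_.predict_nyha(nm, "soc", t) == pytest.approx(p29)
        # trend mode keeps moving when there is any slope
        assert np.all(re_.predict_nyha(nm, "soc", 120.0, mode="trend") >= 0)

    def test_probabilities_sum_to_one_at_all_times(self, trial):
        nm = re_.fit_nyha_model(trial.nyha_obs)
        for arm in ("soc", "ivabradine"):
            for t in (0.0, 10.0, 29.0, 300.0):
                assert re_.predict_nyha(nm, arm, t).sum() == pytest.approx(1.0)

    def test_single_class_data_gives_degenerate_prediction(self):
        df = pd.DataFrame({"id": [1, 1, 2, 2], "arm": "soc",
                           "month": [0, 4, 0, 4], "nyha": 2})
        nm = re_.fit_nyha_model(df)
        assert re_.predict_nyha(nm, "soc", 10.0)[1] >= 0.99

    def test_class_outside_range_rejected(self):
        df = pd.DataFrame({"id": [1], "arm": "soc", "month": [0], "nyha": [5]})
        with pytest.raises(re_.FittingError):
            re_.fit_nyha_model(df)

    def test_cutpoints_recovered_within_3_se(self, trial, truth):
        """Proportional-odds truth recovery (slope 0 truth, pooled scale)."""
        nm = re_.fit_nyha_model(trial.nyha_obs)
        cuts = nm.arms["soc"]["cutpoints"]
        n = (trial.nyha_obs["arm"] == "soc").sum()
        for hat, true, p in zip(cuts, truth.nyha_cutpoints, (0.02, 0.52, 0.97)):
            se = 1.0 / np.sqrt(n * p * (1 - p))
            assert abs(hat - true) < 3 * se + 0.02


# ---------------------------------------------------------------------------
# utility mixed model
# ---------------------------------------------------------------------------

class TestUtilityModel:
    def test_noiseless_limit_recovers_fixed_effects_exactly(self):
        rows = []
        for pid in range(30):
            for k, hosp in [(1, False), (2, False), (3, False), (3, True), (4, False)]:
                u = {1: 0.82, 2: 0.74, 3: 0.64, 4: 0.46}[k] + (-0.10 if hosp else 0.0)
                rows.append({"id": pid, "nyha": k, "hosp_window": hosp, "utility": u})
        m = re_.fit_utility_model(pd.DataFrame(rows))
        assert m.flagged_degenerate
        assert m.random_intercept_sd == 0.0 and m.residual_sd == 0.0
        assert m.utilities_by_class() == pytest.approx([0.82, 0.74, 0.64, 0.46])
        assert m.hosp_offsets[3] == pytest.approx(-0.10)

    def test_table_values_and_variances_recovered(self, trial, truth):
        m = re_.fit_utility_model(trial.eq5d_obs)
        assert m.utilities_by_class() == pytest.approx([0.82, 0.74, 0.64, 0.46], abs=0.012)
        # hospitalization decrements: classes II/III carry most observations;
        # classes I (2% occupancy) and IV (3%) have few admissions in window
        assert m.hosp_offsets[2] == pytest.approx(-0.07, abs=0.025)
        assert m.hosp_offsets[3] == pytest.approx(-0.10, abs=0.025)
        assert truth.utility_random_intercept_sd == 0.10
        assert 0.08 < m.random_intercept_sd < 0.12
        assert m.residual_sd == pytest.approx(truth.utility_residual_sd, abs=0.02)

    def test_predicted_utilities_never_exceed_one(self, trial):
        m = re_.fit_utility_model(trial.eq5d_obs)
        for k in (1, 2, 3, 4):
            for hosp in (False, True):
                assert m.state_utility(k, hosp) <= 1.0
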