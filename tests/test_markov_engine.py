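from dataclasses import replace

import numpy as np
import pytest

from chfcea.costing import CostSchedule
from chfcea.markov_engine import (
    CVBaseline,
    StrategyInputs,
    accrue,
    build_trace,
    discount_factor,
    microsimulate,
    overall_survival,
    run_both_arms,
    run_strategy,
)


class TestDiscountFactor:
    def test_closed_form_values(self):
        assert discount_factor(0.035, 0) == 1.0
        assert discount_factor(0.035, 12) == pytest.approx(1.0 / 1.035)
        assert discount_factor(0.0, 360) == 1.0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(-0.01, 12)


class TestOverallSurvival:
    def test_starts_at_one(self, base_inputs):
        assert overall_survival(base_inputs, 0) == 1.0

    def test_product_of_competing_processes(self, life_table):
        # CV-only vs non-CV-only curves multiply to the combined curve
        inputs = StrategyInputs(life_table=life_table)
        cv_only = replace(inputs, life_table=None)
        ncv_only = replace(inputs, cv_baseline=CVBaseline(rate=1e-12, shape=0.0))
        m = 120
        assert overall_survival(inputs, m) == pytest.approx(
            overall_survival(cv_only, m) * overall_survival(ncv_only, m), rel=1e-9)

    def test_null_hazard_ratio_equalizes_arms(self, life_table):
        inputs = StrategyInputs(life_table=life_table, hr_cv=1.0)
        m = np.arange(0, 480, 17)
        soc = overall_survival(replace(inputs, arm="soc"), m)
        iva = overall_survival(replace(inputs, arm="ivabradine"), m)
        assert np.allclose(soc, iva)


class TestTraceInvariants:
    def test_alive_fraction_non_increasing(self, calibrated_inputs):
        for arm in ("soc", "ivabradine"):
            tr = build_trace(replace(calibrated_inputs, arm=arm))
            assert np.all(np.diff(tr["alive"]) <= 1e-12)

    def test_occupancy_sums_to_one(self, calibrated_inputs):
        tr = build_trace(calibrated_inputs)
        occ = tr[["occ1", "occ2", "occ3", "occ4"]].sum(axis=1)
        assert np.allclose(occ, 1.0)

    def test_qaly_equals_ly_when_utilities_one_and_no_extras(self, life_table):
        inputs = StrategyInputs(
            life_table=life_table, utilities=(1.0, 1.0, 1.0, 1.0),
            admission_disutilities=(0.0, 0.0, 0.0, 0.0),
            hosp_rate_soc=0.0, discount_annual=0.0)
        res = run_strategy(inputs)
        assert res.qaly == pytest.approx(res.ly, rel=1e-12)

    def test_protective_hazard_ratio_extends_life(self, calibrated_inputs):
        soc, iva = run_both_arms(calibrated_inputs)
        assert iva.ly >= soc.ly
        assert iva.qaly <= iva.ly  # utilities never exceed 1

    def test_undiscounted_outcomes_dominate_discounted(self, calibrated_inputs):
        disc = run_strategy(calibrated_inputs)
        undisc = run_strategy(replace(calibrated_inputs, discount_annual=0.0))
        assert undisc.ly >= disc.ly
        assert undisc.qaly >= disc.qaly
        assert undisc.total_cost >= disc.total_cost

    def test_total_cost_is_sum_of_components(self, calibrated_inputs):
        soc, iva = run_both_arms(calibrated_inputs)
        for res in (soc, iva):
            assert res.total_cost == pytest.approx(
                res.cost_drug + res.cost_hosp + res.cost_mgmt + res.cost_oneoff,
                abs=1e-6)

    def test_horizon_shorter_than_one_cycle_rejected(self, life_table):
        with pytest.raises(ValueError):
            StrategyInputs(life_table=life_table, horizon_months=0)


class TestAccrualDetails:
    def test_empty_cohort_accrues_nothing(self, life_table):
        inputs = StrategyInputs(life_table=life_table)
        tr = build_trace(inputs)
        tr.loc[:, tr.columns != "cycle"] = 0.0
        res = accrue(tr, "soc")
        assert res.total_cost == 0.0 and res.ly == 0.0 and res.qaly == 0.0

    def test_titration_ecg_is_exactly_the_cycle0_oneoff(self, calibrated_inputs):
        _, iva = run_both_arms(calibrated_inputs)
        no_ecg = replace(calibrated_inputs,
                         costs=replace(calibrated_inputs.costs, ecg_oneoff=0.0))
        _, iva2 = run_both_arms(no_ecg)
        assert iva.total_cost - iva2.total_cost == pytest.approx(3.44)
        assert iva.qaly == pytest.approx(iva2.qaly)

    def test_finite_treatment_duration_stops_drug_cost(self, calibrated_inputs):
        limited = replace(calibrated_inputs, treatment_duration_months=60.0)
        _, iva_life = run_both_arms(calibrated_inputs)
        _, iva_5yr = run_both_arms(limited)
        assert iva_5yr.cost_drug < iva_life.cost_drug
        # with persisting effects, survival is unchanged
        assert iva_5yr.ly == pytest.approx(iva_life.ly)

    def test_reverting_effects_shrink_survival_gain(self, calibrated_inputs):
        revert = replace(calibrated_inputs, treatment_duration_months=60.0,
                         discontinuation="revert")
        soc, iva_rev = run_both_arms(revert)
        _, iva_persist = run_both_arms(replace(revert, discontinuation="persist"))
        assert soc.ly < iva_rev.ly < iva_persist.ly

    def test_half_cycle_correction_shrinks_accruals(self, calibrated_inputs):
        hc = run_strategy(replace(calibrated_inputs, half_cycle=True))
        plain = run_strategy(calibrated_inputs)
        assert hc.ly < plain.ly


def test_trace_matches_microsimulation_oracle(calibrated_inputs):
    """Cohort-trace expectations equal individual-simulation means within
    3 Monte-Carlo SEs (LY, QALY, lifetime admissions) - the core engine
    correctness property."""
    inputs = replace(calibrated_inputs, arm="ivabradine")
    tr = build_trace(inputs)
    res = accrue(tr, "ivabradine")
    ms = microsimulate(inputs, 200_000, seed=17)
    assert abs(ms["ly"] - res.ly) < 3 * ms["ly_se"]
    assert abs(ms["qaly"] - res.qaly) < 3 * ms["qaly_se"]
    assert abs(ms["admissions"] - tr["expected_admissions"].sum()) < 3 * ms["admissions_se"]


def test_km_baseline_matches_parametric_within_its_support(calibrated_inputs):
    cb = calibrated_inputs.cv_baseline
    grid = np.arange(0.0, 30.0)
    km = CVBaseline(distribution="kaplan_meier", km_times=grid,
                    km_surv=np.exp(-cb.cumhaz(grid)))
    assert np.allclose(km.cumhaz(grid), cb.cumhaz(grid), atol=1e-9)
    # beyond support the extension keeps the cumulative hazard increasing
    far = km.cumhaz(np.array([29.0, 100.0, 400.0]))
    assert np.all(np.diff(far) > 0)
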