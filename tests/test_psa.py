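from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from chfcea import psa
from chfcea.economics import incremental
from chfcea.markov_engine import run_both_arms


@pytest.fixture(scope="module")
def small_cloud(calibrated_inputs):
    dists = psa.default_parameter_set(calibrated_inputs)
    draws = psa.draw_parameters(dists, 400, seed=9)
    return psa.run_psa(calibrated_inputs, draws, seed=9)


class TestMarginals:
    def test_lognormal_ci_reproduced(self):
        m = psa.lognormal_from_ci(0.90, 0.80, 1.03)
        u = np.random.default_rng(1).random(100_000)
        x = m.ppf(u)
        assert np.quantile(x, 0.025) == pytest.approx(0.80, abs=0.01)
        assert np.quantile(x, 0.975) == pytest.approx(1.03, abs=0.01)

    def test_beta_and_gamma_moments(self):
        u = np.random.default_rng(2).random(200_000)
        b = psa.beta_from_mean_se(0.74, 0.074).ppf(u)
        assert b.mean() == pytest.approx(0.74, abs=0.002)
        assert b.std() == pytest.approx(0.074, abs=0.002)
        g = psa.gamma_from_mean_se(26.05, 5.21).ppf(u)
        assert g.mean() == pytest.approx(26.05, rel=0.01)

    def test_oversized_beta_se_rejected(self):
        with pytest.raises(ValueError):
            psa.beta_from_mean_se(0.99, 0.5)


class TestDrawParameters:
    def test_identity_correlation_gives_independence(self):
        dists = psa.ParameterDistributionSet(marginals={
            "a": psa.Marginal("normal", (0.0, 1.0)),
            "b": psa.Marginal("normal", (0.0, 1.0)),
            "c": psa.Marginal("gamma", (4.0, 1.0)),
        })
        draws = psa.draw_parameters(dists, 10_000, seed=3)
        corr = draws.corr().to_numpy()
        off = corr[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 0.03)

    def test_target_correlation_reproduced(self):
        dists = psa.ParameterDistributionSet(marginals={
            "a": psa.Marginal("normal", (0.0, 1.0)),
            "b": psa.Marginal("normal", (0.0, 1.0)),
        })
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        draws = psa.draw_parameters(dists, 10_000, correlation=R, seed=4)
        assert draws["a"].corr(draws["b"]) == pytest.approx(0.5, abs=0.03)

    def test_mvn_block_uses_cholesky_of_vcov(self):
        cov = np.array([[0.04, 0.01], [0.01, 0.02]])
        dists = psa.ParameterDistributionSet(
            mvn_blocks=[(("b0", "b1"), (1.0, -0.5), cov)])
        draws = psa.draw_parameters(dists, 20_000, seed=5)
        assert draws["b0"].mean() == pytest.approx(1.0, abs=0.01)
        assert np.cov(draws["b0"], draws["b1"])[0, 1] == pytest.approx(0.01, abs=0.003)

    def test_non_psd_correlation_names_eigenvalue(self):
        dists = psa.ParameterDistributionSet(marginals={
            "a": psa.Marginal("normal", (0.0, 1.0)),
            "b": psa.Marginal("normal", (0.0, 1.0)),
        })
        R = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="eigenvalue"):
            psa.draw_parameters(dists, 10, correlation=R)

    def test_seed_reproducibility(self, calibrated_inputs):
        dists = psa.default_parameter_set(calibrated_inputs)
        d1 = psa.draw_parameters(dists, 50, seed=11)
        d2 = psa.draw_parameters(dists, 50, seed=11)
        pd.testing.assert_frame_equal(d1, d2)


class TestRunPSA:
    def test_degenerate_draws_reproduce_deterministic_result(self, calibrated_inputs):
        soc, iva = run_both_arms(calibrated_inputs)
        det = incremental(iva, soc)
        draws = pd.DataFrame({
            "hr_cv": [calibrated_inputs.hr_cv] * 3,
            "rr_hosp": [calibrated_inputs.rr_hosp] * 3,
        })
        cloud = psa.run_psa(calibrated_inputs, draws)
        assert np.allclose(cloud.draws["delta_cost"], det.delta_cost)
        assert np.allclose(cloud.draws["delta_qaly"], det.delta_qaly)

    def test_single_draw_rerun_is_identical(self, calibrated_inputs):
        dists = psa.default_parameter_set(calibrated_inputs)
        draws = psa.draw_parameters(dists, 1, seed=13)
        c1 = psa.run_psa(calibrated_inputs, draws, seed=13)
        c2 = psa.run_psa(calibrated_inputs, draws, seed=13)
        pd.testing.assert_frame_equal(c1.draws, c2.draws)

    def test_invalid_draws_rejected_and_counted(self, calibrated_inputs):
        draws = pd.DataFrame({"hr_cv": [0.9, -0.5, 0.8]})
        cloud = psa.run_psa(calibrated_inputs, draws)
        assert cloud.n_rejected == 1
        assert len(cloud.draws) == 2

    def test_mean_incremental_qaly_near_deterministic(self, small_cloud, calibrated_inputs):
        soc, iva = run_both_arms(calibrated_inputs)
        det = incremental(iva, soc)
        dq = small_cloud.draws["delta_qaly"]
        se = dq.std() / np.sqrt(len(dq))
        # distributions are centred near base values, so the cloud mean
        # should sit close to the deterministic increment
        assert abs(dq.mean() - det.delta_qaly) < 4 * se


class TestCEAC:
    def test_equals_brute_force_count(self, small_cloud):
        grid = [0.0, 10_000.0, 36_000.0, 80_000.0]
        curve = psa.ceac(small_cloud, grid)
        dq = small_cloud.draws["delta_qaly"].to_numpy()
        dc = small_cloud.draws["delta_cost"].to_numpy()
        for lam, p in zip(curve["threshold"], curve["p_cost_effective"]):
            count = sum(1 for q, c in zip(dq, dc) if lam * q - c > 0)
            assert p == count / len(dq)

    def test_zero_threshold_counts_cost_saving_draws(self, small_cloud):
        p0 = psa.ceac(small_cloud, [0.0])["p_cost_effective"].iloc[0]
        assert p0 == (small_cloud.draws["delta_cost"] < 0).mean()

    def test_monotone_when_all_gains_positive(self, small_cloud):
        sub = small_cloud.draws[small_cloud.draws["delta_qaly"] > 0]
        cloud = psa.PSACloud(sub, seed=0)
        curve = psa.ceac(cloud, np.linspace(0, 100_000, 21))
        assert np.all(np.diff(curve["p_cost_effective"]) >= 0)

    def test_all_dominant_draws_give_probability_one(self):
        cloud = psa.PSACloud(pd.DataFrame({
            "delta_cost": [-10.0, -5.0], "delta_qaly": [0.1, 0.2]}), seed=0)
        curve = psa.ceac(cloud, [0.0, 36_000.0, 1e6])
        assert (curve["p_cost_effective"] == 1.0).all()

    def test_value_invariant_to_grid_resolution(self, small_cloud):
        fine = psa.ceac(small_cloud, np.arange(0, 100_001, 500.0))
        coarse = psa.ceac(small_cloud, [36_000.0])
        at = fine.loc[fine["threshold"] == 36_000.0, "p_cost_effective"].iloc[0]
        assert at == coarse["p_cost_effective"].iloc[0]

    def test_empty_grid_rejected(self, small_cloud):
        with pytest.raises(ValueError):
            psa.ceac(small_cloud, [])
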