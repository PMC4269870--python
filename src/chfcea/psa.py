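"""Probabilistic sensitivity analysis and acceptability curves.

Parameter uncertainty is propagated by Monte Carlo: each draw replaces a set
of model parameters, the two-arm model is re-run in full, and the cloud of
(delta cost, delta QALY) pairs yields the cost-effectiveness acceptability
curve CEAC(lambda) = P(lambda * dQALY - dCost > 0).

Marginal families follow health-economics convention: lognormal for ratio
effects (HR, RR) parameterized from the published 95% CI; beta for utilities
and proportions; gamma for costs and rates.  Where no CI is published the
standard errors are documented assumptions (10% of the mean for utilities,
20% for costs).  Dependence is induced through a Gaussian copula whose
correlation matrix is factored by Cholesky decomposition; multivariate-normal
coefficient blocks (e.g. a fitted model's vcov) are drawn the same way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .economics import DEFAULT_THRESHOLD, incremental, set_parameter
from .markov_engine import StrategyInputs, run_both_arms

__all__ = [
    "Marginal",
    "lognormal_from_ci",
    "beta_from_mean_se",
    "gamma_from_mean_se",
    "ParameterDistributionSet",
    "default_parameter_set",
    "draw_parameters",
    "PSACloud",
    "run_psa",
    "ceac",
]


@dataclass
class Marginal:
    """One marginal distribution: family in {'lognormal','beta','gamma',
    'normal','fixed'} with scipy-style parameters."""

    family: str
    params: tuple

    def ppf(self, u: np.ndarray) -> np.ndarray:
        if self.family == "lognormal":
            mu, sigma = self.params
            return np.exp(stats.norm.ppf(u, mu, sigma))
        if self.family == "beta":
            a, b = self.params
            return stats.beta.ppf(u, a, b)
        if self.family == "gamma":
            k, theta = self.params
            return stats.gamma.ppf(u, k, scale=theta)
        if self.family == "normal":
            mu, sd = self.params
            return stats.norm.ppf(u, mu, sd)
        if self.family == "fixed":
            return np.full_like(np.asarray(u, dtype=float), self.params[0])
        raise ValueError(f"unknown marginal family {self.family!r}")


def lognormal_from_ci(point: float, lo: float, hi: float) -> Marginal:
    """Lognormal with median at the point estimate and sigma from the CI width."""
    sigma = (np.log(hi) - np.log(lo)) / (2.0 * 1.959963984540054)
    return Marginal("lognormal", (float(np.log(point)), float(sigma)))


def beta_from_mean_se(mean: float, se: float) -> Marginal:
    """Method-of-moments beta on [0, 1]."""
    if not 0.0 < mean < 1.0:
        raise ValueError("beta mean must be inside (0, 1)")
    nu = mean * (1.0 - mean) / se**2 - 1.0
    if nu <= 0:
        raise ValueError("SE too large for a beta distribution at this mean")
    return Marginal("beta", (mean * nu, (1.0 - mean) * nu))


def gamma_from_mean_se(mean: float, se: float) -> Marginal:
    """Method-of-moments gamma: shape k = (mean/se)^2, scale = se^2/mean."""
    if mean <= 0:
        raise ValueError("gamma mean must be positive")
    return Marginal("gamma", ((mean / se) ** 2, se**2 / mean))


@dataclass
class ParameterDistributionSet:
    """Named marginals plus optional multivariate-normal coefficient blocks.

    ``marginals`` maps model parameter names (as understood by
    :func:`chfcea.economics.set_parameter`) to :class:`Marginal`.
    ``mvn_blocks`` is a list of (names, mean vector, covariance matrix).
    """

    marginals: dict = field(default_factory=dict)
    mvn_blocks: list = field(default_factory=list)


def default_parameter_set(base: StrategyInputs) -> ParameterDistributionSet:
    """The documented base-case PSA distributions."""
    m = {
        "hr_cv": lognormal_from_ci(base.hr_cv, 0.80, 1.03),
        "rr_hosp": lognormal_from_ci(base.rr_hosp, 0.78, 0.93),
        "hosp_rate_soc": gamma_from_mean_se(base.hosp_rate_soc, 0.10 * base.hosp_rate_soc),
        "costs.mgmt_monthly": gamma_from_mean_se(base.costs.mgmt_monthly,
                                                 0.20 * base.costs.mgmt_monthly),
        "costs.per_diem_icu": gamma_from_mean_se(base.costs.per_diem_icu,
                                                 0.20 * base.costs.per_diem_icu),
        "costs.per_diem_cardiac": gamma_from_mean_se(base.costs.per_diem_cardiac,
                                                     0.20 * base.costs.per_diem_cardiac),
    }
    for k, u in enumerate(base.utilities, start=1):
        m[f"utility_nyha{k}"] = beta_from_mean_se(u, 0.10 * u)
    for k, d in enumerate(base.admission_disutilities, start=1):
        m[f"disutility_nyha{k}"] = beta_from_mean_se(d, 0.10 * d)
    return ParameterDistributionSet(marginals=m)


def _cholesky_psd(corr: np.ndarray) -> np.ndarray:
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() < -1e-10:
        raise ValueError(
            f"correlation matrix is not positive semi-definite "
            f"(smallest eigenvalue {eigvals.min():.3e})")
    jitter = 0.0 if eigvals.min() > 1e-12 else 1e-10
    return np.linalg.cholesky(corr + jitter * np.eye(len(corr)))


def draw_parameters(
    dists: ParameterDistributionSet,
    n_sims: int,
    correlation: np.ndarray | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Seed-reproducible parameter draws.

    Marginals are coupled through a Gaussian copula with the given
    correlation matrix (identity when omitted), factored by Cholesky
    decomposition; MVN blocks are drawn from their own covariance the same
    way.
    """
    rng = np.random.default_rng(seed)
    names = list(dists.marginals)
    k = len(names)
    out = {}
    if k:
        if correlation is None:
            correlation = np.eye(k)
        correlation = np.asarray(correlation, dtype=float)
        if correlation.shape != (k, k):
            raise ValueError(f"correlation must be {k}x{k} for {k} marginals")
        L = _cholesky_psd(correlation)
        z = rng.standard_normal((n_sims, k)) @ L.T
        u = stats.norm.cdf(z)
        for j, name in enumerate(names):
            out[name] = dists.marginals[name].ppf(u[:, j])
    for block_names, mean, cov in dists.mvn_blocks:
        Lb = np.linalg.cholesky(np.asarray(cov, dtype=float))
        zb = rng.standard_normal((n_sims, len(block_names))) @ Lb.T
        draws = np.asarray(mean, dtype=float) + zb
        for j, name in enumerate(block_names):
            out[name] = draws[:, j]
    return pd.DataFrame(out)


@dataclass
class PSACloud:
    """Paired incremental draws plus the parameter record that produced them."""

    draws: pd.DataFrame          # delta_cost, delta_qaly, delta_ly + parameters
    seed: int
    n_rejected: int = 0
    threshold: float = DEFAULT_THRESHOLD


def run_psa(
    base_inputs: StrategyInputs,
    draws: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    seed: int = 0,
) -> PSACloud:
    """One full two-arm evaluation per parameter draw.

    Draws producing invalid inputs (e.g. a non-positive rate) are rejected
    and counted rather than truncated.
    """
    records = []
    n_rejected = 0
    for _, row in draws.iterrows():
        try:
            inputs = base_inputs
            for name, value in row.items():
                inputs = set_parameter(inputs, name, float(value))
            soc, iva = run_both_arms(inputs)
        except (ValueError, KeyError):
            n_rejected += 1
            continue
        res = incremental(iva, soc, threshold)
        rec = dict(row)
        rec.update(delta_cost=res.delta_cost, delta_qaly=res.delta_qaly,
                   delta_ly=res.delta_ly)
        records.append(rec)
    return PSACloud(pd.DataFrame(records), seed=seed, n_rejected=n_rejected,
                    threshold=threshold)


def ceac(cloud: PSACloud, thresholds) -> pd.DataFrame:
    """P(ivabradine cost-effective) at each willingness-to-pay value."""
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ValueError("threshold grid is empty")
    if len(cloud.draws) == 0:
        raise ValueError("PSA cloud is empty")
    dq = cloud.draws["delta_qaly"].to_numpy()
    dc = cloud.draws["delta_cost"].to_numpy()
    prob = [(lam * dq - dc > 0).mean() for lam in thresholds]
    return pd.DataFrame({"threshold": thresholds, "p_cost_effective": prob})
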