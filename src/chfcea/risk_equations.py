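"""Risk equations: the four regression families driving the cohort model.

* Parametric proportional-hazards survival for cardiovascular death
  (Gompertz, exponential, Weibull) with right censoring, fitted by maximum
  likelihood; Kaplan-Meier as the non-parametric sensitivity input.
* Poisson regression with an exposure offset for recurrent all-cause
  hospital admissions (treatment effect = rate ratio).
* Proportional-odds (cumulative logit) models for the NYHA class
  distribution over time, fitted per treatment arm, with last observation
  carried forward beyond the trial window.
* A linear mixed model (random patient intercept) for repeated EQ-5D
  utilities, with NYHA-class fixed effects and a per-class decrement when an
  admission falls inside the +/-30 day window around the visit.

Time is measured in months throughout.  The Gompertz hazard is
``h(t) = lambda * exp(gamma * t)`` and covariates act proportionally on the
hazard, so ``S(t) = exp(-(lambda/gamma) * (exp(gamma*t) - 1) * exp(x'beta))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

__all__ = [
    "SurvivalModel",
    "RateModel",
    "NYHAModel",
    "UtilityModel",
    "fit_parametric_survival",
    "select_distribution",
    "predict_survival",
    "apply_hazard_ratio",
    "kaplan_meier",
    "km_overlay",
    "fit_poisson_rate",
    "fit_nyha_model",
    "predict_nyha",
    "fit_utility_model",
]

DISTRIBUTIONS = ("gompertz", "exponential", "weibull")


class FittingError(RuntimeError):
    """Raised when a model cannot be fitted (degenerate data, no events)."""


# ---------------------------------------------------------------------------
# Parametric survival
# ---------------------------------------------------------------------------

@dataclass
class SurvivalModel:
    """Fitted parametric baseline with proportional-hazards coefficients.

    ``baseline_params`` is (rate, shape): for Gompertz the shape is gamma per
    month, for Weibull the Weibull exponent p, for exponential it is the
    degenerate value (0.0 for the Gompertz family limit).
    """

    distribution: str
    baseline_params: tuple
    coefficients: dict
    loglik: float
    aic: float
    bic: float
    vcov: np.ndarray
    param_names: list
    converged: bool
    n: int
    n_events: int
    data_fingerprint: tuple = ()

    def linear_predictor(self, profile: dict | None) -> float:
        if not profile:
            return 0.0
        return float(sum(self.coefficients.get(k, 0.0) * v for k, v in profile.items()))


def _cumhaz(distribution: str, rate: float, shape: float, t: np.ndarray) -> np.ndarray:
    """Baseline cumulative hazard H0(t)."""
    t = np.asarray(t, dtype=float)
    if distribution == "exponential":
        return rate * t
    if distribution == "gompertz":
        if abs(shape) < 1e-12:
            return rate * t
        return rate / shape * np.expm1(shape * t)
    if distribution == "weibull":
        return rate * t**shape
    raise ValueError(f"unknown distribution {distribution!r}")


def _log_hazard(distribution: str, log_rate: float, shape: float, t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if distribution == "exponential":
        return np.full_like(t, log_rate)
    if distribution == "gompertz":
        return log_rate + shape * t
    if distribution == "weibull":
        return log_rate + np.log(shape) + (shape - 1.0) * np.log(t)
    raise ValueError(f"unknown distribution {distribution!r}")


def _negloglik_and_grad(theta, distribution, t, d, X):
    """Right-censored PH negative log-likelihood with analytic gradient.

    theta = (log_rate, shape_param, beta...) where shape_param is gamma for
    Gompertz and log(p) for Weibull; absent for exponential.
    """
    log_rate = theta[0]
    rate = np.exp(log_rate)
    has_shape = distribution != "exponential"
    if distribution == "gompertz":
        shape = theta[1]
    elif distribution == "weibull":
        shape = np.exp(theta[1])
    else:
        shape = 0.0
    beta = theta[2:] if has_shape else theta[1:]
    xb = X @ beta if X.shape[1] else np.zeros(len(t))
    exb = np.exp(xb)
    H = _cumhaz(distribution, rate, shape, t) * exb
    logh = _log_hazard(distribution, log_rate, shape, t) + xb
    ll = float(np.sum(d * logh) - np.sum(H))

    grad = np.empty_like(theta)
    grad[0] = np.sum(d) - np.sum(H)  # d/dlog_rate: H proportional to rate
    if distribution == "gompertz":
        if abs(shape) < 1e-8:
            dH_dg = rate * exb * t**2 / 2.0
        else:
            dH_dg = rate * exb * (t * np.exp(shape * t) * shape - np.expm1(shape * t)) / shape**2
        grad[1] = np.sum(d * t) - np.sum(dH_dg)
    elif distribution == "weibull":
        logt = np.log(t)
        dll_dp = np.sum(d * (1.0 / shape + logt)) - np.sum(H * logt)
        grad[1] = shape * dll_dp  # chain rule for log(p)
    k0 = 2 if has_shape else 1
    for j in range(X.shape[1]):
        grad[k0 + j] = np.sum(d * X[:, j]) - np.sum(H * X[:, j])
    return -ll, -grad


def _numeric_hessian(fun, theta, eps=1e-5):
    k = len(theta)
    hess = np.zeros((k, k))
    for i in range(k):
        step = eps * max(1.0, abs(theta[i]))
        tp, tm = theta.copy(), theta.copy()
        tp[i] += step
        tm[i] -= step
        _, gp = fun(tp)
        _, gm = fun(tm)
        hess[:, i] = (gp - gm) / (2.0 * step)
    return (hess + hess.T) / 2.0


def _fingerprint(t, d):
    return (len(t), int(d.sum()), round(float(np.sum(t)), 6))


def fit_parametric_survival(
    records: pd.DataFrame,
    distribution: str = "gompertz",
    covariates: list | None = None,
    max_iter: int = 500,
) -> SurvivalModel:
    """Maximum-likelihood PH fit on right-censored times.

    ``records`` needs columns ``time`` (months, > 0) and ``event`` (1 = CV
    death observed) plus any covariate columns named in ``covariates``.
    """
    if distribution not in DISTRIBUTIONS:
        raise ValueError(f"distribution must be one of {DISTRIBUTIONS}")
    covariates = list(covariates or [])
    t = records["time"].to_numpy(float)
    d = records["event"].to_numpy(float)
    if (t <= 0).any():
        raise FittingError("all survival times must be positive")
    if d.sum() == 0:
        raise FittingError("no events observed; survival model is not estimable")
    X = records[covariates].to_numpy(float) if covariates else np.empty((len(t), 0))

    crude = np.log(d.sum() / t.sum())
    has_shape = distribution != "exponential"
    theta0 = np.concatenate([[crude], [0.0] if has_shape else [], np.zeros(len(covariates))])

    fun = lambda th: _negloglik_and_grad(th, distribution, t, d, X)
    res = minimize(fun, theta0, jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-9})
    theta = res.x
    ll = -res.fun
    hess = _numeric_hessian(fun, theta)
    try:
        vcov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        vcov = np.full((len(theta), len(theta)), np.nan)

    rate = float(np.exp(theta[0]))
    if distribution == "gompertz":
        shape = float(theta[1])
    elif distribution == "weibull":
        shape = float(np.exp(theta[1]))
    else:
        shape = 0.0
    k0 = 2 if has_shape else 1
    coeffs = {name: float(theta[k0 + j]) for j, name in enumerate(covariates)}
    k = len(theta)
    names = ["log_rate"] + (["shape"] if has_shape else []) + covariates
    return SurvivalModel(
        distribution=distribution,
        baseline_params=(rate, shape),
        coefficients=coeffs,
        loglik=ll,
        aic=-2.0 * ll + 2.0 * k,
        bic=-2.0 * ll + k * np.log(len(t)),
        vcov=vcov,
        param_names=names,
        converged=bool(res.success),
        n=len(t),
        n_events=int(d.sum()),
        data_fingerprint=_fingerprint(t, d),
    )


def select_distribution(models: list) -> pd.DataFrame:
    """Rank fitted survival models by AIC (ascending, stable on ties).

    All models must have been fitted on the same data; BIC is reported
    alongside for the same ranking.
    """
    if len(models) < 2:
        raise ValueError("need at least two fitted models to rank")
    fps = {m.data_fingerprint for m in models}
    if len(fps) > 1:
        raise ValueError("models were fitted on different datasets")
    rows = [
        {"distribution": m.distribution, "aic": m.aic, "bic": m.bic,
         "loglik": m.loglik, "order_in": i}
        for i, m in enumerate(models)
    ]
    df = pd.DataFrame(rows).sort_values(["aic", "order_in"], kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.drop(columns="order_in").reset_index(drop=True)


def predict_survival(model: SurvivalModel, profile: dict | None, t_months) -> np.ndarray | float:
    """S(t | profile) from the fitted PH model; S(0) = 1, non-increasing."""
    t = np.asarray(t_months, dtype=float)
    if (t < 0).any():
        raise ValueError("survival requested at negative time")
    rate, shape = model.baseline_params
    H = _cumhaz(model.distribution, rate, shape, np.atleast_1d(t))
    s = np.exp(-H * np.exp(model.linear_predictor(profile)))
    return float(s[0]) if np.ndim(t_months) == 0 else s


def apply_hazard_ratio(survival, hr: float):
    """Proportional-hazards identity: S_treated(t) = S(t) ** HR."""
    if hr <= 0:
        raise ValueError("hazard ratio must be positive")
    return np.asarray(survival) ** hr if np.ndim(survival) else float(survival**hr)


def kaplan_meier(records: pd.DataFrame):
    """Product-limit survival estimate (lifelines) on time/event columns."""
    from lifelines import KaplanMeierFitter

    if len(records) == 0:
        raise FittingError("empty input to Kaplan-Meier estimator")
    kmf = KaplanMeierFitter()
    kmf.fit(records["time"], event_observed=records["event"])
    return kmf


def km_overlay(records: pd.DataFrame, models: list, t_grid=None) -> pd.DataFrame:
    """KM curve vs fitted parametric curves on a shared grid (for plots)."""
    kmf = kaplan_meier(records)
    if t_grid is None:
        t_grid = np.linspace(0.0, float(records["time"].max()), 60)
    out = pd.DataFrame({"t": t_grid, "kaplan_meier": kmf.survival_function_at_times(t_grid).to_numpy()})
    for m in models:
        out[m.distribution] = predict_survival(m, None, t_grid)
    return out


# ---------------------------------------------------------------------------
# Poisson admission rates
# ---------------------------------------------------------------------------

@dataclass
class RateModel:
    """Poisson rate model: log rate per patient-month with PH-style effects."""

    log_baseline_rate: float
    coefficients: dict
    vcov: np.ndarray
    param_names: list
    loglik: float
    converged: bool
    non_estimable: bool = False

    @property
    def rate_ratio(self) -> float:
        return float(np.exp(self.coefficients.get("treat", 0.0)))

    def rate(self, profile: dict | None = None) -> float:
        lp = sum(self.coefficients.get(k, 0.0) * v for k, v in (profile or {}).items())
        return float(np.exp(self.log_baseline_rate + lp))


def fit_poisson_rate(records: pd.DataFrame, covariates: list | None = None) -> RateModel:
    """Exposure-offset Poisson MLE on per-patient admission counts.

    ``records`` needs ``n_admissions`` and ``exposure_months`` (> 0) columns
    plus covariates (``treat`` for the treatment rate ratio).
    """
    import statsmodels.api as sm

    covariates = list(covariates or [])
    if (records["exposure_months"] <= 0).any() or records["exposure_months"].sum() <= 0:
        raise FittingError("non-positive exposure in Poisson rate model")
    y = records["n_admissions"].to_numpy(float)
    X = sm.add_constant(records[covariates].to_numpy(float)) if covariates else \
        np.ones((len(records), 1))
    offset = np.log(records["exposure_months"].to_numpy(float))

    non_estimable = False
    if "treat" in covariates:
        for arm in (0, 1):
            if y[records["treat"].to_numpy() == arm].sum() == 0:
                non_estimable = True
    model = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset)
    res = model.fit()
    params = np.asarray(res.params, dtype=float)
    coeffs = {name: float(params[j + 1]) for j, name in enumerate(covariates)}
    return RateModel(
        log_baseline_rate=float(params[0]),
        coefficients=coeffs,
        vcov=np.asarray(res.cov_params(), dtype=float),
        param_names=["log_rate"] + covariates,
        loglik=float(res.llf),
        converged=bool(res.converged),
        non_estimable=non_estimable,
    )


# ---------------------------------------------------------------------------
# NYHA proportional-odds model (arm-stratified)
# ---------------------------------------------------------------------------

@dataclass
class NYHAModel:
    """Cumulative-logit NYHA model per arm: P(class <= k | t) = expit(c_k - b*t).

    ``arms`` maps arm name -> dict(cutpoints: 3 increasing thresholds,
    slope: per-month drift, degenerate_class: int or None).  The prediction
    horizon marks where last-observation-carried-forward takes over.
    """

    arms: dict
    prediction_horizon: float = 29.0

    def class_probabilities(self, arm: str, t: float) -> np.ndarray:
        a = self.arms[arm]
        if a.get("degenerate_class") is not None:
            p = np.zeros(4)
            p[a["degenerate_class"] - 1] = 1.0
            return p
        cum = expit(np.asarray(a["cutpoints"]) - a["slope"] * t)
        cum = np.concatenate([[0.0], cum, [1.0]])
        return np.diff(cum)


def fit_nyha_model(records: pd.DataFrame, prediction_horizon: float = 29.0) -> NYHAModel:
    """Arm-stratified proportional-odds fit of NYHA class on visit month.

    ``records`` is long-format with columns ``arm``, ``month``, ``nyha``
    (classes 1-4).  A single-class arm yields a flagged degenerate fit.
    """
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    if not records["nyha"].isin([1, 2, 3, 4]).all():
        raise FittingError("NYHA classes must be in {1, 2, 3, 4}")
    arms = {}
    for arm, grp in records.groupby("arm"):
        classes = np.sort(grp["nyha"].unique())
        if len(classes) == 1:
            arms[arm] = {"cutpoints": None, "slope": 0.0,
                         "degenerate_class": int(classes[0])}
            continue
        endog = pd.Series(
            pd.Categorical(grp["nyha"], categories=sorted(grp["nyha"].unique()),
                           ordered=True),
            index=grp.index, name="nyha")
        mod = OrderedModel(endog, grp[["month"]].astype(float), distr="logit")
        res = mod.fit(method="bfgs", disp=False)
        thresholds = mod.transform_threshold_params(res.params)[1:-1]
        # re-embed into the full 1..4 scale when some classes are absent
        cuts_full = []
        obs_classes = sorted(grp["nyha"].unique())
        ti = 0
        for k in (1, 2, 3):
            if k in obs_classes and any(c > k for c in obs_classes):
                cuts_full.append(float(thresholds[ti]))
                ti += 1
            elif all(c > k for c in obs_classes):
                cuts_full.append(-30.0)  # no mass at or below k
            else:
                cuts_full.append(30.0)  # no mass above k
        # OrderedModel uses P(y<=k)=F(c_k - xb); slope sign matches directly
        arms[arm] = {"cutpoints": np.asarray(cuts_full),
                     "slope": float(np.asarray(res.params)[0]),
                     "degenerate_class": None}
    return NYHAModel(arms=arms, prediction_horizon=prediction_horizon)


def predict_nyha(model: NYHAModel, arm: str, t_months: float, mode: str = "locf") -> np.ndarray:
    """Four-class NYHA distribution at month ``t``.

    ``mode='locf'`` freezes the distribution at the prediction horizon (the
    trial end); ``mode='trend'`` continues the fitted cumulative-logit drift.
    """
    if mode not in ("locf", "trend"):
        raise ValueError("mode must be 'locf' or 'trend'")
    t_eff = min(t_months, model.prediction_horizon) if mode == "locf" else t_months
    p = model.class_probabilities(arm, t_eff)
    return p / p.sum()


# ---------------------------------------------------------------------------
# Mixed-effects utility regression
# ---------------------------------------------------------------------------

@dataclass
class UtilityModel:
    """Repeated-measures EQ-5D model.

    Fixed effects: intercept = NYHA I with no admission in the +/-30 day
    window; additive offsets for NYHA II-IV; per-class decrement when an
    admission falls in the window.  Random patient intercept plus residual.
    """

    intercept: float
    nyha_offsets: dict            # {2: ., 3: ., 4: .}
    hosp_offsets: dict            # {1: ., 2: ., 3: ., 4: .} (negative = worse)
    random_intercept_sd: float
    residual_sd: float
    flagged_degenerate: bool = False

    def state_utility(self, nyha: int, hospitalized: bool = False) -> float:
        u = self.intercept + (self.nyha_offsets.get(nyha, 0.0) if nyha > 1 else 0.0)
        if hospitalized:
            u += self.hosp_offsets.get(nyha, 0.0)
        return float(min(u, 1.0))

    def utilities_by_class(self) -> np.ndarray:
        return np.array([self.state_utility(k) for k in (1, 2, 3, 4)])

    def decrements_by_class(self) -> np.ndarray:
        """Positive per-admission utility decrements per NYHA class."""
        return np.array([-self.hosp_offsets.get(k, 0.0) for k in (1, 2, 3, 4)])


def _utility_design(records: pd.DataFrame):
    X = pd.DataFrame({"const": 1.0}, index=records.index)
    for k in (2, 3, 4):
        X[f"nyha{k}"] = (records["nyha"] == k).astype(float)
    for k in (1, 2, 3, 4):
        X[f"hosp_nyha{k}"] = ((records["nyha"] == k) & records["hosp_window"]).astype(float)
    return X


def fit_utility_model(records: pd.DataFrame) -> UtilityModel:
    """Fit the random-intercept utility model on long-format EQ-5D data.

    ``records`` columns: ``id`` (patient), ``nyha``, ``hosp_window`` (bool),
    ``utility``.  Noise-free data (zero within-cell variance) falls back to
    exact cell means with zero variance components, flagged.
    """
    import statsmodels.api as sm

    if "id" not in records.columns and "patient_id" in records.columns:
        records = records.rename(columns={"patient_id": "id"})
    y = records["utility"].to_numpy(float)
    X = _utility_design(records)
    cell = records.groupby(["nyha", "hosp_window"])["utility"]
    within_var = float((cell.var(ddof=0).fillna(0.0) * cell.count()).sum() / len(records))
    if within_var < 1e-12:
        means = cell.mean()
        base = float(means.get((1, False), means[~means.index.get_level_values("hosp_window")].iloc[0]))
        nyha_off, hosp_off = {}, {}
        for k in (2, 3, 4):
            if (k, False) in means.index:
                nyha_off[k] = float(means[(k, False)]) - base
        for k in (1, 2, 3, 4):
            if (k, True) in means.index:
                ref = base + nyha_off.get(k, 0.0) if k > 1 else base
                hosp_off[k] = float(means[(k, True)]) - ref
        return UtilityModel(base, nyha_off, hosp_off, 0.0, 0.0, flagged_degenerate=True)

    model = sm.MixedLM(y, X.to_numpy(float), groups=records["id"].to_numpy())
    res = model.fit(reml=True, method="lbfgs")
    fe = dict(zip(X.columns, np.asarray(res.fe_params, dtype=float)))
    return UtilityModel(
        intercept=fe["const"],
        nyha_offsets={k: fe[f"nyha{k}"] for k in (2, 3, 4)},
        hosp_offsets={k: fe[f"hosp_nyha{k}"] for k in (1, 2, 3, 4)},
        random_intercept_sd=float(np.sqrt(max(np.asarray(res.cov_re)[0, 0], 0.0))),
        residual_sd=float(np.sqrt(max(res.scale, 0.0))),
    )
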