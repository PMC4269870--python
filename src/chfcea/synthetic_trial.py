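"""SHIFT-like synthetic individual patient data with known ground truth.

The real trial data behind the cost-utility model are not public, so every
fitting and engine stage is exercised against simulated patients whose
generating parameters are known exactly:

* cardiovascular death times from a Gompertz proportional-hazards process
  (treatment log-HR plus optional baseline-covariate effects),
* non-CV death from an age/sex life table, independent of the CV process,
* recurrent all-cause hospital admissions from a Poisson process with a
  treatment log-rate-ratio, tagged HF / other-CV / non-CV,
* NYHA class observations from a cumulative-logit (proportional-odds)
  process with a per-arm time drift, observed at scheduled visits,
* repeated EQ-5D utilities = fixed effects (NYHA class, admission within
  +/-30 days of the visit) + patient random intercept + residual, truncated
  to the EQ-5D tariff range [-0.594, 1].

All times are in months; default parameter magnitudes are documented,
config-overridable assumptions (the source trial's baselines are unpublished).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "TruthParams",
    "TrialData",
    "PatientRecord",
    "generate_cohort",
    "simulate_followup",
    "survival_frame",
    "admission_frame",
    "DEFAULT_COVARIATES",
]

EQ5D_MIN, EQ5D_MAX = -0.594, 1.0
VISIT_MONTHS = (0, 4, 8, 12, 16, 20, 24, 28)


class ConfigurationError(ValueError):
    pass


class SimulationError(RuntimeError):
    pass


# name, family, params — assumed baseline mix (trial baselines unpublished)
DEFAULT_COVARIATES = [
    ("lvef", "normal", {"mean": 29.0, "sd": 5.0}),
    ("hf_duration", "lognormal", {"mean_log": 0.7, "sd_log": 0.9}),
    ("beta_blocker", "categorical",
     {"levels": [0, 1, 2, 3], "probs": [0.11, 0.37, 0.26, 0.26]}),
    ("diabetes", "bernoulli", {"p": 0.30}),
    ("prior_cad", "bernoulli", {"p": 0.60}),
]


@dataclass
class CohortConfig:
    n_patients: int = 1000
    mean_age: float = 60.0
    sd_age: float = 10.0
    female_fraction: float = 0.25
    arm_allocation: float = 0.5
    followup_months: float = 29.0
    nyha_baseline_probs: tuple = (0.02, 0.50, 0.45, 0.03)
    covariate_spec: list = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ConfigurationError("female_fraction must be in [0, 1]")
        if not 0.0 < self.arm_allocation < 1.0:
            raise ConfigurationError("arm_allocation must be in (0, 1)")
        if self.followup_months <= 0:
            raise ConfigurationError("followup_months must be positive")
        if abs(sum(self.nyha_baseline_probs) - 1.0) > 1e-9:
            raise ConfigurationError("nyha_baseline_probs must sum to 1")


def _nyha_cutpoints(probs=(0.02, 0.50, 0.45, 0.03)) -> np.ndarray:
    cum = np.cumsum(probs)[:3]
    return np.log(cum / (1.0 - cum))


@dataclass
class TruthParams:
    """Known generating parameters (monthly time scale)."""

    gompertz_rate: float = 0.004          # baseline CV hazard scale / month
    gompertz_shape: float = 0.01          # hazard log-slope / month
    log_hr_treatment: float = float(np.log(0.90))
    covariate_betas: dict = field(default_factory=dict)
    hosp_rate: float = 0.03               # admissions / patient-month (SoC)
    log_rr_treatment: float = float(np.log(0.83))
    admission_cause_probs: tuple = (0.45, 0.30, 0.25)   # hf / other_cv / non_cv
    nyha_cutpoints: np.ndarray = field(default_factory=_nyha_cutpoints)
    nyha_time_slope: dict = field(
        default_factory=lambda: {"soc": 0.0, "ivabradine": 0.0})
    utility_intercept: float = 0.82       # NYHA I, no admission window
    utility_nyha_offsets: tuple = (-0.08, -0.18, -0.36)  # II, III, IV
    utility_hosp_offsets: tuple = (-0.04, -0.07, -0.10, -0.29)  # per class
    utility_random_intercept_sd: float = 0.10
    utility_residual_sd: float = 0.08

    def __post_init__(self) -> None:
        if self.gompertz_rate <= 0:
            raise ConfigurationError("gompertz_rate must be positive")
        if self.hosp_rate < 0:
            raise ConfigurationError("hosp_rate must be non-negative")
        cuts = np.asarray(self.nyha_cutpoints, dtype=float)
        if not np.all(np.diff(cuts) > 0):
            raise ConfigurationError("nyha_cutpoints must be strictly increasing")
        if self.utility_random_intercept_sd < 0 or self.utility_residual_sd < 0:
            raise ConfigurationError("utility SDs must be non-negative")


@dataclass
class PatientRecord:
    """One synthetic subject: covariates, events, repeated observations."""

    id: int
    arm: str
    covariates: dict
    death_time: float          # months; followup if censored
    death_cause: str           # 'cv', 'non_cv', 'none'
    admission_times: list      # [(month, cause), ...]
    nyha_obs: list             # [(month, class), ...]
    eq5d_obs: list             # [(month, utility), ...]


@dataclass
class TrialData:
    """Completed trial as tidy tables (one row per patient / per observation)."""

    patients: pd.DataFrame     # id, arm, treat, covariates, death_time, death_cause
    admissions: pd.DataFrame   # id, month, cause
    nyha_obs: pd.DataFrame     # id, arm, month, nyha
    eq5d_obs: pd.DataFrame     # id, month, nyha, hosp_window, utility

    def patient_records(self):
        adm = self.admissions.groupby("id") if len(self.admissions) else None
        covcols = [c for c in self.patients.columns
                   if c not in ("id", "arm", "treat", "death_time", "death_cause")]
        for _, row in self.patients.iterrows():
            pid = int(row["id"])
            a = (adm.get_group(pid)[["month", "cause"]].to_records(index=False).tolist()
                 if adm is not None and pid in self.admissions["id"].values else [])
            ny = self.nyha_obs.loc[self.nyha_obs["id"] == pid, ["month", "nyha"]]
            eq = self.eq5d_obs.loc[self.eq5d_obs["id"] == pid, ["month", "utility"]]
            yield PatientRecord(
                id=pid, arm=row["arm"], covariates={c: row[c] for c in covcols},
                death_time=float(row["death_time"]), death_cause=row["death_cause"],
                admission_times=a,
                nyha_obs=list(ny.itertuples(index=False, name=None)),
                eq5d_obs=list(eq.itertuples(index=False, name=None)),
            )

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.patients.to_csv(out / "patients.csv", index=False)
        self.admissions.to_csv(out / "admissions.csv", index=False)
        self.nyha_obs.to_csv(out / "nyha_obs.csv", index=False)
        self.eq5d_obs.to_csv(out / "eq5d_obs.csv", index=False)


def _draw_covariate(rng, family, params, n):
    if family == "normal":
        return rng.normal(params["mean"], params["sd"], n)
    if family == "lognormal":
        return rng.lognormal(params["mean_log"], params["sd_log"], n)
    if family == "bernoulli":
        return (rng.random(n) < params["p"]).astype(int)
    if family == "categorical":
        return rng.choice(params["levels"], size=n, p=params["probs"])
    raise ConfigurationError(f"unknown covariate distribution family {family!r}")


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw baseline covariates and randomize arms (reproducible by seed)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    df = pd.DataFrame({"id": np.arange(n)})
    df["treat"] = (rng.random(n) < config.arm_allocation).astype(int)
    df["arm"] = np.where(df["treat"] == 1, "ivabradine", "soc")
    df["age"] = rng.normal(config.mean_age, config.sd_age, n)
    df["female"] = (rng.random(n) < config.female_fraction).astype(int)
    df["nyha_baseline"] = rng.choice([1, 2, 3, 4], size=n, p=config.nyha_baseline_probs)
    for name, family, params in config.covariate_spec:
        df[name] = _draw_covariate(rng, family, params, n)
    return df


def _gompertz_times(rng, n, rate, shape, lp):
    """Inverse-transform Gompertz PH draws: H(t)*e^lp = E ~ Exp(1)."""
    e = rng.exponential(1.0, n)
    scaled = e / (rate * np.exp(lp))
    if abs(shape) < 1e-12:
        return scaled
    return np.log1p(shape * scaled) / shape


def _noncv_times(rng, ages, female, life_table, horizon_months):
    """Non-CV death times from annual life-table probabilities (months)."""
    n = len(ages)
    times = np.full(n, np.inf)
    n_years = int(np.ceil(horizon_months / 12.0))
    for sex, mask in (("f", female == 1), ("m", female == 0)):
        if not mask.any():
            continue
        idx = np.where(mask)[0]
        for i in idx:
            q = life_table.annual_qx_path(ages[i], n_years, sex)
            monthly_q = 1.0 - (1.0 - np.repeat(q, 12)[: int(np.ceil(horizon_months))]) ** (1 / 12)
            u = rng.random(len(monthly_q))
            hit = np.nonzero(u < monthly_q)[0]
            if len(hit):
                times[i] = hit[0] + rng.random()
    return times


def simulate_followup(
    patients: pd.DataFrame,
    truth: TruthParams,
    seed: int,
    followup_months: float = 29.0,
    life_table=None,
    visit_months=VISIT_MONTHS,
) -> TrialData:
    """Complete the cohort: deaths, admissions, NYHA and EQ-5D observations."""
    rng = np.random.default_rng(seed)
    n = len(patients)
    treat = patients["treat"].to_numpy()

    lp = treat * truth.log_hr_treatment
    for name, beta in truth.covariate_betas.items():
        lp = lp + beta * patients[name].to_numpy(float)
    if not np.all(np.isfinite(lp)):
        raise SimulationError("non-finite linear predictor in survival process")

    cv_t = _gompertz_times(rng, n, truth.gompertz_rate, truth.gompertz_shape, lp)
    if life_table is not None:
        noncv_t = _noncv_times(rng, patients["age"].to_numpy(), patients["female"].to_numpy(),
                               life_table, followup_months)
    else:
        noncv_t = np.full(n, np.inf)

    death_t = np.minimum(cv_t, noncv_t)
    observed = np.minimum(death_t, followup_months)
    cause = np.where(death_t > followup_months, "none",
                     np.where(cv_t <= noncv_t, "cv", "non_cv"))

    out = patients.copy()
    out["death_time"] = observed
    out["death_cause"] = cause

    # recurrent admissions over each patient's exposure
    log_rate = np.log(truth.hosp_rate) if truth.hosp_rate > 0 else -np.inf
    rate = np.where(treat == 1, np.exp(log_rate + truth.log_rr_treatment),
                    truth.hosp_rate)
    counts = rng.poisson(rate * observed) if truth.hosp_rate > 0 else np.zeros(n, int)
    rows = np.repeat(np.arange(n), counts)
    adm_month = rng.random(len(rows)) * observed[rows]
    adm_cause = rng.choice(["hf", "other_cv", "non_cv"], size=len(rows),
                           p=truth.admission_cause_probs)
    admissions = pd.DataFrame({
        "id": patients["id"].to_numpy()[rows], "month": adm_month, "cause": adm_cause,
    }).sort_values(["id", "month"], ignore_index=True)

    # scheduled NYHA / EQ-5D visits while alive and in follow-up
    cuts = np.asarray(truth.nyha_cutpoints, dtype=float)
    arm_label = out["arm"].to_numpy()
    b_i = rng.normal(0.0, truth.utility_random_intercept_sd, n)
    nyha_rows, eq_rows = [], []
    u_by_class = truth.utility_intercept + np.concatenate(
        [[0.0], np.asarray(truth.utility_nyha_offsets)])
    hosp_off = np.asarray(truth.utility_hosp_offsets)
    adm_by_id = {pid: g["month"].to_numpy() for pid, g in admissions.groupby("id")}
    from scipy.special import expit

    for v in visit_months:
        alive = observed > v
        if v > followup_months or not alive.any():
            continue
        idx = np.where(alive)[0]
        slope = np.array([truth.nyha_time_slope[a] for a in arm_label[idx]])
        cum = expit(cuts[None, :] - (slope * v)[:, None])
        u = rng.random(len(idx))
        k = 1 + (u[:, None] > cum).sum(axis=1)  # class 1..4
        hospw = np.array([
            bool(len(adm_by_id.get(int(out["id"].iloc[i]), np.empty(0)))
                 and np.any(np.abs(adm_by_id[int(out["id"].iloc[i])] - v) <= 1.0))
            for i in idx
        ])
        eps = rng.normal(0.0, truth.utility_residual_sd, len(idx))
        util = u_by_class[k - 1] + hospw * hosp_off[k - 1] + b_i[idx] + eps
        util = np.clip(util, EQ5D_MIN, EQ5D_MAX)
        pid = out["id"].to_numpy()[idx]
        nyha_rows.append(pd.DataFrame({
            "id": pid, "arm": arm_label[idx], "month": float(v), "nyha": k}))
        eq_rows.append(pd.DataFrame({
            "id": pid, "month": float(v), "nyha": k,
            "hosp_window": hospw, "utility": util}))

    nyha_obs = (pd.concat(nyha_rows, ignore_index=True) if nyha_rows
                else pd.DataFrame(columns=["id", "arm", "month", "nyha"]))
    eq5d_obs = (pd.concat(eq_rows, ignore_index=True) if eq_rows
                else pd.DataFrame(columns=["id", "month", "nyha", "hosp_window", "utility"]))
    return TrialData(out, admissions, nyha_obs, eq5d_obs)


def survival_frame(trial: TrialData) -> pd.DataFrame:
    """Time-to-CV-death frame: non-CV death and trial end are censoring."""
    p = trial.patients
    df = pd.DataFrame({
        "time": p["death_time"].clip(lower=1e-6),
        "event": (p["death_cause"] == "cv").astype(int),
        "treat": p["treat"],
    })
    for c in p.columns:
        if c not in ("id", "arm", "treat", "death_time", "death_cause"):
            df[c] = p[c].to_numpy()
    return df


def admission_frame(trial: TrialData) -> pd.DataFrame:
    """Per-patient admission counts with exposure for the Poisson rate model."""
    counts = trial.admissions.groupby("id").size()
    p = trial.patients
    return pd.DataFrame({
        "n_admissions": p["id"].map(counts).fillna(0).astype(int),
        "exposure_months": p["death_time"].clip(lower=1e-6),
        "treat": p["treat"],
    })
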