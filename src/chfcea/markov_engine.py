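"""Two-state monthly Markov cohort engine (alive / dead).

Each strategy arm is evaluated as a deterministic cohort trace: the alive
fraction is the product of cardiovascular survival (parametric baseline with
the treatment hazard ratio applied as ``S**HR``) and life-table non-CV
survival, assumed independent.  NYHA occupancy and expected admissions are
overlaid on the alive state to accrue utilities and costs; nothing feeds back
into survival.  Membership for accrual is the alive fraction at cycle start
(deaths at cycle boundaries); a half-cycle correction is available as a flag.

Accruals per cycle m (discount factor ``(1+r)^(-m/12)``):

* life-years:  alive(m) / 12
* QALYs:       alive(m) * [sum_k occ_k u_k - adm_rate * sum_k occ_k d_k] / 12
  (each expected admission removes utility d_k for exactly one cycle)
* costs:       drug + HF management per alive month, admissions times
  cause-mix episode costs, plus the one-off titration ECG in cycle 0 of the
  ivabradine arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .costing import ADMISSION_CAUSES, CostSchedule, episode_cost
from .life_tables import LifeTable, monthly_noncv_survival
from .risk_equations import NYHAModel, _cumhaz, predict_nyha

__all__ = [
    "StrategyInputs",
    "StrategyResult",
    "discount_factor",
    "overall_survival",
    "build_trace",
    "accrue",
    "run_strategy",
    "run_both_arms",
    "microsimulate",
]


def discount_factor(annual_rate: float, cycle_m) -> np.ndarray | float:
    """Discount factor (1 + rate)^(-m/12) at the start of cycle ``m``."""
    if annual_rate < 0:
        raise ValueError("discount rate must be non-negative")
    m = np.asarray(cycle_m, dtype=float)
    if (m < 0).any():
        raise ValueError("cycle index must be non-negative")
    f = (1.0 + annual_rate) ** (-m / 12.0)
    return float(f) if np.ndim(cycle_m) == 0 else f


@dataclass
class CVBaseline:
    """Baseline CV survival: parametric (gompertz/exponential/weibull) or a
    Kaplan-Meier step function extended beyond its support at its average
    within-support hazard."""

    distribution: str = "gompertz"
    rate: float = 0.004
    shape: float = 0.01
    km_times: np.ndarray | None = None
    km_surv: np.ndarray | None = None

    def cumhaz(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.distribution == "kaplan_meier":
            s = np.interp(t, self.km_times, self.km_surv)
            tmax = float(self.km_times[-1])
            smax = max(float(self.km_surv[-1]), 1e-12)
            h_avg = -np.log(smax) / tmax
            inside = -np.log(np.maximum(s, 1e-12))
            return np.where(t <= tmax, inside, -np.log(smax) + h_avg * (t - tmax))
        return _cumhaz(self.distribution, self.rate, self.shape, t)


@dataclass
class StrategyInputs:
    """Everything one arm evaluation needs.

    Treatment effects (``hr_cv``, ``rr_hosp``, the ivabradine drug cost and
    titration ECG) are applied only when ``arm == 'ivabradine'``.  With a
    finite ``treatment_duration_months``, the drug cost always stops at
    discontinuation; whether the clinical effects persist afterwards or the
    hazards revert to baseline is set by ``discontinuation`` ('persist',
    matching the published scenario behaviour, or 'revert').
    """

    arm: str = "soc"
    cv_baseline: CVBaseline = field(default_factory=CVBaseline)
    hr_cv: float = 0.90
    life_table: LifeTable | None = None
    age0: float = 60.0
    female_fraction: float = 0.25
    hosp_rate_soc: float = 0.04
    rr_hosp: float = 0.83
    nyha: object = (0.02, 0.50, 0.45, 0.03)   # fixed mix or NYHAModel
    nyha_mode: str = "locf"
    utilities: tuple = (0.82, 0.74, 0.64, 0.46)
    admission_disutilities: tuple = (0.04, 0.07, 0.10, 0.29)
    costs: CostSchedule = field(default_factory=CostSchedule)
    horizon_months: int = 480
    discount_annual: float = 0.035
    treatment_duration_months: float | None = None
    discontinuation: str = "persist"
    trial_months: float = 29.0
    half_cycle: bool = False
    utility_age_decrement_per_year: float = 0.0
    # multiplicative adjustment of the SoC baseline CV hazard (subgroups)
    hazard_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.arm not in ("soc", "ivabradine"):
            raise ValueError("arm must be 'soc' or 'ivabradine'")
        if self.hr_cv <= 0 or self.rr_hosp <= 0:
            raise ValueError("hazard ratio and rate ratio must be positive")
        if self.horizon_months < 1:
            raise ValueError("horizon must cover at least one cycle")
        if self.discontinuation not in ("persist", "revert"):
            raise ValueError("discontinuation must be 'persist' or 'revert'")


@dataclass
class StrategyResult:
    arm: str
    ly: float
    qaly: float
    cost_drug: float
    cost_hosp: float
    cost_mgmt: float
    cost_oneoff: float

    @property
    def total_cost(self) -> float:
        return self.cost_drug + self.cost_hosp + self.cost_mgmt + self.cost_oneoff


def _cv_survival_curve(inputs: StrategyInputs, months: np.ndarray) -> np.ndarray:
    h0 = inputs.cv_baseline.cumhaz(months) * inputs.hazard_multiplier
    if inputs.arm != "ivabradine":
        return np.exp(-h0)
    dur = inputs.treatment_duration_months
    if dur is None or inputs.discontinuation == "persist":
        return np.exp(-inputs.hr_cv * h0)
    h_dur = inputs.cv_baseline.cumhaz(np.asarray([dur]))[0] * inputs.hazard_multiplier
    h = np.where(months <= dur, inputs.hr_cv * h0,
                 inputs.hr_cv * h_dur + (h0 - h_dur))
    return np.exp(-h)


def overall_survival(inputs: StrategyInputs, m) -> float:
    """P(alive at start of cycle m): CV survival x non-CV survival."""
    months = np.atleast_1d(np.asarray(m, dtype=float))
    s_cv = _cv_survival_curve(inputs, months)
    if inputs.life_table is not None:
        s_ncv = np.atleast_1d(monthly_noncv_survival(
            inputs.life_table, inputs.age0, inputs.female_fraction,
            months.astype(int)))
    else:
        s_ncv = np.ones_like(s_cv)
    out = s_cv * s_ncv
    return float(out[0]) if np.ndim(m) == 0 else out


def _occupancy_matrix(inputs: StrategyInputs, months: np.ndarray) -> np.ndarray:
    if isinstance(inputs.nyha, NYHAModel):
        return np.vstack([
            predict_nyha(inputs.nyha, inputs.arm, float(t), mode=inputs.nyha_mode)
            for t in months
        ])
    mix = np.asarray(inputs.nyha, dtype=float)
    mix = mix / mix.sum()
    return np.tile(mix, (len(months), 1))


def build_trace(inputs: StrategyInputs) -> pd.DataFrame:
    """Cycle-by-cycle cohort trace with discounted accrual increments."""
    H = int(inputs.horizon_months)
    m = np.arange(H, dtype=float)
    s_now = overall_survival(inputs, m)
    s_next = overall_survival(inputs, m + 1.0)
    membership = 0.5 * (s_now + s_next) if inputs.half_cycle else s_now

    df_m = discount_factor(inputs.discount_annual, m)
    treated = inputs.arm == "ivabradine"
    dur = inputs.treatment_duration_months
    on_treatment = np.ones(H, bool) if dur is None else (m < dur)

    # admission rate per alive patient-month
    rr = np.ones(H)
    if treated:
        if inputs.discontinuation == "persist":
            rr[:] = inputs.rr_hosp
        else:
            rr[on_treatment] = inputs.rr_hosp
    adm_rate = inputs.hosp_rate_soc * rr

    occ = _occupancy_matrix(inputs, m)
    u = np.asarray(inputs.utilities, dtype=float)
    d = np.asarray(inputs.admission_disutilities, dtype=float)
    u_mean = occ @ u
    if inputs.utility_age_decrement_per_year:
        u_mean = u_mean * (1.0 - inputs.utility_age_decrement_per_year * m / 12.0)
    d_mean = occ @ d

    ly_inc = membership * df_m / 12.0
    qaly_inc = membership * (u_mean - adm_rate * d_mean) * df_m / 12.0

    c = inputs.costs
    drug_monthly = np.full(H, c.drug_monthly_soc)
    if treated:
        drug_monthly = drug_monthly + np.where(on_treatment, c.drug_monthly_iva, 0.0)
    per_episode = sum(c.cause_mix[cause] * episode_cost(cause, c)
                      for cause in ADMISSION_CAUSES)
    cost_drug = membership * drug_monthly * df_m
    cost_mgmt = membership * c.mgmt_monthly * df_m
    cost_hosp = membership * adm_rate * per_episode * df_m
    cost_oneoff = np.zeros(H)
    if treated:
        cost_oneoff[0] = c.ecg_oneoff * s_now[0]

    trace = pd.DataFrame({
        "cycle": m.astype(int),
        "alive": s_now,
        "membership": membership,
        "adm_rate": adm_rate,
        "expected_admissions": membership * adm_rate,
        "ly_inc": ly_inc,
        "qaly_inc": qaly_inc,
        "cost_drug": cost_drug,
        "cost_mgmt": cost_mgmt,
        "cost_hosp": cost_hosp,
        "cost_oneoff": cost_oneoff,
    })
    for k in range(4):
        trace[f"occ{k + 1}"] = occ[:, k]
    return trace


def accrue(trace: pd.DataFrame, arm: str) -> StrategyResult:
    """Sum discounted increments into a strategy result."""
    return StrategyResult(
        arm=arm,
        ly=float(trace["ly_inc"].sum()),
        qaly=float(trace["qaly_inc"].sum()),
        cost_drug=float(trace["cost_drug"].sum()),
        cost_hosp=float(trace["cost_hosp"].sum()),
        cost_mgmt=float(trace["cost_mgmt"].sum()),
        cost_oneoff=float(trace["cost_oneoff"].sum()),
    )


def run_strategy(inputs: StrategyInputs) -> StrategyResult:
    return accrue(build_trace(inputs), inputs.arm)


def run_both_arms(inputs: StrategyInputs) -> tuple:
    """Evaluate SoC and ivabradine arms from shared settings."""
    soc = run_strategy(replace(inputs, arm="soc"))
    iva = run_strategy(replace(inputs, arm="ivabradine"))
    return soc, iva


def microsimulate(inputs: StrategyInputs, n_patients: int, seed: int) -> dict:
    """Individual-level Monte Carlo evaluation of the same strategy.

    Used as an independent correctness oracle for the cohort trace: samples a
    death cycle from the overall survival curve, then per alive person-month
    samples a NYHA class from the occupancy distribution and an admission
    count from the Poisson rate, accruing the same discounted quantities.
    Returns means and Monte-Carlo standard errors for LY, QALY and lifetime
    expected admissions.
    """
    rng = np.random.default_rng(seed)
    H = int(inputs.horizon_months)
    grid = np.arange(H + 1, dtype=float)
    s = overall_survival(inputs, grid)
    # P(death during cycle m) = S(m) - S(m+1); surviving the horizon keeps all cycles
    pdeath = np.diff(-s)
    probs = np.concatenate([pdeath, [s[-1]]])
    probs = np.maximum(probs, 0.0)
    probs = probs / probs.sum()
    death_cycle = rng.choice(np.arange(H + 1), size=n_patients, p=probs)
    # person alive at cycle starts 0..death_cycle (inclusive), capped at H-1
    n_alive_cycles = np.minimum(death_cycle + 1, H)

    df_m = discount_factor(inputs.discount_annual, np.arange(H, dtype=float))
    occ = _occupancy_matrix(inputs, np.arange(H, dtype=float))
    u = np.asarray(inputs.utilities, dtype=float)
    d = np.asarray(inputs.admission_disutilities, dtype=float)

    treated = inputs.arm == "ivabradine"
    dur = inputs.treatment_duration_months
    rr = np.ones(H)
    if treated:
        if inputs.discontinuation == "persist":
            rr[:] = inputs.rr_hosp
        else:
            rr[np.arange(H) < (dur if dur is not None else H)] = inputs.rr_hosp
    adm_rate = inputs.hosp_rate_soc * rr

    ly = np.zeros(n_patients)
    qaly = np.zeros(n_patients)
    adm = np.zeros(n_patients)
    order = np.argsort(n_alive_cycles)
    sorted_alive = n_alive_cycles[order]
    for mth in range(H):
        first = np.searchsorted(sorted_alive, mth + 1)
        idx = order[first:]
        if len(idx) == 0:
            break
        k = rng.choice(4, size=len(idx), p=occ[mth])
        n_adm = rng.poisson(adm_rate[mth], size=len(idx))
        ly[idx] += df_m[mth] / 12.0
        um = u[k]
        if inputs.utility_age_decrement_per_year:
            um = um * (1.0 - inputs.utility_age_decrement_per_year * mth / 12.0)
        qaly[idx] += (um - n_adm * d[k]) * df_m[mth] / 12.0
        adm[idx] += n_adm
    out = {}
    for name, arr in (("ly", ly), ("qaly", qaly), ("admissions", adm)):
        out[name] = float(arr.mean())
        out[f"{name}_se"] = float(arr.std(ddof=1) / np.sqrt(n_patients))
    return out
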