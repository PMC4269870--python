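"""Run configuration: a validated YAML schema tying the pipeline together.

Unknown keys are rejected (no silent typos) and all violations are reported
at once by pydantic.  ``RunConfig.to_strategy_inputs()`` materializes the
engine inputs; the life table defaults to the bundled synthetic fixture.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .costing import CostSchedule
from .life_tables import load_bundled_life_table, read_life_table
from .markov_engine import CVBaseline, StrategyInputs

__all__ = ["RunConfig", "load_config", "dump_config", "default_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class EngineConfig(_Strict):
    horizon_months: int = Field(480, ge=1)
    discount_annual: float = Field(0.035, ge=0.0)
    half_cycle: bool = False
    treatment_duration_months: float | None = None
    discontinuation: str = "persist"
    trial_months: float = 29.0
    age0: float = 60.0
    female_fraction: float = Field(0.25, ge=0.0, le=1.0)
    gompertz_rate: float = Field(0.004, gt=0.0)
    gompertz_shape: float = 0.01
    utility_age_decrement_per_year: float = 0.0


class EffectsConfig(_Strict):
    hr_cv: float = Field(0.90, gt=0.0)
    hr_cv_ci: tuple[float, float] = (0.80, 1.03)
    rr_hosp: float = Field(0.83, gt=0.0)
    rr_hosp_ci: tuple[float, float] = (0.78, 0.93)
    hf_only_hr: float = 0.74
    hf_death_share: float = Field(0.55, ge=0.0, le=1.0)


class CostsConfig(_Strict):
    drug_monthly_iva: float = 40.52
    drug_monthly_soc: float = 35.26
    mgmt_monthly: float = 26.05
    ecg_oneoff: float = 3.44
    per_diem_icu: float = 200.0
    per_diem_cardiac: float = 110.0
    los_hf: float = 7.0
    los_other_cv: float = 4.0
    los_allcause: float = 5.0
    hf_icu_fraction: float = 0.30
    hf_icu_days: float = 3.0
    hf_ward_days_after_icu: float = 4.0
    cause_mix: dict[str, float] = {"hf": 0.45, "other_cv": 0.30, "non_cv": 0.25}

    def to_schedule(self) -> CostSchedule:
        return CostSchedule(**self.model_dump())


class UtilitiesConfig(_Strict):
    by_class: tuple[float, float, float, float] = (0.82, 0.74, 0.64, 0.46)
    admission_decrements: tuple[float, float, float, float] = (0.04, 0.07, 0.10, 0.29)


class CalibrationConfig(_Strict):
    soc_ly: float = 5.61
    soc_qaly: float = 3.99
    soc_hosp_cost: float = 1781.0
    soc_total_cost: float = 5873.0
    hosp_rate_soc_start: float = 0.04
    nyha_mix: tuple[float, float, float, float] = (0.02, 0.50, 0.45, 0.03)
    n_starts: int = 6


class PSAConfig(_Strict):
    n_sims: int = 5000
    seed: int = 2013
    threshold_grid_max: float = 100_000.0
    threshold_grid_step: float = 2_000.0


class SyntheticConfig(_Strict):
    n_patients: int = 20_000
    mean_age: float = 60.0
    sd_age: float = 10.0
    female_fraction: float = 0.25
    arm_allocation: float = 0.5
    followup_months: float = 29.0
    seed: int = 1


class RunConfig(_Strict):
    threshold: float = 36_000.0
    life_table_path: str | None = None
    out_dir: str = "results"
    engine: EngineConfig = EngineConfig()
    effects: EffectsConfig = EffectsConfig()
    costs: CostsConfig = CostsConfig()
    utilities: UtilitiesConfig = UtilitiesConfig()
    calibration: CalibrationConfig = CalibrationConfig()
    psa: PSAConfig = PSAConfig()
    synthetic: SyntheticConfig = SyntheticConfig()

    def life_table(self):
        if self.life_table_path is None:
            return load_bundled_life_table()
        return read_life_table(self.life_table_path)

    def to_strategy_inputs(self) -> StrategyInputs:
        e = self.engine
        return StrategyInputs(
            arm="soc",
            cv_baseline=CVBaseline(distribution="gompertz",
                                   rate=e.gompertz_rate, shape=e.gompertz_shape),
            hr_cv=self.effects.hr_cv,
            life_table=self.life_table(),
            age0=e.age0,
            female_fraction=e.female_fraction,
            hosp_rate_soc=self.calibration.hosp_rate_soc_start,
            rr_hosp=self.effects.rr_hosp,
            nyha=self.calibration.nyha_mix,
            utilities=self.utilities.by_class,
            admission_disutilities=self.utilities.admission_decrements,
            costs=self.costs.to_schedule(),
            horizon_months=e.horizon_months,
            discount_annual=e.discount_annual,
            treatment_duration_months=e.treatment_duration_months,
            discontinuation=e.discontinuation,
            trial_months=e.trial_months,
            half_cycle=e.half_cycle,
            utility_age_decrement_per_year=e.utility_age_decrement_per_year,
        )


class ConfigError(ValueError):
    pass


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration (defaults applied)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if raw.get("life_table_path") and not Path(raw["life_table_path"]).exists():
        raise ConfigError(f"life_table_path does not exist: {raw['life_table_path']}")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        msgs = "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors())
        raise ConfigError(f"invalid configuration {path}: {msgs}") from exc


def dump_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=False)


def default_config() -> RunConfig:
    return RunConfig()
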