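"""Unit-cost construction for the payer-perspective model (2013 euros).

Translates tariff and price inputs — per-diem ward tariffs, length of stay by
admission cause, the ivabradine dose mix, manufacturer rebates, and the
standard-care drug basket — into the per-cycle and per-episode unit costs the
cohort engine consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "CostSchedule",
    "RebateScheme",
    "net_price",
    "ivabradine_monthly_cost",
    "episode_cost",
    "mixture_episode_cost",
    "soc_monthly_cost",
]

ADMISSION_CAUSES = ("hf", "other_cv", "non_cv")


@dataclass
class RebateScheme:
    """Manufacturer rebates applied to the ex-factory price.

    positive_list_rebate: flat rebate for inclusion on the reimbursement list.
    volume_rebate: sales-volume rebate (statutory range 0-8%; 5% assumed).
    """

    positive_list_rebate: float = 0.09
    volume_rebate: float = 0.05

    def __post_init__(self) -> None:
        for r in (self.positive_list_rebate, self.volume_rebate):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rebate {r} outside [0, 1]")


@dataclass
class CostSchedule:
    """Base-case unit costs: monthly drug/management costs, per-diems, LoS."""

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
    # share of all-cause admissions by cause; chosen so the mixture LoS is
    # close to the 5-day all-cause average
    cause_mix: dict = field(
        default_factory=lambda: {"hf": 0.45, "other_cv": 0.30, "non_cv": 0.25}
    )

    def __post_init__(self) -> None:
        numeric = [
            self.drug_monthly_iva, self.drug_monthly_soc, self.mgmt_monthly,
            self.ecg_oneoff, self.per_diem_icu, self.per_diem_cardiac,
            self.los_hf, self.los_other_cv, self.los_allcause,
            self.hf_icu_fraction, self.hf_icu_days, self.hf_ward_days_after_icu,
        ]
        if any(v < 0 for v in numeric):
            raise ValueError("cost-schedule entries must be non-negative")
        if abs(self.hf_icu_days + self.hf_ward_days_after_icu - self.los_hf) > 1e-9:
            raise ValueError("HF ICU days + post-ICU ward days must equal the HF LoS")
        if set(self.cause_mix) != set(ADMISSION_CAUSES):
            raise ValueError(f"cause_mix must have keys {ADMISSION_CAUSES}")
        if abs(sum(self.cause_mix.values()) - 1.0) > 1e-9:
            raise ValueError("cause_mix must sum to 1")


def net_price(ex_factory: float, scheme: RebateScheme, compound: bool = False) -> float:
    """Price net of the two manufacturer rebates.

    Both rebates are levied on the ex-factory base, so the base rule is
    additive: ``p * (1 - r1 - r2)``.  ``compound=True`` applies them
    sequentially instead (``p * (1-r1) * (1-r2)``).
    """
    if ex_factory < 0:
        raise ValueError("ex-factory price must be non-negative")
    r1, r2 = scheme.positive_list_rebate, scheme.volume_rebate
    if r1 + r2 > 1.0 and not compound:
        raise ValueError("rebates sum to more than 100%")
    if compound:
        return ex_factory * (1.0 - r1) * (1.0 - r2)
    return ex_factory * (1.0 - r1 - r2)


def ivabradine_monthly_cost(
    dose_mix: dict,
    monthly_price_5mg: float,
    monthly_price_7p5mg: float,
) -> float:
    """Dose-mix-weighted monthly ivabradine cost.

    ``dose_mix`` maps dose labels {'2.5', '5', '7.5'} (mg b.i.d.) to usage
    proportions.  The 2.5 mg dose is costed at half the 5 mg price (scored
    tablets halved in practice).
    """
    if set(dose_mix) != {"2.5", "5", "7.5"}:
        raise ValueError("dose_mix must have keys '2.5', '5', '7.5'")
    if abs(sum(dose_mix.values()) - 1.0) > 1e-9:
        raise ValueError("dose mix proportions must sum to 1")
    return (
        dose_mix["2.5"] * monthly_price_5mg / 2.0
        + dose_mix["5"] * monthly_price_5mg
        + dose_mix["7.5"] * monthly_price_7p5mg
    )


def episode_cost(cause: str, schedule: CostSchedule) -> float:
    """Expected cost of one hospital admission of the given cause.

    HF admissions: a fraction pass through ICU (ICU days then cardiac-ward
    days), the rest spend the whole HF LoS in a cardiac ward.  Other-CV and
    non-CV admissions are costed at cardiac-ward per-diem for their LoS (no
    separate non-CV per-diem is available; the all-cause LoS is used).
    """
    s = schedule
    if cause == "hf":
        icu_path = s.hf_icu_days * s.per_diem_icu + s.hf_ward_days_after_icu * s.per_diem_cardiac
        ward_path = s.los_hf * s.per_diem_cardiac
        return s.hf_icu_fraction * icu_path + (1.0 - s.hf_icu_fraction) * ward_path
    if cause == "other_cv":
        return s.los_other_cv * s.per_diem_cardiac
    if cause == "non_cv":
        return s.los_allcause * s.per_diem_cardiac
    raise ValueError(f"unknown admission cause {cause!r}; expected one of {ADMISSION_CAUSES}")


def mixture_episode_cost(schedule: CostSchedule) -> float:
    """Cause-mix-weighted expected cost per all-cause admission."""
    return sum(schedule.cause_mix[c] * episode_cost(c, schedule) for c in ADMISSION_CAUSES)


def soc_monthly_cost(basket: list) -> float:
    """Monthly standard-care drug cost from a therapy basket.

    ``basket`` rows are (drug, proportion_using, daily_dose_mg, price_per_mg).
    Monthly cost sums proportion x daily cost x (365.25/12) over rows.
    """
    days_per_month = 365.25 / 12.0
    total = 0.0
    for drug, prop, daily_mg, price_per_mg in basket:
        if not 0.0 <= prop <= 1.0:
            raise ValueError(f"usage proportion for {drug} outside [0, 1]")
        if daily_mg < 0 or price_per_mg < 0:
            raise ValueError(f"negative dose or price for {drug}")
        total += prop * daily_mg * price_per_mg * days_per_month
    return total
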