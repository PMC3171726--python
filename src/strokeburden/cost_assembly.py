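"""Micro-costing rules for per-person annual stroke costs.

Implements the assembly of societal per-person costs from utilisation and
wage inputs: the uninsured share of medical costs, informal caregiver time,
transport to healthcare institutions, out-of-pocket spending beyond the first
year, and the two productivity valuations (human capital and friction cost).
These operations validate or regenerate cost schedules of the shape used by
the Markov engine; the bundled cost table itself is taken as authoritative
input.

Money is in thousand KRW (2008).  The uninsured proportions (29.5% of total
medical cost for admissions, 15.2% for outpatient care) are proportions of
the TOTAL medical cost, so the uninsured amount implied by an insured amount
is insured * f / (1 - f) per setting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .parameters import (
    CostBandParams,
    Gender,
    GenderAgeBandKey,
    GeneralPopulationLifeTable,
    ModelConfig,
    band_of,
)

__all__ = [
    "UNINSURED_FRACTION_INPATIENT",
    "UNINSURED_FRACTION_OUTPATIENT",
    "UtilizationProfile",
    "WageInputs",
    "uninsured_cost",
    "caregiver_cost",
    "transport_cost",
    "second_year_out_of_pocket",
    "human_capital_premature_cost",
    "absenteeism_cost",
    "friction_premature_cost",
    "training_cost_2008",
    "assemble_annual_cost",
    "friction_cost_table",
]

#: Uninsured share of total medical cost, by care setting.
UNINSURED_FRACTION_INPATIENT = 0.295
UNINSURED_FRACTION_OUTPATIENT = 0.152

#: An outpatient visit occupies one third of a caregiver's day.
OUTPATIENT_DAY_FRACTION = 1.0 / 3.0

#: Caregiver accompaniment (extra transport + caregiver transport time)
#: applies to patients older than this age.
CAREGIVER_ACCOMPANIMENT_AGE = 65


@dataclass(frozen=True)
class UtilizationProfile:
    """Annual healthcare utilisation for an average patient."""

    inpatient_days: float = 0.0
    admissions: float = 0.0
    outpatient_visits: float = 0.0
    insured_cost_inpatient: float = 0.0
    insured_cost_outpatient: float = 0.0
    out_of_pocket_outside_first_year: float = 0.0

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class WageInputs:
    """Wage and unit-price inputs for caregiver, transport and productivity costs.

    Defaults are the published 2008-KRW unit values: the average daily wage of
    women aged 20-50 (56.809 thousand KRW) valuing informal caregiver time,
    and average round-trip transport of 0.891 (outpatient) and 2.896
    (admission) thousand KRW.
    """

    daily_wage_caregiver: float = 56.809
    transport_outpatient: float = 0.891
    transport_admission: float = 2.896
    annual_wage_by_gender_age: Mapping[GenderAgeBandKey, float] = field(default_factory=dict)
    second_year_oop_ratio: float = 0.25
    hourly_wage: float | None = None

    def __post_init__(self) -> None:
        if not 0.13 <= self.second_year_oop_ratio <= 0.38:
            raise ValueError("second_year_oop_ratio must lie in [0.13, 0.38]")
        if min(self.daily_wage_caregiver, self.transport_outpatient, self.transport_admission) < 0:
            raise ValueError("wages and transport prices must be nonnegative")

    def annual_wage(self, gender: Gender | str, age: float) -> float:
        key = GenderAgeBandKey(Gender(gender), band_of(age))
        try:
            return self.annual_wage_by_gender_age[key]
        except KeyError as exc:
            raise KeyError(f"no annual wage configured for {key}") from exc

    @property
    def hourly(self) -> float:
        """Hourly wage; defaults to the daily wage over an 8-hour day."""
        return self.hourly_wage if self.hourly_wage is not None else self.daily_wage_caregiver / 8.0


def uninsured_cost(insured_inpatient: float, insured_outpatient: float) -> float:
    """Uninsured medical cost implied by insured amounts, per care setting."""
    if insured_inpatient < 0 or insured_outpatient < 0:
        raise ValueError("insured costs must be nonnegative")
    f_in, f_out = UNINSURED_FRACTION_INPATIENT, UNINSURED_FRACTION_OUTPATIENT
    return insured_inpatient * f_in / (1.0 - f_in) + insured_outpatient * f_out / (1.0 - f_out)


def caregiver_cost(profile: UtilizationProfile, wages: WageInputs, patient_age: float) -> float:
    """Informal caregiver cost: hospital days plus a third-day per visit.

    For patients older than 65 the caregiver travels too, adding one extra
    round trip per admission and per outpatient visit.
    """
    cost = profile.inpatient_days * wages.daily_wage_caregiver
    cost += profile.outpatient_visits * wages.daily_wage_caregiver * OUTPATIENT_DAY_FRACTION
    if patient_age > CAREGIVER_ACCOMPANIMENT_AGE:
        cost += (
            profile.admissions * wages.transport_admission
            + profile.outpatient_visits * wages.transport_outpatient
        )
    return cost


def transport_cost(profile: UtilizationProfile, wages: WageInputs) -> float:
    """Patient round-trip transport over all visits and admissions."""
    return (
        profile.outpatient_visits * wages.transport_outpatient
        + profile.admissions * wages.transport_admission
    )


def second_year_out_of_pocket(first_year_oop: float, ratio: float) -> float:
    """Out-of-pocket spending in year two and beyond, scaled from year one."""
    if not 0.13 <= ratio <= 0.38:
        raise ValueError("second-year ratio must lie within the published range [0.13, 0.38]")
    if first_year_oop < 0:
        raise ValueError("first-year out-of-pocket cost must be nonnegative")
    return first_year_oop * ratio


def human_capital_premature_cost(
    gender: Gender | str,
    age_at_death: float,
    life_table: GeneralPopulationLifeTable,
    wages: WageInputs,
    retirement_age: int = 65,
) -> float:
    """Forgone earnings over the potential years of life lost (PYLL).

    PYLL is the general-population remaining life expectancy at the age of
    death; earnings are summed year by year from the age of death up to the
    retirement age (or the end of the PYLL span if sooner), a fractional
    final year being credited pro rata.  Zero at or beyond retirement.
    """
    if age_at_death >= retirement_age:
        return 0.0
    pyll = life_table.at_band(gender, age_at_death)
    horizon = min(float(retirement_age), age_at_death + pyll)
    cost = 0.0
    age = age_at_death
    while age < horizon:
        credit = min(1.0, horizon - age)
        cost += credit * wages.annual_wage(gender, age)
        age += 1.0
    return cost


def absenteeism_cost(
    inpatient_days: float,
    outpatient_hours: float,
    wages: WageInputs,
    age: float,
    retirement_age: int = 65,
) -> float:
    """Morbidity productivity loss: wages over days hospitalised and visit hours."""
    if age >= retirement_age:
        return 0.0
    return inpatient_days * wages.daily_wage_caregiver + outpatient_hours * wages.hourly


def training_cost_2008(config: ModelConfig) -> float:
    """Employer training cost per replacement hire, in thousand KRW (2008).

    The 2000 USD estimate is inflated by the consumer price index and
    converted at the configured exchange rate.
    """
    usd_2008 = config.training_cost_usd_2000 * config.cpi_2008_base_2000 / 100.0
    return usd_2008 * config.exchange_rate_krw_per_usd / 1000.0


def friction_premature_cost(
    gender: Gender | str,
    age_at_death: float,
    wages: WageInputs,
    config: ModelConfig,
) -> float:
    """Friction-cost valuation of a premature death.

    The employer loses output for the friction period (half a year of the
    decedent's wage by default) and pays to train a replacement; zero at or
    beyond retirement.
    """
    if age_at_death >= config.retirement_age:
        return 0.0
    wage = wages.annual_wage(gender, age_at_death)
    return config.friction_period_years * wage + training_cost_2008(config)


def assemble_annual_cost(
    profile: UtilizationProfile,
    wages: WageInputs,
    patient_age: float,
) -> dict[str, float]:
    """Per-person annual cost breakdown (thousand KRW) from utilisation inputs."""
    insured = profile.insured_cost_inpatient + profile.insured_cost_outpatient
    uninsured = uninsured_cost(profile.insured_cost_inpatient, profile.insured_cost_outpatient)
    caregiver = caregiver_cost(profile, wages, patient_age)
    transport = transport_cost(profile, wages)
    oop_first = profile.out_of_pocket_outside_first_year
    breakdown = {
        "insured_medical": insured,
        "uninsured_medical": uninsured,
        "informal_caregiver": caregiver,
        "transport": transport,
        "out_of_pocket_first_year": oop_first,
        "out_of_pocket_subsequent_year": second_year_out_of_pocket(
            oop_first, wages.second_year_oop_ratio
        ),
    }
    breakdown["total_first_year"] = insured + uninsured + caregiver + transport + oop_first
    return breakdown


def friction_cost_table(
    cost_table: Mapping[GenderAgeBandKey, CostBandParams],
    wages: WageInputs,
    config: ModelConfig,
) -> dict[GenderAgeBandKey, CostBandParams]:
    """Cost table with premature-death costs revalued by the friction method."""
    out: dict[GenderAgeBandKey, CostBandParams] = {}
    for key, costs in cost_table.items():
        premature = (
            friction_premature_cost(key.gender, key.band, wages, config)
            if key.band < config.retirement_age
            else 0.0
        )
        out[key] = CostBandParams(
            cost_first_year=costs.cost_first_year,
            cost_subsequent_year=costs.cost_subsequent_year,
            cost_fatal=costs.cost_fatal,
            cost_premature_death=premature,
        )
    return out
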