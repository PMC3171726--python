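"""Derivation of per-cycle Markov transition probabilities.

The national report tabulates, per gender and 10-year band, the attack rate
of acute stroke in the whole population (R_t), the first-ever incidence among
people without prior stroke (R_n) and the prevalence of prior stroke (p).
Because the attack rate is a prevalence-weighted mixture of the two
sub-population rates,

    R_t = p * R_s + (1 - p) * R_n,

the recurrent-stroke rate among people with prior stroke is recovered as
R_s = (R_t - (1 - p) * R_n) / p.  The recurrence is split into non-fatal and
fatal components with the 12-month survival proportion P_nfs, non-stroke
mortality after stroke is the general-population non-stroke rate scaled by a
standardised mortality ratio (D_s = D_t * SMR), and each per-person-year rate
r is converted to a per-cycle probability with p = 1 - exp(-r * t).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .parameters import (
    BANDS,
    EpiBandParams,
    Gender,
    GenderAgeBandKey,
    ModelConfig,
    band_of,
)

__all__ = [
    "DerivedRisks",
    "TransitionSet",
    "recurrent_risk",
    "split_recurrence",
    "nonstroke_mortality_stroke_pop",
    "rate_to_probability",
    "derive_risks",
    "build_transition_set",
    "transition_table",
]

PER_100K = 100_000.0


@dataclass(frozen=True)
class DerivedRisks:
    """Rates per 100,000 person-years derived for one gender x band."""

    recurrent_risk: float
    recurrent_nonfatal_risk: float
    recurrent_fatal_risk: float
    nonstroke_mortality_stroke_pop: float


@dataclass(frozen=True)
class TransitionSet:
    """The four per-cycle exits from the 'alive post stroke' state."""

    p_nonfatal_recurrence: float
    p_fatal_recurrence: float
    p_nonstroke_death: float
    p_stay_no_recurrence: float

    def __post_init__(self) -> None:
        probs = (
            self.p_nonfatal_recurrence,
            self.p_fatal_recurrence,
            self.p_nonstroke_death,
            self.p_stay_no_recurrence,
        )
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError(f"transition probabilities outside [0, 1]: {probs}")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError(f"transition probabilities must sum to 1, got {sum(probs)!r}")

    @property
    def p_death(self) -> float:
        """Total probability of leaving the living state this cycle."""
        return self.p_fatal_recurrence + self.p_nonstroke_death


def recurrent_risk(params: EpiBandParams) -> float:
    """Recurrent-stroke rate R_s per 100,000 among people with prior stroke.

    Solves the attack-rate mixture R_t = p*R_s + (1-p)*R_n for R_s.
    """
    p = params.prevalence
    if p <= 0:
        raise ValueError("recurrent risk is undefined at zero prevalence")
    numerator = params.attack_rate - (1.0 - p) * params.risk_new_onset
    if numerator < 0:
        raise ValueError(
            "inconsistent inputs: attack rate below the non-prior-stroke "
            f"contribution ({params.attack_rate} < {(1.0 - p) * params.risk_new_onset:.4f})"
        )
    return numerator / p


def split_recurrence(recurrent: float, first_year_survival: float) -> tuple[float, float]:
    """Split R_s into (non-fatal, fatal) components using P_nfs."""
    if not 0.0 <= first_year_survival <= 1.0:
        raise ValueError("first_year_survival must be a fraction in [0, 1]")
    nonfatal = recurrent * first_year_survival
    return nonfatal, recurrent - nonfatal


def nonstroke_mortality_stroke_pop(d_t: float, smr: float) -> float:
    """Non-stroke mortality among people with prior stroke: D_s = D_t * SMR."""
    if d_t < 0 or smr < 0:
        raise ValueError("rates and SMRs must be nonnegative")
    return d_t * smr


def rate_to_probability(rate: float, cycle_length: float = 1.0) -> float:
    """Convert a per-person-year rate to a per-cycle probability.

    Uses p = 1 - exp(-r*t); the result is bounded above by r*t.
    """
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    if cycle_length <= 0:
        raise ValueError("cycle_length must be positive")
    return -math.expm1(-rate * cycle_length)


def derive_risks(params: EpiBandParams, smr: float) -> DerivedRisks:
    r_s = recurrent_risk(params)
    r_nfs, r_fs = split_recurrence(r_s, params.first_year_survival)
    d_s = nonstroke_mortality_stroke_pop(params.nonstroke_mortality_general, smr)
    return DerivedRisks(r_s, r_nfs, r_fs, d_s)


def build_transition_set(
    gender: Gender | str,
    attained_age: float,
    epi_table: dict[GenderAgeBandKey, EpiBandParams],
    config: ModelConfig,
) -> TransitionSet:
    """Per-cycle transition probabilities at an attained age.

    The band is a step function of attained age (boundaries 55/65/75/85, the
    last open-ended); rates are divided by 100,000 before conversion.  The
    stay-alive probability is the complement of the three exits, floored at
    zero with proportional renormalisation if they were ever to exceed one.
    """
    gender = Gender(gender)
    if not BANDS[0] <= attained_age <= config.terminal_age:
        raise ValueError(
            f"attained_age {attained_age} outside [{BANDS[0]}, {config.terminal_age}]"
        )
    params = epi_table[GenderAgeBandKey(gender, band_of(attained_age))]
    risks = derive_risks(params, config.smr.for_gender(gender))
    t = config.cycle_length_years
    p_nfs = rate_to_probability(risks.recurrent_nonfatal_risk / PER_100K, t)
    p_fs = rate_to_probability(risks.recurrent_fatal_risk / PER_100K, t)
    p_d = rate_to_probability(risks.nonstroke_mortality_stroke_pop / PER_100K, t)
    exits = p_nfs + p_fs + p_d
    if exits > 1.0:
        p_nfs, p_fs, p_d = (p / exits for p in (p_nfs, p_fs, p_d))
        exits = 1.0
    return TransitionSet(
        p_nonfatal_recurrence=p_nfs,
        p_fatal_recurrence=p_fs,
        p_nonstroke_death=p_d,
        p_stay_no_recurrence=1.0 - exits,
    )


def transition_table(
    epi_table: dict[GenderAgeBandKey, EpiBandParams], config: ModelConfig
) -> pd.DataFrame:
    """One TransitionSet per gender x band, as a tidy DataFrame."""
    rows = []
    for gender in Gender:
        for band in BANDS:
            ts = build_transition_set(gender, band, epi_table, config)
            risks = derive_risks(
                epi_table[GenderAgeBandKey(gender, band)], config.smr.for_gender(gender)
            )
            rows.append(
                {
                    "gender": gender.value,
                    "band": band,
                    "recurrent_risk_per_100k": risks.recurrent_risk,
                    "p_nonfatal_recurrence": ts.p_nonfatal_recurrence,
                    "p_fatal_recurrence": ts.p_fatal_recurrence,
                    "p_nonstroke_death": ts.p_nonstroke_death,
                    "p_stay_no_recurrence": ts.p_stay_no_recurrence,
                }
            )
    return pd.DataFrame(rows)
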