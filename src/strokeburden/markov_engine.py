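"""Three-state yearly-cycle Markov cohort engine.

Every cohort starts in 'post primary stroke event' at its onset age.  Cycle 1
applies the 12-month case fatality (1 - first_year_survival) directly as a
probability; survivors enter 'alive post stroke'.  Each later cycle applies
the attained-age transition set (non-fatal recurrence, fatal recurrence,
non-stroke death, stay), with the band updated as the cohort ages.  The
cohort is closed at the terminal age (99): anyone alive after the final cycle
is counted as dying in the following year with no further cost.

Life-year convention: decedents contribute zero life-years in their cycle of
death, so life expectancy is the sum over cycles of the end-of-cycle alive
fraction.  No half-cycle correction is applied.

Costs (thousand KRW, undiscounted): cycle 1 charges the first-year cost to
survivors and the fatal cost (plus the premature-death productivity cost of
the onset band) to decedents.  Later cycles charge the subsequent-year cost
to those who stay recurrence-free, the first-year cost to non-fatal
recurrences, and the fatal cost plus the attained-age band's premature-death
cost to fatal recurrences; non-stroke deaths accrue no stroke cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import (
    BANDS,
    CostBandParams,
    EpiBandParams,
    Gender,
    GenderAgeBandKey,
    GeneralPopulationLifeTable,
    ModelConfig,
    band_of,
)
from .transitions import build_transition_set

__all__ = [
    "CohortTrace",
    "CostBreakdown",
    "LifetimeResult",
    "run_cohort",
    "life_expectancy",
    "years_of_life_lost",
    "expected_lifetime_cost",
    "lifetime_result",
    "all_cohort_results",
]


@dataclass
class CohortTrace:
    """Per-cycle state occupancy and event fractions for one cohort.

    Arrays are indexed by cycle (cycle 1 first); ``ages[k]`` is the attained
    age during that cycle.  Event fractions are of the whole cohort.
    """

    gender: Gender
    onset_age: int
    ages: np.ndarray
    entering_alive: np.ndarray
    alive_end: np.ndarray
    first_year_nonfatal: float
    first_year_fatal: float
    nonfatal_recurrence: np.ndarray
    fatal_recurrence: np.ndarray
    nonstroke_death: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.alive_end) > 1e-15):
            raise ValueError("alive fraction must be non-increasing")
        events = self.nonfatal_recurrence + self.fatal_recurrence + self.nonstroke_death
        if np.any(events - self.entering_alive > 1e-12) or np.any(events < -1e-15):
            raise ValueError("event fractions must lie within the entering alive fraction")

    @property
    def dead_end(self) -> np.ndarray:
        return 1.0 - self.alive_end

    @property
    def n_cycles(self) -> int:
        return len(self.ages)


@dataclass(frozen=True)
class CostBreakdown:
    """Expected lifetime cost split into medical/other and premature parts."""

    total: float
    excl_premature: float

    @property
    def premature(self) -> float:
        return self.total - self.excl_premature


@dataclass(frozen=True)
class LifetimeResult:
    gender: Gender
    onset_age: int
    life_expectancy_post_stroke: float
    life_expectancy_general: float
    years_of_life_lost: float
    reduction_pct: float
    lifetime_cost_total: float
    lifetime_cost_excl_premature: float


def run_cohort(
    gender: Gender | str,
    onset_age: int,
    epi_table: dict[GenderAgeBandKey, EpiBandParams],
    config: ModelConfig,
) -> CohortTrace:
    """Propagate one gender/onset-age cohort to the terminal age."""
    gender = Gender(gender)
    if onset_age not in BANDS:
        raise ValueError(f"onset_age must be one of {BANDS}, got {onset_age}")
    onset = epi_table[GenderAgeBandKey(gender, onset_age)]
    n_cycles = config.terminal_age - onset_age + 1
    ages = np.arange(onset_age, config.terminal_age + 1)

    entering = np.zeros(n_cycles)
    alive_end = np.zeros(n_cycles)
    nfs = np.zeros(n_cycles)
    fs = np.zeros(n_cycles)
    nsd = np.zeros(n_cycles)

    entering[0] = 1.0
    fy_fatal = 1.0 - onset.first_year_survival
    fy_nonfatal = onset.first_year_survival
    alive_end[0] = onset.first_year_survival

    alive = alive_end[0]
    for k in range(1, n_cycles):
        entering[k] = alive
        ts = build_transition_set(gender, int(ages[k]), epi_table, config)
        nfs[k] = alive * ts.p_nonfatal_recurrence
        fs[k] = alive * ts.p_fatal_recurrence
        nsd[k] = alive * ts.p_nonstroke_death
        alive = alive * (1.0 - ts.p_death)
        alive_end[k] = alive

    return CohortTrace(
        gender=gender,
        onset_age=onset_age,
        ages=ages,
        entering_alive=entering,
        alive_end=alive_end,
        first_year_nonfatal=fy_nonfatal,
        first_year_fatal=fy_fatal,
        nonfatal_recurrence=nfs,
        fatal_recurrence=fs,
        nonstroke_death=nsd,
    )


def life_expectancy(trace: CohortTrace) -> float:
    """Expected years lived after the event (end-of-cycle occupancy sum)."""
    return float(trace.alive_end.sum())


def years_of_life_lost(le_post_stroke: float, le_general: float) -> tuple[float, float]:
    """Years of life lost and the percent reduction in life expectancy."""
    if le_general <= 0:
        raise ValueError("general-population life expectancy must be positive")
    yll = le_general - le_post_stroke
    return yll, 100.0 * yll / le_general


def expected_lifetime_cost(
    trace: CohortTrace,
    cost_table: dict[GenderAgeBandKey, CostBandParams],
    config: ModelConfig,
) -> CostBreakdown:
    """Accumulate expected per-cycle costs over the cohort trace."""
    onset_costs = cost_table[GenderAgeBandKey(trace.gender, trace.onset_age)]
    medical = (
        trace.first_year_nonfatal * onset_costs.cost_first_year
        + trace.first_year_fatal * onset_costs.cost_fatal
    )
    premature = trace.first_year_fatal * onset_costs.cost_premature_death
    for k in range(1, trace.n_cycles):
        band_costs = cost_table[GenderAgeBandKey(trace.gender, band_of(trace.ages[k]))]
        stay = trace.entering_alive[k] - (
            trace.nonfatal_recurrence[k] + trace.fatal_recurrence[k] + trace.nonstroke_death[k]
        )
        medical += (
            stay * band_costs.cost_subsequent_year
            + trace.nonfatal_recurrence[k] * band_costs.cost_first_year
            + trace.fatal_recurrence[k] * band_costs.cost_fatal
        )
        premature += trace.fatal_recurrence[k] * band_costs.cost_premature_death
    return CostBreakdown(total=medical + premature, excl_premature=medical)


def lifetime_result(
    gender: Gender | str,
    onset_age: int,
    epi_table: dict[GenderAgeBandKey, EpiBandParams],
    cost_table: dict[GenderAgeBandKey, CostBandParams],
    life_table: GeneralPopulationLifeTable,
    config: ModelConfig,
) -> LifetimeResult:
    """Run one cohort and summarise life expectancy, YLL and lifetime cost."""
    gender = Gender(gender)
    trace = run_cohort(gender, onset_age, epi_table, config)
    le = life_expectancy(trace)
    le_gen = life_table.at(gender, onset_age)
    yll, reduction = years_of_life_lost(le, le_gen)
    costs = expected_lifetime_cost(trace, cost_table, config)
    return LifetimeResult(
        gender=gender,
        onset_age=onset_age,
        life_expectancy_post_stroke=le,
        life_expectancy_general=le_gen,
        years_of_life_lost=yll,
        reduction_pct=reduction,
        lifetime_cost_total=costs.total,
        lifetime_cost_excl_premature=costs.excl_premature,
    )


def all_cohort_results(
    epi_table: dict[GenderAgeBandKey, EpiBandParams],
    cost_table: dict[GenderAgeBandKey, CostBandParams],
    life_table: GeneralPopulationLifeTable,
    config: ModelConfig,
) -> list[LifetimeResult]:
    """Lifetime results for all ten gender x onset-age cohorts."""
    return [
        lifetime_result(g, onset, epi_table, cost_table, life_table, config)
        for g in Gender
        for onset in BANDS
    ]
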