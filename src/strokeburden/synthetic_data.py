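"""Synthetic parameter sets, claim records and a microsimulation oracle.

Every stage of the pipeline can be exercised without external data:

* :func:`generate_scenario` draws an internally consistent parameter set
  (epidemiologic rates, cost schedule, wage schedule, life table) from
  plausible ranges.  The attack rate is composed from the prevalence, the
  first-ever rate and a *known* recurrent rate, so the mixture decomposition
  can be tested against ground truth.
* :func:`microsim_oracle` estimates life expectancy and lifetime cost by
  simulating independent individual life histories with the same transition
  sets as the cohort engine but an entirely separate accumulation path, which
  makes it an independent check on the engine's expectation arithmetic.
* :func:`generate_claims`/:func:`ascertain_incident_cases` emulate the
  claims-based incident-case definition: a first stroke claim in the index
  year with a claim-free washout window, labelled fatal when death follows
  within 365 days.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np

from .parameters import (
    BANDS,
    CostBandParams,
    EpiBandParams,
    Gender,
    GenderAgeBandKey,
    GeneralPopulationLifeTable,
    ModelConfig,
)
from .parameters import band_of
from .transitions import build_transition_set

__all__ = [
    "SyntheticScenario",
    "SyntheticClaimRecord",
    "MicrosimResult",
    "generate_scenario",
    "microsim_oracle",
    "generate_claims",
    "ascertain_incident_cases",
    "YEAR_DAYS",
]

#: Fixed year length for the fatal/non-fatal cutoff; calendar subtleties ignored.
YEAR_DAYS = 365

STROKE_CODES = ("I60", "I61", "I62", "I63", "I64")


@dataclass(frozen=True)
class SyntheticScenario:
    """A complete, validated random parameter set plus its ground truth."""

    seed: int
    epi_table: dict[GenderAgeBandKey, EpiBandParams]
    cost_table: dict[GenderAgeBandKey, CostBandParams]
    wage_table: dict[GenderAgeBandKey, float]
    life_table: GeneralPopulationLifeTable
    config: ModelConfig
    true_recurrent_risk: dict[GenderAgeBandKey, float] = field(default_factory=dict)


def generate_scenario(seed: int) -> SyntheticScenario:
    """Draw a reproducible scenario; every table passes the input validators."""
    rng = np.random.default_rng(seed)
    epi: dict[GenderAgeBandKey, EpiBandParams] = {}
    cost: dict[GenderAgeBandKey, CostBandParams] = {}
    wages: dict[GenderAgeBandKey, float] = {}
    life: dict[tuple[Gender, int], float] = {}
    true_rs: dict[GenderAgeBandKey, float] = {}

    for gender in Gender:
        # Age-monotone scaffolding per gender.
        prevalence = np.sort(rng.uniform(0.001, 0.10, len(BANDS)))
        new_onset = np.sort(rng.uniform(50, 3000, len(BANDS)))
        recurrent = np.sort(rng.uniform(2000, 20000, len(BANDS)))
        survival = np.sort(rng.uniform(0.20, 0.95, len(BANDS)))[::-1]
        mortality = np.sort(rng.uniform(100, 20000, len(BANDS)))
        # oldest band keeps a short remaining life expectancy; each younger
        # band adds several years, keeping the schedule age-realistic
        le = (rng.uniform(2.0, 8.0) + np.concatenate(
            ([0.0], np.cumsum(rng.uniform(3.0, 10.0, len(BANDS) - 1)))
        ))[::-1]
        for i, band in enumerate(BANDS):
            key = GenderAgeBandKey(gender, band)
            p, r_n, r_s = float(prevalence[i]), float(new_onset[i]), float(recurrent[i])
            epi[key] = EpiBandParams(
                prevalence=p,
                risk_new_onset=r_n,
                attack_rate=p * r_s + (1.0 - p) * r_n,
                incident_cases=int(rng.integers(100, 20000)),
                first_year_survival=float(survival[i]),
                nonstroke_mortality_general=float(mortality[i]),
            )
            true_rs[key] = r_s
            cost[key] = CostBandParams(
                cost_first_year=float(rng.uniform(1000, 12000)),
                cost_subsequent_year=float(rng.uniform(200, 2500)),
                cost_fatal=float(rng.uniform(2000, 15000)),
                cost_premature_death=float(rng.uniform(0, 600000)) if band < 65 else 0.0,
            )
            wages[key] = float(rng.uniform(8000, 45000)) if band < 65 else 0.0
            life[(gender, band)] = float(le[i])

    return SyntheticScenario(
        seed=seed,
        epi_table=epi,
        cost_table=cost,
        wage_table=wages,
        life_table=GeneralPopulationLifeTable(values=life),
        config=ModelConfig(),
        true_recurrent_risk=true_rs,
    )


@dataclass(frozen=True)
class MicrosimResult:
    mean_life_years: float
    se_life_years: float
    mean_cost: float
    se_cost: float
    n: int


def microsim_oracle(
    gender: Gender | str,
    onset_age: int,
    scenario: SyntheticScenario,
    n: int,
    seed: int,
) -> MicrosimResult:
    """Monte-Carlo estimate of mean life-years and lifetime cost.

    Simulates ``n`` independent life histories drawing each cycle's transition
    from the same TransitionSet as the cohort engine; life-years and costs are
    accumulated per individual, so the expectation path is independent of the
    engine's.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    gender = Gender(gender)
    rng = np.random.default_rng(seed)
    epi = scenario.epi_table
    costs = scenario.cost_table
    config = scenario.config

    onset = epi[GenderAgeBandKey(gender, onset_age)]
    c0 = costs[GenderAgeBandKey(gender, onset_age)]

    life = np.zeros(n)
    cost = np.zeros(n)

    # Cycle 1: direct 12-month case fatality.
    died_first = rng.random(n) < (1.0 - onset.first_year_survival)
    cost[died_first] += c0.cost_fatal + c0.cost_premature_death
    alive = ~died_first
    cost[alive] += c0.cost_first_year
    life[alive] += 1.0

    for age in range(onset_age + 1, config.terminal_age + 1):
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        ts = build_transition_set(gender, age, epi, config)
        cb = costs[GenderAgeBandKey(gender, band_of(age))]
        u = rng.random(idx.size)
        fatal = u < ts.p_fatal_recurrence
        nonstroke = (~fatal) & (u < ts.p_fatal_recurrence + ts.p_nonstroke_death)
        recur = (~fatal) & (~nonstroke) & (
            u < ts.p_fatal_recurrence + ts.p_nonstroke_death + ts.p_nonfatal_recurrence
        )
        stay = ~(fatal | nonstroke | recur)

        cost[idx[fatal]] += cb.cost_fatal + cb.cost_premature_death
        cost[idx[recur]] += cb.cost_first_year
        cost[idx[stay]] += cb.cost_subsequent_year
        survived = recur | stay
        life[idx[survived]] += 1.0
        alive[idx[fatal | nonstroke]] = False

    return MicrosimResult(
        mean_life_years=float(life.mean()),
        se_life_years=float(life.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        mean_cost=float(cost.mean()),
        se_cost=float(cost.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        n=n,
    )


# ---------------------------------------------------------------------------
# Claims ascertainment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticClaimRecord:
    """One stroke-coded claim line for one person."""

    person_id: int
    event_date: dt.date
    diagnosis_code: str
    setting: str  # inpatient | outpatient
    death_date: dt.date | None = None

    def __post_init__(self) -> None:
        if self.diagnosis_code not in STROKE_CODES:
            raise ValueError(f"diagnosis_code must be one of {STROKE_CODES}")
        if self.setting not in ("inpatient", "outpatient"):
            raise ValueError("setting must be 'inpatient' or 'outpatient'")
        if self.death_date is not None and self.death_date < self.event_date:
            raise ValueError("death_date cannot precede event_date")


def generate_claims(
    seed: int,
    n_persons: int,
    index_year: int = 2002,
    year_span: int = 2,
) -> list[SyntheticClaimRecord]:
    """Synthetic claim histories spanning the washout window and index year.

    Each person receives one to five stroke claims scattered over
    ``[index_year - year_span, index_year]``; roughly a third of persons die,
    at a random lag after their first claim, so that both fatal and non-fatal
    incident cases occur.
    """
    rng = np.random.default_rng(seed)
    start = dt.date(index_year - year_span, 1, 1)
    days_total = (dt.date(index_year, 12, 31) - start).days
    records: list[SyntheticClaimRecord] = []
    for pid in range(n_persons):
        n_claims = int(rng.integers(1, 6))
        offsets = np.sort(rng.integers(0, days_total + 1, n_claims))
        first = start + dt.timedelta(days=int(offsets[0]))
        death = None
        if rng.random() < 0.35:
            death = first + dt.timedelta(days=int(rng.integers(0, 3 * YEAR_DAYS)))
        for off in offsets:
            date = start + dt.timedelta(days=int(off))
            if death is not None and date > death:
                continue
            records.append(
                SyntheticClaimRecord(
                    person_id=pid,
                    event_date=date,
                    diagnosis_code=str(rng.choice(STROKE_CODES)),
                    setting=str(rng.choice(["inpatient", "outpatient"], p=[0.4, 0.6])),
                    death_date=death,
                )
            )
    return records


def ascertain_incident_cases(
    records: list[SyntheticClaimRecord],
    index_year: int,
    window_years: int = 1,
) -> tuple[list[int], dict[int, bool]]:
    """Identify incident cases and label them fatal or non-fatal.

    A person is an incident case if their first stroke claim of the index
    year is preceded by no stroke claim within the washout window
    (``window_years`` x 365 days).  The case is fatal when death occurs
    within 365 days of the index event.

    Returns the sorted incident person ids and a mapping id -> fatal flag.
    """
    by_person: dict[int, list[SyntheticClaimRecord]] = {}
    for rec in records:
        by_person.setdefault(rec.person_id, []).append(rec)

    incident: list[int] = []
    fatal: dict[int, bool] = {}
    window = dt.timedelta(days=window_years * YEAR_DAYS)
    for pid, recs in by_person.items():
        recs = sorted(recs, key=lambda r: r.event_date)
        index_claims = [r for r in recs if r.event_date.year == index_year]
        if not index_claims:
            continue
        index_event = index_claims[0]
        prior = [
            r
            for r in recs
            if index_event.event_date - window <= r.event_date < index_event.event_date
        ]
        if prior:
            continue
        incident.append(pid)
        death = index_event.death_date
        fatal[pid] = bool(
            death is not None and (death - index_event.event_date).days <= YEAR_DAYS
        )
    incident.sort()
    return incident, fatal
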