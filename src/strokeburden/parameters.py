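"""Typed model inputs, validation and delimited-text I/O.

All monetary amounts are stored in thousand KRW (2008 values).  Percentage
columns in the fixture files (prevalence, one-year survival) are converted to
fractions at load time; per-100,000 person-year rate columns are kept on their
printed scale and only divided down inside :mod:`strokeburden.transitions`.

The bundled fixtures under ``strokeburden/data`` carry the national
epidemiologic parameter table (gender x 10-year onset band), the per-person
annual cost schedule by onset band, and general-population life expectancies
at the five modelled onset ages.
"""

from __future__ import annotations

import enum
from decimal import Decimal
from importlib import resources
from pathlib import Path
from typing import Mapping, NamedTuple

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "Gender",
    "BANDS",
    "GenderAgeBandKey",
    "band_of",
    "EpiBandParams",
    "MortalityAdjustment",
    "CostBandParams",
    "GeneralPopulationLifeTable",
    "ModelConfig",
    "ParameterError",
    "load_epi_table",
    "load_cost_table",
    "load_life_table",
    "load_wage_table",
    "load_config",
    "write_epi_table",
    "write_cost_table",
    "default_epi_table",
    "default_cost_table",
    "default_life_table",
    "default_wage_table",
    "default_config",
    "data_path",
]

#: Lower bounds of the 10-year onset bands; 85 is open-ended.
BANDS: tuple[int, ...] = (45, 55, 65, 75, 85)


class Gender(str, enum.Enum):
    male = "male"
    female = "female"


class GenderAgeBandKey(NamedTuple):
    gender: Gender
    band: int


class ParameterError(ValueError):
    """A parameter table failed validation; the message names row and rule."""


def band_of(age: float) -> int:
    """Lower bound of the 10-year band containing ``age`` (>= 45)."""
    if age < BANDS[0]:
        raise ParameterError(f"age {age} below the youngest modelled band ({BANDS[0]})")
    return max(b for b in BANDS if b <= min(age, BANDS[-1]))


class EpiBandParams(BaseModel):
    """Epidemiologic rates and survival for one gender x onset band.

    ``prevalence`` (p) and ``first_year_survival`` (the non-fatal proportion
    P_nfs) are fractions; the three rates are per 100,000 person-years.
    """

    model_config = ConfigDict(frozen=True)

    prevalence: float = Field(gt=0, lt=1)
    risk_new_onset: float = Field(ge=0)
    attack_rate: float = Field(ge=0)
    incident_cases: int = Field(ge=0)
    first_year_survival: float = Field(gt=0, le=1)
    nonstroke_mortality_general: float = Field(ge=0)

    @model_validator(mode="after")
    def _consistent_attack_rate(self) -> "EpiBandParams":
        floor = (1.0 - self.prevalence) * self.risk_new_onset
        if self.attack_rate < floor:
            raise ValueError(
                "attack_rate must be >= (1 - prevalence) * risk_new_onset "
                f"({self.attack_rate} < {floor:.4f}); the implied recurrent "
                "risk would be negative"
            )
        return self


class MortalityAdjustment(BaseModel):
    """Standardised mortality ratios for non-stroke death after stroke."""

    model_config = ConfigDict(frozen=True)

    smr_male: float = Field(default=1.914, gt=0)
    smr_female: float = Field(default=2.295, gt=0)

    def for_gender(self, gender: Gender | str) -> float:
        return self.smr_male if Gender(gender) is Gender.male else self.smr_female


class CostBandParams(BaseModel):
    """Per-person annual stroke costs for one onset band, thousand KRW."""

    model_config = ConfigDict(frozen=True)

    cost_first_year: float = Field(ge=0)
    cost_subsequent_year: float = Field(ge=0)
    cost_fatal: float = Field(ge=0)
    cost_premature_death: float = Field(default=0.0, ge=0)


class GeneralPopulationLifeTable(BaseModel):
    """Remaining life expectancy (years) at each modelled exact onset age."""

    model_config = ConfigDict(frozen=True)

    values: Mapping[tuple[Gender, int], float]

    @model_validator(mode="after")
    def _monotone(self) -> "GeneralPopulationLifeTable":
        for g in Gender:
            les = [self.values[(g, b)] for b in BANDS if (g, b) in self.values]
            if any(later >= earlier for earlier, later in zip(les, les[1:])):
                raise ValueError(f"life expectancy must strictly decrease with age ({g.value})")
        return self

    def at(self, gender: Gender | str, age: int) -> float:
        key = (Gender(gender), age)
        if key not in self.values:
            raise ParameterError(f"no life expectancy for {key}")
        return self.values[key]

    def at_band(self, gender: Gender | str, age: float) -> float:
        """Life expectancy looked up by the band containing ``age``."""
        return self.at(gender, band_of(age))


class ModelConfig(BaseModel):
    """Global model settings (cycle structure, SMRs, costing constants)."""

    model_config = ConfigDict(frozen=True)

    cycle_length_years: float = Field(default=1.0, gt=0)
    terminal_age: int = 99
    retirement_age: int = 65
    smr: MortalityAdjustment = MortalityAdjustment()
    productivity_mode: str = Field(default="human_capital", pattern="^(human_capital|friction)$")
    friction_period_years: float = Field(default=0.5, ge=0)
    training_cost_usd_2000: float = Field(default=362.0, ge=0)
    cpi_2008_base_2000: float = Field(default=129.3, gt=0)
    exchange_rate_krw_per_usd: float = Field(default=1200.0, gt=0)

    @model_validator(mode="after")
    def _terminal_after_onset(self) -> "ModelConfig":
        if self.terminal_age <= BANDS[-1]:
            raise ValueError("terminal_age must exceed every onset age")
        return self


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_EPI_COLUMNS = [
    "gender",
    "band",
    "prevalence_pct",
    "risk_new_onset_per_100k",
    "incident_cases",
    "attack_rate_per_100k",
    "first_year_survival_pct",
    "nonstroke_mortality_per_100k",
]

_COST_COLUMNS = [
    "gender",
    "band",
    "cost_first_year",
    "cost_subsequent_year",
    "cost_fatal",
    "cost_premature_death",
]


def _check_keys(df: pd.DataFrame, path: object) -> None:
    seen: set[GenderAgeBandKey] = set()
    for _, row in df.iterrows():
        try:
            key = GenderAgeBandKey(Gender(row["gender"]), int(row["band"]))
        except ValueError as exc:
            raise ParameterError(f"{path}: bad gender/band in row {row.to_dict()}: {exc}") from exc
        if key.band not in BANDS:
            raise ParameterError(f"{path}: band {key.band} is not one of {BANDS}")
        if key in seen:
            raise ParameterError(f"{path}: duplicate row for {key}")
        seen.add(key)
    missing = {GenderAgeBandKey(g, b) for g in Gender for b in BANDS} - seen
    if missing:
        names = ", ".join(f"({k.gender.value}, {k.band})" for k in sorted(missing))
        raise ParameterError(f"{path}: missing rows: {names}")


def load_epi_table(path: str | Path) -> dict[GenderAgeBandKey, EpiBandParams]:
    """Read the epidemiologic parameter table from delimited text.

    Raises :class:`ParameterError` naming the offending row and rule on any
    missing band, duplicate key or invariant violation.
    """
    # percent columns stay strings so the fraction is rounded only once
    df = pd.read_csv(
        path, comment="#", float_precision="round_trip",
        dtype={"prevalence_pct": str, "first_year_survival_pct": str},
    )
    missing_cols = set(_EPI_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ParameterError(f"{path}: missing columns {sorted(missing_cols)}")
    _check_keys(df, path)
    table: dict[GenderAgeBandKey, EpiBandParams] = {}
    for _, row in df.iterrows():
        key = GenderAgeBandKey(Gender(row["gender"]), int(row["band"]))
        try:
            table[key] = EpiBandParams(
                prevalence=_pct_to_frac(row["prevalence_pct"]),
                risk_new_onset=float(row["risk_new_onset_per_100k"]),
                attack_rate=float(row["attack_rate_per_100k"]),
                incident_cases=int(row["incident_cases"]),
                first_year_survival=_pct_to_frac(row["first_year_survival_pct"]),
                nonstroke_mortality_general=float(row["nonstroke_mortality_per_100k"]),
            )
        except ValueError as exc:
            raise ParameterError(f"{path}: row ({key.gender.value}, {key.band}): {exc}") from exc
    return table


def load_cost_table(path: str | Path) -> dict[GenderAgeBandKey, CostBandParams]:
    """Read the per-person annual cost table (thousand KRW).

    An absent/zero premature-death entry is stored as 0; bands at or beyond
    retirement (65+) must not carry a premature-death cost.
    """
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing_cols = set(_COST_COLUMNS) - {c for c in df.columns} - {"cost_premature_death"}
    if missing_cols - {"cost_premature_death"}:
        raise ParameterError(f"{path}: missing columns {sorted(missing_cols)}")
    _check_keys(df, path)
    table: dict[GenderAgeBandKey, CostBandParams] = {}
    for _, row in df.iterrows():
        key = GenderAgeBandKey(Gender(row["gender"]), int(row["band"]))
        premature = row.get("cost_premature_death", 0.0)
        premature = 0.0 if pd.isna(premature) else float(premature)
        try:
            params = CostBandParams(
                cost_first_year=float(row["cost_first_year"]),
                cost_subsequent_year=float(row["cost_subsequent_year"]),
                cost_fatal=float(row["cost_fatal"]),
                cost_premature_death=premature,
            )
        except ValueError as exc:
            raise ParameterError(f"{path}: row ({key.gender.value}, {key.band}): {exc}") from exc
        if key.band >= 65 and params.cost_premature_death != 0:
            raise ParameterError(
                f"{path}: row ({key.gender.value}, {key.band}): premature-death "
                "cost must be 0 for bands at or beyond retirement (65+)"
            )
        table[key] = params
    return table


def load_life_table(path: str | Path) -> GeneralPopulationLifeTable:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    values = {
        (Gender(row["gender"]), int(row["age"])): float(row["life_expectancy_years"])
        for _, row in df.iterrows()
    }
    try:
        return GeneralPopulationLifeTable(values=values)
    except ValueError as exc:
        raise ParameterError(f"{path}: {exc}") from exc


def load_wage_table(path: str | Path) -> dict[GenderAgeBandKey, float]:
    """Read a gender x band annual wage schedule (thousand KRW/year)."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    table: dict[GenderAgeBandKey, float] = {}
    for _, row in df.iterrows():
        wage = float(row["annual_wage"])
        if wage < 0:
            raise ParameterError(f"{path}: negative wage for {row['gender']}/{row['band']}")
        table[GenderAgeBandKey(Gender(row["gender"]), int(row["band"]))] = wage
    return table


def load_config(path: str | Path) -> ModelConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    smr = MortalityAdjustment(
        smr_male=raw.pop("smr_male", 1.914), smr_female=raw.pop("smr_female", 2.295)
    )
    try:
        return ModelConfig(smr=smr, **raw)
    except (TypeError, ValueError) as exc:
        raise ParameterError(f"{path}: {exc}") from exc


def _fmt(x: float) -> str:
    """Shortest representation that parses back to the same float."""
    return repr(float(x))


def _pct_to_frac(x: object) -> float:
    """Percent -> fraction with a single rounding (exact decimal shift)."""
    s = x if isinstance(x, str) else repr(float(x))  # type: ignore[arg-type]
    return float(Decimal(s) / 100)


def _frac_to_pct(f: float) -> str:
    """Fraction -> percent string such that ``_pct_to_frac`` recovers ``f``."""
    return str(Decimal(repr(float(f))) * 100)


def write_epi_table(table: Mapping[GenderAgeBandKey, EpiBandParams], path: str | Path) -> None:
    rows = []
    for key in sorted(table, key=lambda k: (k.gender.value == "female", k.band)):
        p = table[key]
        rows.append(
            {
                "gender": key.gender.value,
                "band": key.band,
                "prevalence_pct": _frac_to_pct(p.prevalence),
                "risk_new_onset_per_100k": _fmt(p.risk_new_onset),
                "incident_cases": p.incident_cases,
                "attack_rate_per_100k": _fmt(p.attack_rate),
                "first_year_survival_pct": _frac_to_pct(p.first_year_survival),
                "nonstroke_mortality_per_100k": _fmt(p.nonstroke_mortality_general),
            }
        )
    pd.DataFrame(rows, columns=_EPI_COLUMNS).to_csv(path, index=False)


def write_cost_table(table: Mapping[GenderAgeBandKey, CostBandParams], path: str | Path) -> None:
    rows = []
    for key in sorted(table, key=lambda k: (k.gender.value == "female", k.band)):
        c = table[key]
        rows.append(
            {
                "gender": key.gender.value,
                "band": key.band,
                "cost_first_year": _fmt(c.cost_first_year),
                "cost_subsequent_year": _fmt(c.cost_subsequent_year),
                "cost_fatal": _fmt(c.cost_fatal),
                "cost_premature_death": _fmt(c.cost_premature_death),
            }
        )
    pd.DataFrame(rows, columns=_COST_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Bundled fixtures
# ---------------------------------------------------------------------------


def data_path(name: str) -> Path:
    """Path to a bundled data file."""
    return Path(str(resources.files("strokeburden").joinpath("data", name)))


def default_epi_table() -> dict[GenderAgeBandKey, EpiBandParams]:
    return load_epi_table(data_path("epi_params.csv"))


def default_cost_table() -> dict[GenderAgeBandKey, CostBandParams]:
    return load_cost_table(data_path("cost_params.csv"))


def default_life_table() -> GeneralPopulationLifeTable:
    return load_life_table(data_path("genpop_life_expectancy.csv"))


def default_wage_table() -> dict[GenderAgeBandKey, float]:
    return load_wage_table(data_path("wages_synthetic.csv"))


def default_config() -> ModelConfig:
    return load_config(data_path("config.yaml"))
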