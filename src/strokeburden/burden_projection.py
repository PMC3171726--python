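"""National burden projection and one-way sensitivity analysis.

The national lifetime burden attributes to every incident case of a given
gender and onset band the per-person lifetime cost of that band, so the
national cell is incident_cases x lifetime cost.  Age-group shares of
incidence and of lifetime costs follow directly.  One-way sensitivity reruns
the full cohort pipeline with one parameter group scaled at a time (SMR
+-20%, unit costs +-20%, or the friction-cost productivity valuation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .cost_assembly import WageInputs, friction_cost_table
from .markov_engine import all_cohort_results, lifetime_result
from .parameters import (
    BANDS,
    CostBandParams,
    EpiBandParams,
    Gender,
    GenderAgeBandKey,
    GeneralPopulationLifeTable,
    ModelConfig,
)

__all__ = [
    "BurdenResult",
    "national_burden",
    "model_lifetime_costs",
    "one_way_sensitivity",
    "SENSITIVITY_SCENARIOS",
]

SENSITIVITY_SCENARIOS = ("smr", "costs", "friction")


@dataclass(frozen=True)
class BurdenResult:
    """National lifetime-cost totals and age-group shares."""

    cells: pd.DataFrame  # per (gender, band): incident cases, cost, burden
    total_burden: float  # thousand KRW
    total_incidence: int
    incidence_share_by_band: dict[int, float]  # percent, genders pooled
    cost_share_by_band: dict[int, float]  # percent
    incidence_share_45_64: float
    cost_share_45_64: float


def national_burden(
    epi_table: Mapping[GenderAgeBandKey, EpiBandParams],
    lifetime_costs: Mapping[GenderAgeBandKey, float],
) -> BurdenResult:
    """Project the national lifetime burden from incident counts and costs.

    ``lifetime_costs`` maps each gender/onset band to a per-person lifetime
    cost in thousand KRW (model output or an externally supplied schedule).
    """
    rows = []
    for gender in Gender:
        for band in BANDS:
            key = GenderAgeBandKey(gender, band)
            cases = epi_table[key].incident_cases
            cost = lifetime_costs[key]
            rows.append(
                {
                    "gender": gender.value,
                    "band": band,
                    "incident_cases": cases,
                    "lifetime_cost_per_person": cost,
                    "burden": cases * cost,
                }
            )
    cells = pd.DataFrame(rows)
    total_burden = float(cells["burden"].sum())
    total_cases = int(cells["incident_cases"].sum())
    by_band = cells.groupby("band")[["incident_cases", "burden"]].sum()
    inc_share = (100.0 * by_band["incident_cases"] / total_cases).to_dict()
    cost_share = (100.0 * by_band["burden"] / total_burden).to_dict()
    return BurdenResult(
        cells=cells,
        total_burden=total_burden,
        total_incidence=total_cases,
        incidence_share_by_band={int(k): v for k, v in inc_share.items()},
        cost_share_by_band={int(k): v for k, v in cost_share.items()},
        incidence_share_45_64=inc_share[45] + inc_share[55],
        cost_share_45_64=cost_share[45] + cost_share[55],
    )


def model_lifetime_costs(
    epi_table: Mapping[GenderAgeBandKey, EpiBandParams],
    cost_table: Mapping[GenderAgeBandKey, CostBandParams],
    life_table: GeneralPopulationLifeTable,
    config: ModelConfig,
) -> dict[GenderAgeBandKey, float]:
    """Per-person lifetime costs (thousand KRW) computed by the cohort engine."""
    return {
        GenderAgeBandKey(r.gender, r.onset_age): r.lifetime_cost_total
        for r in all_cohort_results(epi_table, cost_table, life_table, config)
    }


def _scaled_smr_config(config: ModelConfig, factor: float) -> ModelConfig:
    smr = config.smr.model_copy(
        update={"smr_male": config.smr.smr_male * factor, "smr_female": config.smr.smr_female * factor}
    )
    return config.model_copy(update={"smr": smr})


def _scaled_cost_table(
    cost_table: Mapping[GenderAgeBandKey, CostBandParams],
    factor: float,
    scale_premature: bool,
) -> dict[GenderAgeBandKey, CostBandParams]:
    out = {}
    for key, c in cost_table.items():
        out[key] = CostBandParams(
            cost_first_year=c.cost_first_year * factor,
            cost_subsequent_year=c.cost_subsequent_year * factor,
            cost_fatal=c.cost_fatal * factor,
            cost_premature_death=c.cost_premature_death * (factor if scale_premature else 1.0),
        )
    return out


def one_way_sensitivity(
    epi_table: Mapping[GenderAgeBandKey, EpiBandParams],
    cost_table: Mapping[GenderAgeBandKey, CostBandParams],
    life_table: GeneralPopulationLifeTable,
    config: ModelConfig,
    wages: WageInputs | None = None,
    scale_premature: bool = False,
    spread: float = 0.20,
) -> pd.DataFrame:
    """One-way sensitivity of per-person lifetime cost, per cohort.

    Scenarios: both SMRs scaled by 1 +- ``spread``; all unit costs scaled by
    1 +- ``spread`` (premature-death costs included only when
    ``scale_premature`` is set — both variants are reported); and the
    friction-cost productivity valuation (requires a wage schedule).
    Ranges are reported as (low, high) = (min, max) over the scenario pair.
    """
    rows = []
    for gender in Gender:
        for onset in BANDS:
            base = lifetime_result(gender, onset, epi_table, cost_table, life_table, config)
            row: dict[str, object] = {
                "gender": gender.value,
                "onset_age": onset,
                "base_total": base.lifetime_cost_total,
                "base_excl_premature": base.lifetime_cost_excl_premature,
            }

            smr_vals = [
                lifetime_result(
                    gender, onset, epi_table, cost_table, life_table,
                    _scaled_smr_config(config, f),
                ).lifetime_cost_total
                for f in (1.0 - spread, 1.0 + spread)
            ]
            row["smr_low"], row["smr_high"] = min(smr_vals), max(smr_vals)

            for label, premature_flag in (("cost", scale_premature), ("cost_all", True)):
                vals = [
                    lifetime_result(
                        gender, onset, epi_table,
                        _scaled_cost_table(cost_table, f, premature_flag),
                        life_table, config,
                    ).lifetime_cost_total
                    for f in (1.0 - spread, 1.0 + spread)
                ]
                row[f"{label}_low"], row[f"{label}_high"] = min(vals), max(vals)

            if wages is not None:
                row["friction"] = lifetime_result(
                    gender, onset, epi_table,
                    friction_cost_table(cost_table, wages, config),
                    life_table, config,
                ).lifetime_cost_total
            rows.append(row)
    return pd.DataFrame(rows)
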