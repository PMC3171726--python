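"""Report tables and run manifests.

Rounding happens only here, at render time; all upstream computation is kept
at full floating-point precision.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .markov_engine import LifetimeResult

__all__ = ["render_life_table", "render_cost_table", "RunManifest"]


def render_life_table(results: Iterable[LifetimeResult]) -> pd.DataFrame:
    """Life-expectancy report: general-population LE, model LE, YLL, % reduction."""
    results = list(results)
    if not results:
        raise ValueError("no cohort results to render")
    rows = [
        {
            "gender": r.gender.value,
            "onset_age": r.onset_age,
            "life_expectancy_general": round(r.life_expectancy_general, 2),
            "life_expectancy_model": round(r.life_expectancy_post_stroke, 2),
            "years_of_life_lost": round(r.years_of_life_lost, 2),
            "reduction_pct": round(r.reduction_pct, 2),
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def _money(x: float) -> str:
    return f"{round(x):,.0f}"


def _rng(lo: float, hi: float) -> str:
    return f"{_money(lo)}~{_money(hi)}"


def render_cost_table(
    results: Iterable[LifetimeResult],
    sensitivity: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Lifetime-cost report: base case with the excluding-premature figure in
    parentheses, and sensitivity columns as low~high ranges when supplied."""
    results = list(results)
    if not results:
        raise ValueError("no cohort results to render")
    rows = []
    for r in results:
        row: dict[str, object] = {
            "gender": r.gender.value,
            "onset_age": r.onset_age,
            "base_case": f"{_money(r.lifetime_cost_total)} ({_money(r.lifetime_cost_excl_premature)})",
        }
        if sensitivity is not None:
            sel = sensitivity[
                (sensitivity["gender"] == r.gender.value)
                & (sensitivity["onset_age"] == r.onset_age)
            ].iloc[0]
            row["smr_pm20"] = _rng(sel["smr_low"], sel["smr_high"])
            row["cost_pm20"] = _rng(sel["cost_low"], sel["cost_high"])
            if "friction" in sel:
                row["friction"] = _money(sel["friction"])
        rows.append(row)
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Provenance snapshot for one CLI run."""

    command: str
    config: Mapping[str, object]
    inputs: dict[str, str] = dataclasses.field(default_factory=dict)  # path -> sha256
    seeds: list[int] = dataclasses.field(default_factory=list)
    outputs: list[str] = dataclasses.field(default_factory=list)
    timestamp: str = dataclasses.field(
        default_factory=lambda: dt.datetime.now(dt.timezone.utc).isoformat()
    )

    def add_input(self, path: str | Path) -> None:
        p = Path(path)
        self.inputs[str(p)] = _sha256(p)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))
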