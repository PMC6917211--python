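"""Cost accounting: events and person-years to discounted 2018-USD costs.

Costs fall into four additive components:

* **acute** — per-event hospitalization cost, booked in the event's cycle
  (fatal events still incur it);
* **chronic CVD** — annual disease-management cost of each post-event
  health state, starting the cycle *after* the event (the panel records
  the state at cycle start, so this timing is automatic);
* **chronic diabetes** — annual cost per diabetic person-year; and
* **drug** — annual cost per treated (antihypertensive) person-year.

All components are discounted to cycle 0 at the configured rate.  The
per-person-year ledger stores discounted but *unweighted* amounts next to
the half-cycle person-time weight; multi-year totals weight the
person-time components (chronic, drug) by it, while per-event acute costs
are never person-time weighted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from cardiocost.microsim import STATE_NAMES, SimRun

__all__ = ["CostParameters", "CostLedger", "CostedRun", "discount",
           "accumulate", "annualize", "inflate", "cost_run"]

COMPONENTS = ["acute", "chronic_cvd", "chronic_diabetes", "drug"]


class CostParameters(BaseModel):
    model_config = ConfigDict(extra="forbid")

    acute_cost: dict[str, float]
    chronic_cvd_cost: dict[str, float]
    chronic_diabetes_cost: float = Field(ge=0.0)
    drug_cost: dict[str, float]
    base_year: int = 2018
    inflation_multiplier: dict[int, float] = Field(default_factory=lambda: {2018: 1.0})
    discount_rate: float = Field(default=0.03, ge=0.0)


def discount(amount: float, cycle_year: int, rate: float) -> float:
    """Present value at cycle 0: ``amount / (1 + rate) ** cycle_year``."""
    if rate < 0.0:
        raise ValueError("discount rate must be >= 0")
    if cycle_year < 0:
        raise ValueError("cycle_year must be >= 0")
    return amount / (1.0 + rate) ** cycle_year


def inflate(amount: float, from_year: int, multiplier_table: dict[int, float]) -> float:
    """Convert ``amount`` from ``from_year`` dollars to 2018 dollars."""
    if from_year not in multiplier_table:
        raise KeyError(f"no inflation multiplier for year {from_year}")
    return amount * multiplier_table[from_year]


@dataclass
class CostLedger:
    """Per-person-year discounted costs plus aggregation helpers."""

    #: person_id, cycle_year, weight, acute, chronic_cvd, chronic_diabetes,
    #: drug — component values discounted, NOT person-time weighted
    table: pd.DataFrame
    discount_rate: float

    def totals(self) -> dict[str, float]:
        """Component totals over all person-years, half-cycle weighted
        (the weight applies to person-time components, not per-event acute
        costs)."""
        t = self.table
        w = t["weight"].to_numpy()
        out = {"acute": float(t["acute"].sum())}
        for comp in ("chronic_cvd", "chronic_diabetes", "drug"):
            out[comp] = float((t[comp].to_numpy() * w).sum())
        out["chronic"] = out["chronic_cvd"] + out["chronic_diabetes"]
        out["total"] = sum(out[c] for c in COMPONENTS)
        return out

    def final_year(self) -> int:
        return int(self.table["cycle_year"].max())

    def final_year_person_costs(self) -> pd.DataFrame:
        """Final-cycle cross-section, one row per alive person, unweighted."""
        t = self.table
        return t[t["cycle_year"] == self.final_year()].reset_index(drop=True)


def accumulate(ledger: pd.DataFrame, panel: pd.DataFrame,
               params: CostParameters) -> CostLedger:
    """Build the per-person-year cost ledger from events and states."""
    # non-hospitalization bookkeeping rows carry no acute cost by default
    zero_default = {"other_death", "diabetes_onset"}
    for ev in pd.unique(ledger["event_type"]) if len(ledger) else []:
        if ev not in params.acute_cost and ev not in zero_default:
            raise KeyError(f"acute cost missing for event type {ev!r}")

    t = panel[["person_id", "cycle_year", "weight"]].copy()
    cyc = panel["cycle_year"].to_numpy()
    disc = (1.0 + params.discount_rate) ** (-cyc.astype(float))

    state_cost = np.array([params.chronic_cvd_cost.get(s, 0.0) for s in STATE_NAMES])
    t["chronic_cvd"] = state_cost[panel["state"].to_numpy()] * disc
    t["chronic_diabetes"] = (
        panel["diabetes"].to_numpy().astype(float) * params.chronic_diabetes_cost * disc
    )
    drug = params.drug_cost.get("antihypertensive", 0.0)
    t["drug"] = panel["htn_treated"].to_numpy().astype(float) * drug * disc

    t["acute"] = 0.0
    if len(ledger):
        ev = ledger.copy()
        ev["amount"] = ev["event_type"].map(
            lambda e: params.acute_cost.get(e, 0.0)).astype(float)
        ev["amount"] *= (1.0 + params.discount_rate) ** (-ev["cycle_year"].astype(float))
        acute = ev.groupby(["person_id", "cycle_year"])["amount"].sum()
        key = pd.MultiIndex.from_arrays([t["person_id"], t["cycle_year"]])
        t["acute"] = acute.reindex(key, fill_value=0.0).to_numpy()

    t = t[["person_id", "cycle_year", "weight"] + COMPONENTS]
    return CostLedger(table=t, discount_rate=params.discount_rate)


def annualize(costledger: CostLedger, panel: pd.DataFrame | None = None) -> dict:
    """Per-capita annual costs from the final cross-sectional year.

    Component totals of the final cycle (unweighted person-time: the
    cross-section stands for one full calendar year) divided by the number
    of persons alive in that cycle.  Components sum exactly to ``total``.
    """
    fy = costledger.final_year_person_costs()
    n_alive = len(fy)
    if n_alive == 0:
        raise ValueError("no persons alive in the final year")
    out = {comp: float(fy[comp].sum()) / n_alive for comp in COMPONENTS}
    out["chronic"] = out["chronic_cvd"] + out["chronic_diabetes"]
    out["total"] = sum(out[c] for c in COMPONENTS)
    out["n_alive"] = n_alive
    return out


@dataclass
class CostedRun:
    """A scenario run with its cost ledger attached."""

    sim: SimRun
    costs: CostLedger
    params: CostParameters

    def per_capita_annual(self) -> dict:
        return annualize(self.costs, self.sim.panel)


def cost_run(sim: SimRun, params: CostParameters) -> CostedRun:
    return CostedRun(sim=sim, costs=accumulate(sim.ledger, sim.panel, params),
                     params=params)
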