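"""Counterfactual attribution: observed vs optimal-diet cost differences.

The attributable cost of suboptimal diet is the per-capita annual cost
under observed intakes minus the cost under a counterfactual in which
intakes are moved to their optimal levels — per factor individually and
for all factors jointly.  Because factor relative risks combine
multiplicatively, the joint attributable cost is at most the sum of the
single-factor costs (sub-additivity).  Uncertainty intervals come from
Monte-Carlo redraws of the factor relative risks (lognormal on the log-RR
scale) with the simulation rerun per draw; scenario pairs share common
random numbers so differences are low-variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from cardiocost.costs import COMPONENTS, CostedRun, CostParameters, cost_run
from cardiocost.diet import FactorConfig, Scenario, draw_rr_set
from cardiocost.microsim import SimConfig, run
from cardiocost.population import PopulationSpec

__all__ = ["AttributionResult", "PayerMix", "attributable_cost",
           "per_factor_sweep", "national_total", "proportion_of_total",
           "stratify", "bearer_allocation", "ci_from_draws"]

BEARERS = ("household", "government", "third_party")

AGE_BANDS = [("35-49", 35.0, 50.0), ("50-64", 50.0, 65.0), (">=65", 65.0, 200.0)]
BMI_BANDS = [("<30", 0.0, 30.0), (">=30", 30.0, 200.0)]


@dataclass
class AttributionResult:
    """Attributable cost of one scenario comparison."""

    name: str
    per_capita: float
    components: dict[str, float]
    ci: Optional[tuple[float, float]] = None
    national_total: Optional[float] = None
    strata: dict = field(default_factory=dict)
    #: per-person final-year cost difference (for stratification)
    person_costs: Optional[pd.DataFrame] = None
    #: static attributes of the simulated persons (for stratification)
    persons: Optional[pd.DataFrame] = None


class PayerMix(BaseModel):
    """Ultimate cost-bearer shares by insurance category."""

    model_config = ConfigDict(extra="forbid")

    shares: dict[str, dict[str, float]]

    @model_validator(mode="after")
    def _check(self) -> "PayerMix":
        for ins, row in self.shares.items():
            if set(row) != set(BEARERS):
                raise ValueError(f"{ins}: shares must have keys {BEARERS}")
            tot = sum(row.values())
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"{ins}: shares sum to {tot}, not 1")
            for b, v in row.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{ins}[{b}] = {v} outside [0, 1]")
        return self


def attributable_cost(run_observed: CostedRun,
                      run_counterfactual: CostedRun) -> AttributionResult:
    """Per-capita annual attributable cost, by component.

    Both runs must come from the same population (person ids must match);
    with common random numbers the final-year cross-sections then align
    person by person.
    """
    obs, cf = run_observed, run_counterfactual
    if len(obs.sim.persons) != len(cf.sim.persons) or not np.array_equal(
        obs.sim.persons["person_id"], cf.sim.persons["person_id"]
    ):
        raise ValueError("runs use different populations")

    pc_obs = obs.per_capita_annual()
    pc_cf = cf.per_capita_annual()
    components = {c: pc_obs[c] - pc_cf[c] for c in COMPONENTS}
    components["chronic"] = components["chronic_cvd"] + components["chronic_diabetes"]

    a = obs.costs.final_year_person_costs().set_index("person_id")
    b = cf.costs.final_year_person_costs().set_index("person_id")
    ids = a.index.union(b.index)
    diff = pd.DataFrame(index=ids)
    for c in COMPONENTS:
        diff[c] = a[c].reindex(ids, fill_value=0.0) - b[c].reindex(ids, fill_value=0.0)
    diff["total"] = diff[list(COMPONENTS)].sum(axis=1)
    diff = diff.reset_index().rename(columns={"index": "person_id"})

    return AttributionResult(
        name=cf.sim.scenario,
        per_capita=pc_obs["total"] - pc_cf["total"],
        components=components,
        person_costs=diff,
        persons=obs.sim.persons,
    )


def national_total(per_capita: float, population_size: float) -> float:
    """Scale a per-capita annual cost to the national adult population."""
    if population_size <= 0:
        raise ValueError("population_size must be positive")
    return per_capita * population_size


def proportion_of_total(attributable: float, total_direct: float) -> float:
    """Attributable cost as a percentage of total direct disease cost."""
    if total_direct <= 0:
        raise ValueError("total_direct must be positive")
    return 100.0 * attributable / total_direct


def ci_from_draws(draws: Sequence[float]) -> tuple[float, float]:
    """95% percentile interval (2.5th, 97.5th) across Monte-Carlo draws."""
    draws = np.asarray(list(draws), dtype=float)
    if draws.size < 2:
        raise ValueError("need at least 2 draws for a percentile interval")
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return float(lo), float(hi)


def per_factor_sweep(
    population: pd.DataFrame,
    factors: FactorConfig,
    config: SimConfig,
    params: CostParameters,
    seed: int,
    entrant_spec: Optional[PopulationSpec] = None,
    ci_draws: int = 0,
) -> dict[str, AttributionResult]:
    """Attributable cost per factor plus the all-factors-optimal run.

    Returns a mapping with one entry per factor (key: factor name), the
    joint result under ``"combined"``, and each single factor's share of
    the combined cost in ``result.strata["share_of_combined"]``.  With
    ``ci_draws`` > 0, relative risks are redrawn and both runs repeated
    per draw to form 95% percentile intervals on the total.
    """

    def one_pass(fac: FactorConfig, tag: int) -> dict[str, AttributionResult]:
        obs = cost_run(
            run(population, Scenario.observed_all(fac), fac, config, seed,
                entrant_spec=entrant_spec), params)
        out: dict[str, AttributionResult] = {}
        for f in fac.factors:
            cf = cost_run(
                run(population, Scenario.single_optimal(fac, f.name), fac,
                    config, seed, entrant_spec=entrant_spec), params)
            out[f.name] = attributable_cost(obs, cf)
        cf_all = cost_run(
            run(population, Scenario.optimal_all(fac), fac, config, seed,
                entrant_spec=entrant_spec), params)
        out["combined"] = attributable_cost(obs, cf_all)
        return out

    results = one_pass(factors, 0)

    if ci_draws > 0:
        draws: dict[str, list[float]] = {k: [] for k in results}
        for d in range(ci_draws):
            fac_d = draw_rr_set(factors, seed=int(seed) * 1009 + d)
            res_d = one_pass(fac_d, d + 1)
            for k, v in res_d.items():
                draws[k].append(v.per_capita)
        for k in results:
            results[k].ci = ci_from_draws(draws[k])

    combined = results["combined"].per_capita
    for f in factors.factors:
        share = (100.0 * results[f.name].per_capita / combined
                 if combined != 0.0 else float("nan"))
        results[f.name].strata["share_of_combined"] = share
    return results


def _band_label(x: np.ndarray, bands) -> np.ndarray:
    out = np.full(len(x), "", dtype=object)
    for label, lo, hi in bands:
        out[(x >= lo) & (x < hi)] = label
    return out


def stratify(result: AttributionResult, persons: pd.DataFrame | None = None,
             by: str = "sex") -> pd.DataFrame:
    """Per-capita attributable components within strata of one variable.

    ``by`` is one of sex, age_band (35-49 / 50-64 / >=65, at the final
    cross-sectional year), race, education, bmi_band (<30 / >=30) or
    insurance.  The person-weighted mean of the stratum values equals the
    overall per-capita cost exactly.
    """
    if result.person_costs is None:
        raise ValueError("result carries no per-person costs")
    if persons is None:
        persons = result.persons
    if persons is None:
        raise ValueError("no person attribute table available")
    pc = result.person_costs.merge(
        persons[["person_id", "sex", "age", "race", "education", "insurance",
                 "bmi"]],
        on="person_id", how="left")
    if by == "sex":
        key = pc["sex"]
    elif by == "race":
        key = pc["race"]
    elif by == "education":
        key = pc["education"]
    elif by == "insurance":
        key = pc["insurance"]
    elif by == "age_band":
        key = _band_label(pc["age"].to_numpy(float), AGE_BANDS)
    elif by == "bmi_band":
        key = _band_label(pc["bmi"].to_numpy(float), BMI_BANDS)
    else:
        raise KeyError(f"unknown stratifier {by!r}")
    cols = list(COMPONENTS) + ["total"]
    g = pc.groupby(np.asarray(key))[cols]
    out = g.mean()
    out["n"] = g.size()
    return out


def bearer_allocation(costs_by_insurance: dict[str, float] | pd.Series,
                      mix: PayerMix) -> pd.DataFrame:
    """Split per-insurance costs across household/government/third party.

    Grand totals are conserved: the allocated sum equals the input sum.
    """
    if isinstance(costs_by_insurance, pd.Series):
        costs_by_insurance = costs_by_insurance.to_dict()
    rows = {}
    for ins, cost in costs_by_insurance.items():
        if ins not in mix.shares:
            raise KeyError(f"payer mix has no row for insurance {ins!r}")
        rows[ins] = {b: cost * mix.shares[ins][b] for b in BEARERS}
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(BEARERS))
    out.index.name = "insurance"
    return out
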