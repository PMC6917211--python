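"""Yearly-cycle person-level simulation of CVD and diabetes natural history.

Each person occupies one CVD health state per cycle (well, angina,
post-MI, post-stroke, post-MI-and-stroke, or dead) plus a diabetes flag.
Every cycle the model:

1. evaluates a logistic annual CVD risk from age, sex, SBP, total and HDL
   cholesterol, smoking and diabetes, splits it into CHD events (MI,
   angina, cardiac arrest) and stroke by configured shares, and multiplies
   each cause-specific hazard by the person's diet relative risk for that
   disease (CHD RR on CHD events, stroke RR on stroke, diabetes RR on the
   onset hazard);
2. resolves competing risks with a single multinomial draw per person over
   {each event, background death, nothing}, then resolves fatality by
   event-type case fatality;
3. applies state transitions (post-event states are absorbing toward
   "well"; dead states are absorbing) and annual risk-factor drift; and
4. adds an entrant cohort of 35-year-olds grown at the configured rate.

Person-time in the first and last cycle is weighted 0.5 (half-cycle
correction) for cost and exposure accumulation.  All scenario runs on the
same population share per-person random streams (common random numbers),
so scenario differences are not inflated by simulation noise.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field
from scipy.special import expit

from cardiocost.diet import FactorConfig, Scenario, apply_scenario, population_rr
from cardiocost.population import PopulationSpec, entrant_size, make_entrant_cohort

logger = logging.getLogger(__name__)

__all__ = ["SimConfig", "SimRun", "seed_states", "update_risk_factors",
           "annual_event_probs", "step_year", "run",
           "STATE_NAMES", "WELL", "ANGINA", "POST_MI", "POST_STROKE",
           "POST_MI_STROKE", "DEAD_CVD", "DEAD_OTHER"]

WELL, ANGINA, POST_MI, POST_STROKE, POST_MI_STROKE, DEAD_CVD, DEAD_OTHER = range(7)
STATE_NAMES = ["well", "angina", "post_mi", "post_stroke",
               "post_mi_and_stroke", "dead_cvd", "dead_other"]

#: multinomial slot order within a cycle (fixed so common random numbers
#: keep draws comparable across scenarios)
EVENTS = ["mi", "angina", "cardiac_arrest", "stroke", "diabetes_onset", "other_death"]


class LogisticCoeffs(BaseModel):
    model_config = ConfigDict(extra="forbid")
    intercept: float
    age: float
    male: float
    sbp: float
    total_chol: float
    hdl: float
    smoker: float
    diabetes: float


class DiabetesCoeffs(BaseModel):
    model_config = ConfigDict(extra="forbid")
    intercept: float
    age: float
    bmi: float


class BackgroundMortality(BaseModel):
    model_config = ConfigDict(extra="forbid")
    rate_at_35: float = Field(ge=0.0)
    log_slope: float = Field(ge=0.0)


class HtnTreatment(BaseModel):
    model_config = ConfigDict(extra="forbid")
    sbp_threshold: float
    annual_start_prob: float = Field(ge=0.0, le=1.0)


class SimConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    horizon_years: int = Field(default=5, ge=1)
    discount_rate: float = Field(default=0.03, ge=0.0)
    growth_rate: float = 0.005
    half_cycle: bool = True
    entrant_fraction: float = Field(default=0.015, ge=0.0)
    risk_logistic: LogisticCoeffs
    chd_share: float = Field(default=0.70, ge=0.0, le=1.0)
    chd_split: dict[str, float]
    case_fatality: dict[str, float]
    post_event_hazard_multiplier: float = Field(default=2.0, ge=1.0)
    diabetes_logistic: DiabetesCoeffs
    background_mortality: BackgroundMortality
    drift: dict[str, float] = Field(default_factory=dict)
    htn_treatment: HtnTreatment
    #: common random numbers across scenarios (per-person streams keyed by
    #: seed and cycle only); False draws fresh streams per scenario name
    common_random_numbers: bool = True


@dataclass
class SimRun:
    """Outputs of one scenario run."""

    scenario: str
    seed: int
    config: SimConfig
    #: incident events: person_id, cycle_year, event_type, fatal
    ledger: pd.DataFrame
    #: one row per alive person-year: person_id, cycle_year, state,
    #: diabetes, htn_treated, weight (half-cycle person-time weight)
    panel: pd.DataFrame
    #: static attributes of everyone ever simulated (baseline + entrants),
    #: with entry_year and final age
    persons: pd.DataFrame
    n_baseline: int = 0


def seed_states(table: pd.DataFrame) -> np.ndarray:
    """Initial CVD state from disease history flags."""
    mi = np.asarray(table["history_mi"], dtype=bool)
    stroke = np.asarray(table["history_stroke"], dtype=bool)
    angina = np.asarray(table["history_angina"], dtype=bool)
    state = np.full(len(table), WELL, dtype=np.int8)
    state[angina] = ANGINA
    state[mi] = POST_MI
    state[stroke] = POST_STROKE
    state[mi & stroke] = POST_MI_STROKE
    return state


def update_risk_factors(person: pd.DataFrame | pd.Series, drift: dict[str, float]):
    """Advance age by one year and apply configured linear drift."""
    person = person.copy()
    person["age"] = person["age"] + 1.0
    for col, slope in drift.items():
        person[col] = person[col] + slope
    return person


def _split_hazard(p: np.ndarray, rr: np.ndarray, share: float,
                  post_mult: np.ndarray) -> np.ndarray:
    """Cause-specific probability: hazard-scale share of the total CVD
    probability, scaled by the diet RR and the post-event multiplier."""
    h = -np.log1p(-np.minimum(p, 1.0 - 1e-12))
    return -np.expm1(-h * share * rr * post_mult)


def annual_event_probs(
    table: pd.DataFrame,
    state: np.ndarray,
    diabetes: np.ndarray,
    diet_rr: dict[str, np.ndarray],
    config: SimConfig,
    sbp_delta: np.ndarray | float = 0.0,
) -> dict[str, np.ndarray]:
    """Per-person annual probabilities for each competing event.

    ``diet_rr`` maps disease ("CHD", "stroke", "diabetes") to per-person
    relative risks; ``sbp_delta`` shifts SBP inside the risk equation
    (sodium blood-pressure pathway).  Probabilities are clipped to [0, 1];
    a clip is logged.
    """
    c = config.risk_logistic
    age = np.asarray(table["age"], dtype=float)
    male = (np.asarray(table["sex"]) == "male").astype(float)
    sbp = np.asarray(table["sbp"], dtype=float) + sbp_delta
    lp = (c.intercept + c.age * age + c.male * male
          + c.sbp * (sbp - 120.0)
          + c.total_chol * (np.asarray(table["total_chol"], dtype=float) - 200.0)
          + c.hdl * (np.asarray(table["hdl"], dtype=float) - 50.0)
          + c.smoker * np.asarray(table["smoker"], dtype=float)
          + c.diabetes * diabetes.astype(float))
    p_cvd = expit(lp)

    post = np.isin(state, (ANGINA, POST_MI, POST_STROKE, POST_MI_STROKE))
    post_mult = np.where(post, config.post_event_hazard_multiplier, 1.0)

    rr_chd = np.asarray(diet_rr.get("CHD", 1.0)) * np.ones(len(table))
    rr_str = np.asarray(diet_rr.get("stroke", 1.0)) * np.ones(len(table))
    rr_dm = np.asarray(diet_rr.get("diabetes", 1.0)) * np.ones(len(table))
    for name, rr in (("CHD", rr_chd), ("stroke", rr_str), ("diabetes", rr_dm)):
        if (rr < 0).any():
            raise ValueError(f"negative diet RR for {name}")

    probs: dict[str, np.ndarray] = {}
    for ev, split in config.chd_split.items():
        probs[ev] = _split_hazard(p_cvd, rr_chd, config.chd_share * split, post_mult)
    probs["stroke"] = _split_hazard(p_cvd, rr_str, 1.0 - config.chd_share, post_mult)

    d = config.diabetes_logistic
    bmi = np.asarray(table["bmi"], dtype=float)
    p_dm = expit(d.intercept + d.age * (age - 55.0) + d.bmi * (bmi - 29.0))
    h_dm = -np.log1p(-np.minimum(p_dm, 1.0 - 1e-12))
    probs["diabetes_onset"] = np.where(diabetes, 0.0, -np.expm1(-h_dm * rr_dm))

    bm = config.background_mortality
    probs["other_death"] = np.minimum(
        bm.rate_at_35 * np.exp(bm.log_slope * (age - 35.0)), 1.0
    )

    total = sum(probs.values())
    over = total > 1.0
    if over.any():
        logger.warning("event probabilities exceed 1 for %d persons; rescaled",
                       int(over.sum()))
        scale = np.where(over, 1.0 / total, 1.0)
        probs = {k: v * scale for k, v in probs.items()}
    return probs


def step_year(
    state: np.ndarray,
    diabetes: np.ndarray,
    probs: dict[str, np.ndarray],
    config: SimConfig,
    u_event: np.ndarray,
    u_fatal: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Resolve one cycle's events from pre-drawn uniforms.

    Returns updated (state, diabetes) and the cycle's event rows
    (without cycle_year/person_id columns; the caller attaches them).
    Dead persons are passed through unchanged.
    """
    alive = state < DEAD_CVD
    n = len(state)
    # inverse-CDF multinomial over the fixed slot order
    edges = np.zeros(n)
    chosen = np.full(n, -1, dtype=np.int8)
    for i, ev in enumerate(EVENTS):
        p = probs[ev]
        hit = alive & (chosen < 0) & (u_event >= edges) & (u_event < edges + p)
        chosen[hit] = i
        edges = edges + p

    new_state = state.copy()
    new_dm = diabetes.copy()
    rows = {"event_type": [], "fatal": [], "index": []}

    for i, ev in enumerate(EVENTS):
        idx = np.where(chosen == i)[0]
        if len(idx) == 0:
            continue
        if ev == "other_death":
            fatal = np.ones(len(idx), dtype=bool)
            new_state[idx] = DEAD_OTHER
        elif ev == "diabetes_onset":
            fatal = np.zeros(len(idx), dtype=bool)
            new_dm[idx] = True
        else:
            cf = config.case_fatality.get(ev, 0.0)
            fatal = u_fatal[idx] < cf
            dead = idx[fatal]
            surv = idx[~fatal]
            new_state[dead] = DEAD_CVD
            if ev in ("mi", "cardiac_arrest"):
                had_stroke = np.isin(new_state[surv], (POST_STROKE, POST_MI_STROKE))
                new_state[surv] = np.where(had_stroke, POST_MI_STROKE, POST_MI)
            elif ev == "stroke":
                had_mi = np.isin(new_state[surv], (POST_MI, POST_MI_STROKE))
                new_state[surv] = np.where(had_mi, POST_MI_STROKE, POST_STROKE)
            elif ev == "angina":
                well = surv[new_state[surv] == WELL]
                new_state[well] = ANGINA
        rows["event_type"].extend([ev] * len(idx))
        rows["fatal"].extend(fatal.tolist())
        rows["index"].extend(idx.tolist())

    events = pd.DataFrame(rows)
    return new_state, new_dm, events


def _cycle_rng(seed: int, cycle: int, scenario: str, crn: bool) -> np.random.Generator:
    if crn:
        key = [int(seed), 1000 + cycle]
    else:
        digest = hashlib.sha256(scenario.encode()).digest()
        key = [int(seed), 1000 + cycle, int.from_bytes(digest[:4], "little")]
    return np.random.default_rng(np.random.SeedSequence(key))


def run(
    table: pd.DataFrame,
    scenario: Scenario,
    factors: FactorConfig,
    config: SimConfig,
    seed: int,
    entrant_spec: Optional[PopulationSpec] = None,
) -> SimRun:
    """Simulate the population for ``horizon_years`` cycles under a scenario.

    Entrant cohorts of 35-year-olds (``entrant_fraction`` of the baseline
    cohort, grown at ``growth_rate``) join in every cycle after the first.
    Entrant attributes and all random draws are independent of the
    scenario, so two scenarios on the same ``(table, seed)`` are compared
    under common random numbers.
    """
    if config.horizon_years < 1:
        raise ValueError("horizon must be >= 1 year")
    n0 = len(table)
    horizon = config.horizon_years

    # pre-build entrant cohorts (scenario-independent)
    base_entrants = int(round(config.entrant_fraction * n0))
    cohorts = [table.reset_index(drop=True)]
    if entrant_spec is not None and base_entrants > 0:
        for year in range(1, horizon):
            size = entrant_size(base_entrants, config.growth_rate, year)
            ent = make_entrant_cohort(entrant_spec, size, seed=int(seed) * 7919 + year)
            cohorts.append(ent)
    sizes = [len(c) for c in cohorts]
    everyone = pd.concat(cohorts, ignore_index=True)
    everyone["person_id"] = np.arange(len(everyone), dtype=np.int64)
    everyone["entry_year"] = np.repeat(
        np.arange(len(cohorts)) if len(cohorts) > 1 else [0], sizes
    )

    scen_table = apply_scenario(everyone, scenario, factors)

    # intake truncation caps from the observed population quantile
    caps = {
        f.name: float(np.quantile(np.asarray(everyone[f"intake_{f.name}"], float),
                                  factors.intake_cap_quantile))
        for f in factors.factors
    } if n0 else {}

    # sodium blood-pressure pathway: scenario-induced SBP shift
    sbp_delta = np.zeros(len(everyone))
    for f in factors.factors:
        if f.mode == "bp":
            obs = np.asarray(everyone[f"intake_{f.name}"], dtype=float)
            cf = np.asarray(scen_table[f"intake_{f.name}"], dtype=float)
            sbp_delta += f.bp_mmhg_per_gram * (cf - obs) / 1000.0

    state = seed_states(everyone)
    diabetes = np.asarray(everyone["diabetes"], dtype=bool).copy()
    htn = np.asarray(everyone["htn_treated"], dtype=bool).copy()
    cur = everyone[["age", "sex", "sbp", "total_chol", "hdl", "smoker",
                    "bmi"]].copy()
    entered = np.zeros(len(everyone), dtype=bool)
    entered[: sizes[0]] = True

    panel_parts: list[pd.DataFrame] = []
    ledger_parts: list[pd.DataFrame] = []
    pid = np.asarray(everyone["person_id"])

    for cycle in range(horizon):
        if cycle > 0 and len(sizes) > cycle:
            lo = sum(sizes[:cycle])
            entered[lo: lo + sizes[cycle]] = True
        active = entered & (state < DEAD_CVD)
        w = 0.5 if config.half_cycle and cycle in (0, horizon - 1) else 1.0

        panel_parts.append(pd.DataFrame({
            "person_id": pid[active],
            "cycle_year": cycle,
            "state": state[active],
            "diabetes": diabetes[active],
            "htn_treated": htn[active],
            "weight": w,
        }))

        diet_rr = {
            dz: population_rr(scen_table, factors, dz,
                              ages=np.asarray(cur["age"], float), caps=caps)
            for dz in ("CHD", "stroke", "diabetes")
        }
        probs = annual_event_probs(cur, state, diabetes, diet_rr, config,
                                   sbp_delta=sbp_delta)
        # inactive persons can have no events
        probs = {k: np.where(active, v, 0.0) for k, v in probs.items()}

        rng = _cycle_rng(seed, cycle, scenario.name, config.common_random_numbers)
        u = rng.random((3, len(everyone)))
        state, diabetes, events = step_year(state, diabetes, probs, config,
                                            u[0], u[1])
        if len(events):
            events = events.assign(person_id=pid[events["index"].to_numpy()],
                                   cycle_year=cycle).drop(columns="index")
            ledger_parts.append(events)

        # hypertension treatment initiation (drug-cost pathway)
        ht = config.htn_treatment
        eligible = active & (state < DEAD_CVD) & ~htn & \
            ((np.asarray(cur["sbp"], float) + sbp_delta) >= ht.sbp_threshold)
        htn = htn | (eligible & (u[2] < ht.annual_start_prob))

        # age/drift only those already in the model (entrants join at 35)
        cur.loc[entered, "age"] += 1.0
        for col, slope in config.drift.items():
            cur.loc[entered, col] += slope

    ledger = (pd.concat(ledger_parts, ignore_index=True)
              [["person_id", "cycle_year", "event_type", "fatal"]]
              if ledger_parts else
              pd.DataFrame(columns=["person_id", "cycle_year", "event_type", "fatal"]))
    panel = (pd.concat(panel_parts, ignore_index=True) if panel_parts else
             pd.DataFrame(columns=["person_id", "cycle_year", "state",
                                   "diabetes", "htn_treated", "weight"]))
    persons = everyone.copy()
    persons["age"] = np.asarray(cur["age"])
    return SimRun(scenario=scenario.name, seed=int(seed), config=config,
                  ledger=ledger, panel=panel, persons=persons, n_baseline=n0)
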