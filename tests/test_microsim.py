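"""Microsimulation: state seeding, event mechanics, oracle equivalence."""

import numpy as np
import pandas as pd
import pytest

from cardiocost.diet import FactorConfig, Scenario
from cardiocost.microsim import (
    ANGINA, DEAD_CVD, DEAD_OTHER, POST_MI, POST_MI_STROKE, POST_STROKE, WELL,
    SimConfig, annual_event_probs, run, seed_states, step_year,
    update_risk_factors,
)

from conftest import fixed_prob_config, no_factors, toy_table


def observed_none():
    return Scenario(name="observed", transforms={})


class TestSeedStates:
    def test_rules(self):
        t = toy_table(4)
        t.loc[1, "history_mi"] = True
        t.loc[2, "history_mi"] = True
        t.loc[2, "history_stroke"] = True
        t.loc[3, "history_angina"] = True
        s = seed_states(t)
        assert list(s) == [WELL, POST_MI, POST_MI_STROKE, ANGINA]

    def test_population_prevalences(self, pop200k):
        s = seed_states(pop200k)
        n = len(pop200k)
        # P(post_mi_and_stroke) = P(mi) * P(stroke) under independent draws
        p_both = 0.043 * 0.033
        p_mi_only = 0.043 - p_both
        se = np.sqrt(p_mi_only * (1 - p_mi_only) / n)
        assert abs((s == POST_MI).mean() - p_mi_only) < 3 * se


class TestRiskFactorUpdate:
    def test_zero_drift_only_ages(self):
        t = toy_table(3)
        out = update_risk_factors(t, {})
        assert (out["age"] == 56.0).all()
        pd.testing.assert_series_equal(out["sbp"], t["sbp"])

    def test_linear_drift(self):
        t = toy_table(1, sbp=120.0)
        out = update_risk_factors(t, {"sbp": 0.5})
        assert out["sbp"].iloc[0] == pytest.approx(120.5)
        for _ in range(9):
            out = update_risk_factors(out, {"sbp": 0.5})
        assert out["sbp"].iloc[0] == pytest.approx(125.0)


class TestAnnualEventProbs:
    def test_unit_rrs_leave_baseline(self, cfg):
        t = toy_table(100)
        state = seed_states(t)
        dm = np.zeros(100, dtype=bool)
        ones = {dz: np.ones(100) for dz in ("CHD", "stroke", "diabetes")}
        p1 = annual_event_probs(t, state, dm, ones, cfg.sim)
        p2 = annual_event_probs(t, state, dm, {}, cfg.sim)
        for ev in p1:
            np.testing.assert_allclose(p1[ev], p2[ev])

    def test_hazard_scale_doubling(self):
        config = fixed_prob_config(0.005)
        t = toy_table(10)
        state = seed_states(t)
        dm = np.zeros(10, dtype=bool)
        base = annual_event_probs(t, state, dm, {}, config)["mi"]
        double = annual_event_probs(
            t, state, dm, {"CHD": np.full(10, 2.0)}, config)["mi"]
        np.testing.assert_allclose(double / base, 2.0, rtol=0.01)

    def test_no_diabetes_reonset(self, cfg):
        t = toy_table(10, diabetes=True)
        state = seed_states(t)
        dm = np.ones(10, dtype=bool)
        p = annual_event_probs(t, state, dm, {}, cfg.sim)
        assert (p["diabetes_onset"] == 0.0).all()

    def test_probabilities_in_unit_interval(self, cfg):
        t = toy_table(50, age=84.0, sbp=200.0)
        state = seed_states(t)
        dm = np.ones(50, dtype=bool)
        big = {dz: np.full(50, 9.0) for dz in ("CHD", "stroke", "diabetes")}
        p = annual_event_probs(t, state, dm, big, cfg.sim)
        total = sum(p.values())
        assert (total <= 1.0 + 1e-12).all()
        assert all((v >= 0).all() for v in p.values())


class TestStepYear:
    def test_zero_probs_no_events(self, cfg):
        n = 20
        state = np.full(n, WELL, dtype=np.int8)
        dm = np.zeros(n, dtype=bool)
        probs = {ev: np.zeros(n) for ev in
                 ("mi", "angina", "cardiac_arrest", "stroke",
                  "diabetes_onset", "other_death")}
        s2, d2, ev = step_year(state, dm, probs, cfg.sim,
                               np.random.rand(n), np.random.rand(n))
        assert len(ev) == 0
        np.testing.assert_array_equal(s2, state)

    def test_certain_fatal_mi(self):
        config = fixed_prob_config(0.9999, mi_fatality=1.0)
        n = 5
        state = np.full(n, WELL, dtype=np.int8)
        dm = np.zeros(n, dtype=bool)
        probs = {ev: np.zeros(n) for ev in
                 ("angina", "cardiac_arrest", "stroke",
                  "diabetes_onset", "other_death")}
        probs["mi"] = np.ones(n)
        s2, _, ev = step_year(state, dm, probs, config,
                              np.random.rand(n), np.random.rand(n))
        assert (s2 == DEAD_CVD).all()
        assert ev["fatal"].all()

    def test_stroke_after_mi_combines(self):
        config = fixed_prob_config(0.5)
        state = np.array([POST_MI], dtype=np.int8)
        dm = np.zeros(1, dtype=bool)
        probs = {ev: np.zeros(1) for ev in
                 ("mi", "angina", "cardiac_arrest",
                  "diabetes_onset", "other_death")}
        probs["stroke"] = np.ones(1)
        s2, _, _ = step_year(state, dm, probs, config,
                             np.array([0.5]), np.array([0.99]))
        assert s2[0] == POST_MI_STROKE


class TestRun:
    def test_zero_risk_person_years(self):
        config = fixed_prob_config(0.0)
        res = run(toy_table(1), observed_none(), no_factors(), config, seed=1)
        assert len(res.ledger) == 0
        assert len(res.panel) == 5
        assert res.panel["weight"].sum() == pytest.approx(4.0)  # 0.5+1+1+1+0.5

    def test_seed_determinism(self, cfg, pop20k):
        small = pop20k.iloc[:2000].reset_index(drop=True)
        scen = Scenario.observed_all(cfg.factors)
        a = run(small, scen, cfg.factors, cfg.sim, seed=3,
                entrant_spec=cfg.population)
        b = run(small, scen, cfg.factors, cfg.sim, seed=3,
                entrant_spec=cfg.population)
        pd.testing.assert_frame_equal(a.ledger, b.ledger)
        pd.testing.assert_frame_equal(a.panel, b.panel)

    def test_first_event_fraction_matches_analytic(self):
        """Constant MI probability 0.1, no deaths: P(>=1 MI in 5 cycles)
        = 1 - 0.9^5."""
        n = 100000
        config = fixed_prob_config(0.1)
        res = run(toy_table(n), observed_none(), no_factors(), config, seed=5)
        mi = res.ledger[res.ledger["event_type"] == "mi"]
        frac = mi["person_id"].nunique() / n
        expected = 1.0 - 0.9**5
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < 3 * se

    def test_conservation_alive_plus_dead(self, cfg, pop20k):
        small = pop20k.iloc[:3000].reset_index(drop=True)
        res = run(small, Scenario.observed_all(cfg.factors), cfg.factors,
                  cfg.sim, seed=2, entrant_spec=cfg.population)
        # every person appears at most once per cycle; cohort accounting:
        # panel(alive at cycle start) + cumulative deaths = all entered
        deaths = res.ledger[res.ledger["fatal"]]
        assert deaths["person_id"].is_unique
        entered_by = res.persons.groupby("entry_year").size().cumsum()
        for cyc in range(cfg.sim.horizon_years):
            alive = (res.panel["cycle_year"] == cyc).sum()
            dead_before = (deaths["cycle_year"] < cyc).sum()
            total_in = entered_by[entered_by.index <= cyc].iloc[-1]
            assert alive + dead_before == total_in

    def test_raising_rr_monotone_under_crn(self, cfg, pop20k):
        """Higher diet RR never yields fewer CHD events (common random
        numbers)."""
        small = pop20k.iloc[:5000].reset_index(drop=True)
        fc = cfg.factors.model_copy(deep=True)
        worse = fc.model_copy(deep=True)
        worse.factor("ssb").rr_per_unit["CHD"] = 2.0
        scen = Scenario.observed_all(fc)
        chd = ("mi", "angina", "cardiac_arrest")
        n_lo = run(small, scen, fc, cfg.sim, seed=4).ledger \
            .query("event_type in @chd").shape[0]
        n_hi = run(small, scen, worse, cfg.sim, seed=4).ledger \
            .query("event_type in @chd").shape[0]
        assert n_hi >= n_lo

    def test_scenario_null_when_already_optimal(self, cfg, pop20k):
        """Closed cohort (no entrants, who would join with fresh
        suboptimal diets): runs coincide exactly when intakes are already
        optimal."""
        small = pop20k.iloc[:2000].reset_index(drop=True)
        from cardiocost.diet import apply_scenario
        optimal_pop = apply_scenario(small, Scenario.optimal_all(cfg.factors),
                                     cfg.factors)
        a = run(optimal_pop, Scenario.observed_all(cfg.factors), cfg.factors,
                cfg.sim, seed=6)
        b = run(optimal_pop, Scenario.optimal_all(cfg.factors), cfg.factors,
                cfg.sim, seed=6)
        pd.testing.assert_frame_equal(a.ledger, b.ledger)
        pd.testing.assert_frame_equal(a.panel, b.panel)

    def test_entrants_grow_population(self, cfg, pop20k):
        small = pop20k.iloc[:2000].reset_index(drop=True)
        res = run(small, Scenario.observed_all(cfg.factors), cfg.factors,
                  cfg.sim, seed=2, entrant_spec=cfg.population)
        per_cycle = res.panel.groupby("cycle_year").size()
        assert per_cycle.iloc[-1] > per_cycle.iloc[0] * 0.99
        entrants = res.persons[res.persons["entry_year"] > 0]
        assert len(entrants) > 0
        assert (entrants.groupby("entry_year").size().diff().dropna() >= 0).all()

    def test_horizon_validation(self, cfg, pop20k):
        with pytest.raises(Exception):
            SimConfig.model_validate({**cfg.sim.model_dump(),
                                      "horizon_years": 0})
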