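"""Shared fixtures: default configs, cached populations, toy cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cardiocost.config import load_config
from cardiocost.diet import FactorConfig
from cardiocost.microsim import SimConfig
from cardiocost.population import generate_population


@pytest.fixture(scope="session")
def cfg():
    return load_config(None)


@pytest.fixture(scope="session")
def pop20k(cfg):
    return generate_population(cfg.population, n=20000, seed=7)


@pytest.fixture(scope="session")
def pop200k(cfg):
    return generate_population(cfg.population, n=200000, seed=7)


def toy_table(n: int, age: float = 55.0, sbp: float = 120.0,
              diabetes: bool = False) -> pd.DataFrame:
    """Homogeneous disease-free cohort with no intake columns."""
    return pd.DataFrame({
        "person_id": np.arange(n, dtype=np.int64),
        "sex": "female",
        "age": age,
        "race": "white",
        "education": "HS",
        "insurance": "private",
        "bmi": 25.0,
        "sbp": sbp,
        "total_chol": 200.0,
        "hdl": 50.0,
        "smoker": False,
        "diabetes": diabetes,
        "htn_treated": False,
        "history_angina": False,
        "history_mi": False,
        "history_stroke": False,
        "sample_weight": 1.0,
    })


def fixed_prob_config(
    p_cvd: float,
    q_other: float = 0.0,
    mi_fatality: float = 0.0,
    horizon: int = 5,
    half_cycle: bool = True,
    discount: float = 0.0,
) -> SimConfig:
    """Sim config yielding a constant annual MI probability ``p_cvd`` for
    every alive person (all CVD risk routed to MI, no drift, no entrants,
    negligible diabetes onset, constant background mortality)."""
    from scipy.special import logit

    return SimConfig(
        horizon_years=horizon,
        discount_rate=discount,
        growth_rate=0.0,
        half_cycle=half_cycle,
        entrant_fraction=0.0,
        risk_logistic=dict(intercept=float(logit(p_cvd)), age=0.0, male=0.0,
                           sbp=0.0, total_chol=0.0, hdl=0.0, smoker=0.0,
                           diabetes=0.0),
        chd_share=1.0,
        chd_split={"mi": 1.0, "angina": 0.0, "cardiac_arrest": 0.0},
        case_fatality={"mi": mi_fatality, "angina": 0.0,
                       "cardiac_arrest": 0.0, "stroke": 0.0},
        post_event_hazard_multiplier=1.0,
        diabetes_logistic=dict(intercept=-50.0, age=0.0, bmi=0.0),
        background_mortality=dict(rate_at_35=q_other, log_slope=0.0),
        drift={},
        htn_treatment=dict(sbp_threshold=1e9, annual_start_prob=0.0),
    )


def no_factors() -> FactorConfig:
    return FactorConfig(factors=[])
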