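"""Dietary-factor definitions, intake gaps, and disease relative risks.

Each of the ten dietary factors carries an optimal intake level, a
direction (protective factors harm at a deficit, harmful factors at an
excess), and per-unit relative risks for the diseases it causally affects
(CHD, stroke, type 2 diabetes).  The dose-response is log-linear in the
intake gap — the standard comparative-risk-assessment form — so a gap of
``g`` in a factor with per-unit RR ``r`` and reference unit size ``u``
contributes ``exp(a(age) * ln(r) * g / u)`` to a person's disease risk,
where ``a(age)`` is a piecewise-constant age attenuation on the log scale.
Factor RRs combine multiplicatively across factors; no extra benefit is
modeled beyond the optimal level (the gap is floored at zero).

Sodium may alternatively be routed through systolic blood pressure
(``mode: bp``): its excess then raises SBP inside the risk equation rather
than multiplying hazards directly, which also ties it to antihypertensive
drug costs.
"""

from __future__ import annotations

import importlib.resources
from typing import Literal, Optional, Union

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "DietFactorDef",
    "FactorConfig",
    "Scenario",
    "intake_gap",
    "relative_risk",
    "combined_rr",
    "apply_scenario",
    "draw_rr_set",
    "age_attenuation",
    "population_rr",
    "load_default_factors",
]

DISEASES = ("CHD", "stroke", "diabetes")


class DietFactorDef(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str
    unit: str
    #: intake amount corresponding to one application of ``rr_per_unit``
    unit_size: float = Field(gt=0.0)
    direction: Literal["protective", "harmful"]
    optimal: float = Field(ge=0.0)
    #: RR per unit-size of gap, oriented as risk at deficit/excess vs optimal
    rr_per_unit: dict[str, float]
    rr_log_se: dict[str, float] = Field(default_factory=dict)
    #: "direct" multiplies disease hazards; "bp" routes through SBP
    mode: Literal["direct", "bp"] = "direct"
    bp_mmhg_per_gram: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "DietFactorDef":
        for dz, rr in self.rr_per_unit.items():
            if dz not in DISEASES:
                raise ValueError(f"{self.name}: unknown disease {dz!r}")
            if rr <= 0.0:
                raise ValueError(f"{self.name}: rr_per_unit[{dz}] must be > 0")
            if rr < 1.0:
                raise ValueError(
                    f"{self.name}: rr_per_unit[{dz}] = {rr} < 1; orient RRs as "
                    "risk at deficit/excess relative to optimal"
                )
        for dz, se in self.rr_log_se.items():
            if se < 0.0:
                raise ValueError(f"{self.name}: rr_log_se[{dz}] must be >= 0")
        if self.mode == "bp" and self.bp_mmhg_per_gram is None:
            raise ValueError(f"{self.name}: mode 'bp' requires bp_mmhg_per_gram")
        return self


class FactorConfig(BaseModel):
    """The full dietary-factor configuration (factor list + shared knobs)."""

    model_config = ConfigDict(extra="forbid")

    factors: list[DietFactorDef]
    #: (age lo, age hi, multiplier on log-RR) bands, multipliers in [0, 1]
    age_attenuation: list[tuple[float, float, float]] = Field(
        default_factory=lambda: [(35.0, 121.0, 1.0)]
    )
    rr_cap: float = Field(default=10.0, gt=1.0)
    #: intakes truncated at this population quantile before gap computation
    intake_cap_quantile: float = Field(default=0.99, gt=0.0, le=1.0)

    @model_validator(mode="after")
    def _check(self) -> "FactorConfig":
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ValueError("duplicate factor names")
        for lo, hi, m in self.age_attenuation:
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"age attenuation multiplier {m} outside [0, 1]")
            if hi <= lo:
                raise ValueError(f"empty age band ({lo}, {hi})")
        return self

    def factor(self, name: str) -> DietFactorDef:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(f"unknown factor {name!r}")


def load_default_factors() -> FactorConfig:
    """Bundled default factor configuration (synthetic placeholder RRs)."""
    ref = importlib.resources.files("cardiocost.data") / "factors.yaml"
    return FactorConfig.model_validate(yaml.safe_load(ref.read_text()))


class Scenario(BaseModel):
    """A diet counterfactual: one intake transform per factor.

    Transforms are ``"observed"`` (identity), ``"optimal"`` (move intakes
    worse than optimal to the optimal level, leave better-than-optimal
    unchanged) or ``{"fixed": value}``.
    """

    model_config = ConfigDict(extra="forbid")

    name: str
    transforms: dict[str, Union[Literal["observed", "optimal"], dict[str, float]]]

    @model_validator(mode="after")
    def _check(self) -> "Scenario":
        for fname, t in self.transforms.items():
            if isinstance(t, dict):
                if set(t) != {"fixed"} or t["fixed"] < 0:
                    raise ValueError(
                        f"{fname}: fixed transform must be {{'fixed': value >= 0}}"
                    )
        return self

    @classmethod
    def observed_all(cls, factors: FactorConfig) -> "Scenario":
        return cls(name="observed",
                   transforms={f.name: "observed" for f in factors.factors})

    @classmethod
    def optimal_all(cls, factors: FactorConfig) -> "Scenario":
        return cls(name="optimal_all",
                   transforms={f.name: "optimal" for f in factors.factors})

    @classmethod
    def single_optimal(cls, factors: FactorConfig, name: str) -> "Scenario":
        """Only ``name`` moved to optimal; all other factors observed."""
        factors.factor(name)  # raises on unknown name
        t = {f.name: ("optimal" if f.name == name else "observed")
             for f in factors.factors}
        return cls(name=f"optimal_{name}", transforms=t)


# --------------------------------------------------------------------------


def intake_gap(intake, factor: DietFactorDef, cap: float | None = None):
    """Distance from optimal in the factor's harmful direction (>= 0).

    Protective: ``max(0, optimal - intake)``; harmful:
    ``max(0, intake - optimal)``.  ``cap`` truncates extreme intakes before
    the gap is taken (used with the configured population quantile to bound
    extreme relative risks).  Accepts scalars or arrays.
    """
    intake = np.asarray(intake, dtype=float)
    if (intake < 0).any():
        raise ValueError("negative intake")
    if cap is not None:
        intake = np.minimum(intake, cap)
    if factor.direction == "protective":
        gap = np.maximum(0.0, factor.optimal - intake)
    else:
        gap = np.maximum(0.0, intake - factor.optimal)
    return float(gap) if gap.ndim == 0 else gap


def age_attenuation(age, bands: list[tuple[float, float, float]]):
    """Log-RR multiplier for each age, piecewise constant over bands.

    Ages outside all bands use the nearest band's multiplier.
    """
    age = np.asarray(age, dtype=float)
    out = np.full(age.shape, np.nan)
    for lo, hi, m in bands:
        out[(age >= lo) & (age < hi)] = m
    lo0 = min(b[0] for b in bands)
    hi0 = max(b[1] for b in bands)
    out[age < lo0] = next(b[2] for b in bands if b[0] == lo0)
    out[age >= hi0] = next(b[2] for b in bands if b[1] == hi0)
    return float(out) if out.ndim == 0 else out


def relative_risk(
    gap,
    factor: DietFactorDef,
    disease: str,
    age,
    bands: list[tuple[float, float, float]] | None = None,
    rr_cap: float = 10.0,
):
    """RR for one factor-disease pair at an intake gap.

    ``exp(a(age) * ln(rr_unit) * gap / unit_size)``, capped at ``rr_cap``.
    A disease the factor has no configured link to returns 1.
    """
    gap = np.asarray(gap, dtype=float)
    if (gap < 0).any():
        raise ValueError("gap must be >= 0")
    if disease not in DISEASES:
        raise ValueError(f"unknown disease {disease!r}")
    if disease not in factor.rr_per_unit or factor.mode == "bp":
        ones = np.ones_like(gap)
        return float(ones) if ones.ndim == 0 else ones
    a = age_attenuation(age, bands) if bands is not None else 1.0
    log_rr = a * np.log(factor.rr_per_unit[disease]) * gap / factor.unit_size
    rr = np.minimum(np.exp(log_rr), rr_cap)
    return float(rr) if rr.ndim == 0 else rr


def combined_rr(
    intakes: dict[str, float],
    factors: FactorConfig,
    disease: str,
    age: float,
) -> float:
    """Product of per-factor RRs for one person's intake map."""
    if not factors.factors:
        raise ValueError("factor list is empty")
    rr = 1.0
    for f in factors.factors:
        gap = intake_gap(intakes[f.name], f)
        rr *= relative_risk(gap, f, disease, age,
                            bands=factors.age_attenuation, rr_cap=factors.rr_cap)
    return float(min(rr, factors.rr_cap ** len(factors.factors)))


def population_rr(
    table: pd.DataFrame,
    factors: FactorConfig,
    disease: str,
    ages: np.ndarray | None = None,
    caps: dict[str, float] | None = None,
) -> np.ndarray:
    """Vectorized combined RR per person for one disease.

    ``ages`` overrides the table's age column (the microsimulation passes
    current ages as people grow older); ``caps`` holds per-factor intake
    truncation levels.
    """
    ages = np.asarray(table["age"], dtype=float) if ages is None else ages
    atten = age_attenuation(ages, factors.age_attenuation)
    log_rr = np.zeros(len(table))
    for f in factors.factors:
        if disease not in f.rr_per_unit or f.mode == "bp":
            continue
        cap = caps.get(f.name) if caps else None
        gap = intake_gap(np.asarray(table[f"intake_{f.name}"]), f, cap=cap)
        log_rr += np.minimum(
            atten * np.log(f.rr_per_unit[disease]) * gap / f.unit_size,
            np.log(factors.rr_cap),
        )
    return np.exp(log_rr)


def apply_scenario(table: pd.DataFrame, scenario: Scenario,
                   factors: FactorConfig) -> pd.DataFrame:
    """Return a copy of the table with intakes transformed per scenario.

    The optimal transform only moves individuals *worse* than optimal to
    the optimal level; better-than-optimal intakes are preserved.
    """
    out = table.copy()
    for fname, t in scenario.transforms.items():
        f = factors.factor(fname)
        col = f"intake_{fname}"
        if col not in out.columns:
            raise KeyError(f"table has no intake column for factor {fname!r}")
        if t == "observed":
            continue
        x = np.asarray(out[col], dtype=float)
        if t == "optimal":
            if f.direction == "protective":
                out[col] = np.maximum(x, f.optimal)
            else:
                out[col] = np.minimum(x, f.optimal)
        else:  # fixed
            out[col] = float(t["fixed"])
    return out


def draw_rr_set(factors: FactorConfig, seed: int) -> FactorConfig:
    """One Monte-Carlo draw of the factor RRs.

    Each per-unit RR is replaced by ``exp(N(ln rr, se^2))`` using the
    factor's ``rr_log_se``; an SE of zero returns the point estimate.
    Deterministic in ``seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 424242]))
    new_factors = []
    for f in factors.factors:
        rrs = {}
        for dz, rr in f.rr_per_unit.items():
            if dz not in f.rr_log_se:
                raise ValueError(f"{f.name}: rr_log_se missing for {dz}")
            se = f.rr_log_se[dz]
            drawn = float(np.exp(rng.normal(np.log(rr), se))) if se > 0 else rr
            # keep the spec orientation (risk at a gap never below 1)
            rrs[dz] = max(drawn, 1.0)
        new_factors.append(f.model_copy(update={"rr_per_unit": rrs}))
    return factors.model_copy(update={"factors": new_factors})
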