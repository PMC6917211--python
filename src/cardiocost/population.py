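"""Synthetic NHANES-like adult population generator.

Builds person tables with the marginal structure the cost analysis assumes:
demographic category shares, cardiometabolic risk-factor moments, disease-
history prevalences, and right-skewed daily intakes of the ten dietary
factors.  Three intake families are supported:

``side_mixture_gamma``
    A gamma base distribution split at the factor's optimal level; the two
    truncated sides are remixed so that the fraction on the at-or-better-
    than-optimal side equals ``optimal_mass`` exactly, while the gamma shape
    and scale are calibrated so the mixture reproduces the published mean
    and SD.  Used for every factor with a nonzero optimal level.

``zero_inflated_gamma``
    A point mass at zero intake plus a gamma for consumers.  For harmful
    factors whose optimal level is "no intake" the zero mass *is* the
    optimal fraction.

``truncated_normal``
    A normal truncated to a physical range (used for PUFA % energy, bounded
    to [0, 100]).

All randomness flows from a single integer seed through named column
streams, so identical ``(spec, n, seed)`` calls give identical tables.
"""

from __future__ import annotations

import hashlib
import math
from functools import lru_cache
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator
from scipy import optimize, stats

__all__ = [
    "PopulationSpec",
    "generate_population",
    "resample_weighted",
    "make_entrant_cohort",
    "entrant_size",
    "summarize",
]

# Fixed, documented person-table column order (intake columns appended after).
PERSON_COLUMNS = [
    "person_id",
    "sex",
    "age",
    "race",
    "education",
    "insurance",
    "bmi",
    "sbp",
    "total_chol",
    "hdl",
    "smoker",
    "diabetes",
    "htn_treated",
    "history_angina",
    "history_mi",
    "history_stroke",
    "sample_weight",
]

SEXES = ("male", "female")
RACES = ("white", "black", "hispanic", "other")
EDUCATIONS = ("<HS", "HS", "college")
INSURANCES = ("private", "medicare", "medicaid", "dual", "other_gov", "none")


class ContinuousSpec(BaseModel):
    """Marginal spec for one continuous variable (truncated normal)."""

    model_config = ConfigDict(extra="forbid")

    mean: float
    sd: float = Field(ge=0.0)
    lo: float = -math.inf
    hi: float = math.inf


class IntakeSpec(BaseModel):
    """Marginal spec for one dietary factor's daily intake."""

    model_config = ConfigDict(extra="forbid")

    family: Literal["side_mixture_gamma", "zero_inflated_gamma", "truncated_normal"]
    mean: float = Field(gt=0.0)
    sd: float = Field(ge=0.0)
    optimal: float = Field(ge=0.0)
    direction: Literal["protective", "harmful"]
    #: target fraction at-or-better-than optimal (point mass at 0 for
    #: zero-optimal harmful factors); None leaves the tail uncalibrated
    optimal_mass: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    lo: float = 0.0
    hi: float = math.inf

    @model_validator(mode="after")
    def _check(self) -> "IntakeSpec":
        if self.family == "zero_inflated_gamma":
            if self.optimal != 0.0 or self.direction != "harmful":
                raise ValueError(
                    "zero_inflated_gamma is for harmful factors with optimal = 0"
                )
            if self.optimal_mass is None:
                raise ValueError("zero_inflated_gamma requires optimal_mass (zero mass)")
        return self


def _probs_sum_to_one(d: dict[str, float], name: str) -> None:
    tot = sum(d.values())
    if abs(tot - 1.0) > 1e-9:
        raise ValueError(f"{name} category probabilities sum to {tot}, not 1")
    for k, v in d.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}[{k}] = {v} outside [0, 1]")


class PopulationSpec(BaseModel):
    """Full marginal specification of the synthetic adult population."""

    model_config = ConfigDict(extra="forbid")

    #: (low age, high age, share) bands; ages uniform within band
    age_bands: list[tuple[float, float, float]]
    female_share: float = Field(ge=0.0, le=1.0)
    race: dict[str, float]
    education: dict[str, float]
    insurance: dict[str, float]
    continuous: dict[str, ContinuousSpec]
    prevalence: dict[str, float]
    intakes: dict[str, IntakeSpec]
    #: gamma shape for sampling weights (mean fixed at 1); None => all 1.0
    weight_gamma_shape: Optional[float] = Field(default=4.0, gt=0.0)
    n: int = Field(default=0, ge=0)
    seed: int = 0

    @field_validator("age_bands")
    @classmethod
    def _bands(cls, v):
        tot = sum(b[2] for b in v)
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"age band shares sum to {tot}, not 1")
        for lo, hi, share in v:
            if not (0.0 <= share <= 1.0) or hi < lo:
                raise ValueError(f"invalid age band ({lo}, {hi}, {share})")
        return v

    @model_validator(mode="after")
    def _cats(self) -> "PopulationSpec":
        _probs_sum_to_one(self.race, "race")
        _probs_sum_to_one(self.education, "education")
        _probs_sum_to_one(self.insurance, "insurance")
        for k, v in self.prevalence.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"prevalence[{k}] = {v} outside [0, 1]")
        for name in ("bmi", "sbp", "total_chol", "hdl"):
            if name not in self.continuous:
                raise ValueError(f"continuous spec missing required variable {name!r}")
        return self


# --------------------------------------------------------------------------
# intake-distribution calibration


@lru_cache(maxsize=128)
def _fit_side_mixture(
    mean: float, sd: float, threshold: float, mass: float, protective: bool
) -> tuple[float, float]:
    """Gamma (shape, scale) whose side mixture at ``threshold`` with optimal
    mass ``mass`` reproduces ``mean`` and ``sd``.

    The mixture draws the at-or-better side of the base gamma with
    probability ``mass`` and the suboptimal side otherwise, so the optimal
    fraction is exact by construction; the two gamma parameters are then
    free to match the first two moments.
    """

    def moments(k: float, th: float) -> tuple[float, float]:
        g1 = stats.gamma(k + 1.0, scale=th)
        g2 = stats.gamma(k + 2.0, scale=th)
        F = stats.gamma.cdf(threshold, k, scale=th)
        ex_low = k * th * g1.cdf(threshold)
        ex2_low = k * (k + 1.0) * th * th * g2.cdf(threshold)
        ex, ex2 = k * th, k * (k + 1.0) * th * th
        if protective:  # optimal side is the upper tail
            w_low, w_high = 1.0 - mass, mass
        else:
            w_low, w_high = mass, 1.0 - mass
        m1 = w_low * ex_low / F + w_high * (ex - ex_low) / (1.0 - F)
        m2 = w_low * ex2_low / F + w_high * (ex2 - ex2_low) / (1.0 - F)
        return m1, m2 - m1 * m1

    def eqs(x: np.ndarray) -> list[float]:
        k, th = np.exp(x)
        m1, v = moments(k, th)
        return [m1 / mean - 1.0, math.sqrt(max(v, 1e-300)) / sd - 1.0]

    x0 = np.log([(mean / sd) ** 2, sd * sd / mean])
    x, info, ier, msg = optimize.fsolve(eqs, x0, full_output=True)
    if ier != 1 or max(abs(r) for r in eqs(x)) > 1e-6:
        raise ValueError(
            f"side-mixture gamma calibration failed for mean={mean}, sd={sd}, "
            f"threshold={threshold}, mass={mass}: {msg}"
        )
    k, th = np.exp(x)
    return float(k), float(th)


@lru_cache(maxsize=128)
def _fit_truncnorm(
    mean: float, sd: float, lo: float, hi: float
) -> tuple[float, float]:
    """(loc, scale) of a normal whose truncation to [lo, hi] has the target
    mean and SD (the naive loc/scale are biased when a bound is near)."""
    if not (lo < mean < hi):
        raise ValueError(f"target mean {mean} outside truncation range ({lo}, {hi})")

    def eqs(x: np.ndarray) -> list[float]:
        loc, scale = x[0], math.exp(x[1])
        a, b = (lo - loc) / scale, (hi - loc) / scale
        m, v = stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return [(m - mean) / sd, math.sqrt(v) / sd - 1.0]

    x, info, ier, msg = optimize.fsolve(eqs, [mean, math.log(sd)], full_output=True)
    if ier != 1 or max(abs(r) for r in eqs(x)) > 1e-8:
        raise ValueError(f"truncated-normal calibration failed for mean={mean}: {msg}")
    return float(x[0]), float(math.exp(x[1]))


def _truncnorm_ppf(
    u: np.ndarray, mean: float, sd: float, lo: float, hi: float
) -> np.ndarray:
    if sd == 0.0:
        return np.full(len(u), mean)
    loc, scale = _fit_truncnorm(mean, sd, lo, hi)
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return stats.truncnorm.ppf(u, a, b, loc=loc, scale=scale)


def _fit_zero_inflated(mean: float, sd: float, zero_mass: float) -> tuple[float, float]:
    """Gamma (shape, scale) of the consumer part of a zero-inflated gamma."""
    p0 = zero_mass
    if p0 >= 1.0:
        raise ValueError("zero mass must be < 1")
    mu = mean / (1.0 - p0)
    var = (sd * sd + mean * mean) / (1.0 - p0) - mu * mu
    if var <= 0.0:
        raise ValueError(
            f"zero mass {p0} incompatible with mean {mean}, sd {sd} "
            "(consumer variance would be negative)"
        )
    return mu * mu / var, var / mu


def _sample_intake(spec: IntakeSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    if spec.family == "truncated_normal":
        return _truncnorm_ppf(rng.random(n), spec.mean, spec.sd, spec.lo, spec.hi)
    if spec.family == "zero_inflated_gamma":
        k, th = _fit_zero_inflated(spec.mean, spec.sd, spec.optimal_mass)
        x = np.zeros(n)
        consumer = rng.random(n) >= spec.optimal_mass
        x[consumer] = rng.gamma(k, th, size=int(consumer.sum()))
        return x
    # side_mixture_gamma
    if spec.optimal_mass is None:
        k = (spec.mean / spec.sd) ** 2
        th = spec.sd * spec.sd / spec.mean
        return rng.gamma(k, th, size=n)
    protective = spec.direction == "protective"
    k, th = _fit_side_mixture(
        spec.mean, spec.sd, spec.optimal, spec.optimal_mass, protective
    )
    F = stats.gamma.cdf(spec.optimal, k, scale=th)
    on_optimal_side = rng.random(n) < spec.optimal_mass
    u = rng.random(n)
    # map uniforms into the CDF interval of the chosen side, then invert
    if protective:
        q = np.where(on_optimal_side, F + (1.0 - F) * u, F * u)
    else:
        q = np.where(on_optimal_side, F * u, F + (1.0 - F) * u)
    return stats.gamma.ppf(q, k, scale=th)


# --------------------------------------------------------------------------
# generation


def _stream(seed: int, name: str) -> np.random.Generator:
    """Named column stream derived from the master seed."""
    digest = hashlib.sha256(name.encode()).digest()
    tag = int.from_bytes(digest[:4], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


def _categorical(
    rng: np.random.Generator, cats: list[str], probs: list[float], n: int
) -> np.ndarray:
    edges = np.cumsum(probs)
    idx = np.searchsorted(edges, rng.random(n), side="right")
    idx = np.minimum(idx, len(cats) - 1)
    return np.asarray(cats, dtype=object)[idx]


def generate_population(
    spec: PopulationSpec, n: int | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Generate ``n`` synthetic persons from the marginal spec.

    Deterministic: identical ``(spec, n, seed)`` produce identical tables.
    """
    n = spec.n if n is None else int(n)
    seed = spec.seed if seed is None else int(seed)
    if n < 0:
        raise ValueError("n must be nonnegative")

    intake_cols = [f"intake_{f}" for f in spec.intakes]
    if n == 0:
        return pd.DataFrame(columns=PERSON_COLUMNS + intake_cols)

    out: dict[str, np.ndarray] = {}
    out["person_id"] = np.arange(n, dtype=np.int64)

    rng = _stream(seed, "age")
    shares = [b[2] for b in spec.age_bands]
    band = _categorical(rng, list(range(len(spec.age_bands))), shares, n)
    lo = np.array([spec.age_bands[i][0] for i in band.astype(int)])
    hi = np.array([spec.age_bands[i][1] for i in band.astype(int)])
    out["age"] = lo + rng.random(n) * (hi - lo)

    rng = _stream(seed, "sex")
    out["sex"] = np.where(rng.random(n) < spec.female_share, "female", "male").astype(object)
    for var, cats in (("race", spec.race), ("education", spec.education),
                      ("insurance", spec.insurance)):
        rng = _stream(seed, var)
        out[var] = _categorical(rng, list(cats.keys()), list(cats.values()), n)

    for var, cs in spec.continuous.items():
        rng = _stream(seed, f"cont_{var}")
        out[var] = _truncnorm_ppf(rng.random(n), cs.mean, cs.sd, cs.lo, cs.hi)

    flag_map = {
        "smoker": "smoker",
        "diabetes": "diabetes",
        "htn_treated": "htn_treated",
        "angina": "history_angina",
        "mi": "history_mi",
        "stroke": "history_stroke",
    }
    for key, col in flag_map.items():
        rng = _stream(seed, f"prev_{key}")
        out[col] = rng.random(n) < spec.prevalence.get(key, 0.0)

    rng = _stream(seed, "weight")
    if spec.weight_gamma_shape is None:
        out["sample_weight"] = np.ones(n)
    else:
        k = spec.weight_gamma_shape
        out["sample_weight"] = rng.gamma(k, 1.0 / k, size=n)

    for factor, ispec in spec.intakes.items():
        rng = _stream(seed, f"intake_{factor}")
        out[f"intake_{factor}"] = _sample_intake(ispec, n, rng)

    return pd.DataFrame(out, columns=PERSON_COLUMNS + intake_cols)


def resample_weighted(table: pd.DataFrame, n: int, seed: int) -> pd.DataFrame:
    """Draw ``n`` rows with replacement, probability ∝ ``sample_weight``.

    Output weights are reset to 1 and person ids reassigned 0..n-1.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    w = np.asarray(table["sample_weight"], dtype=float)
    if (w < 0).any():
        raise ValueError("negative sample_weight")
    tot = w.sum()
    if len(table) == 0 or tot <= 0:
        raise ValueError("resampling requires at least one positive weight")
    rng = _stream(seed, "resample")
    idx = rng.choice(len(table), size=n, replace=True, p=w / tot)
    out = table.iloc[idx].reset_index(drop=True)
    out["person_id"] = np.arange(n, dtype=np.int64)
    out["sample_weight"] = 1.0
    return out


def entrant_size(base: int, growth_rate: float, year: int) -> int:
    """Entrant cohort size in simulation year ``year`` (year 1 = first
    entrants), growing from ``base`` at ``growth_rate`` per year, rounded
    half-up."""
    if base < 0:
        raise ValueError("base size must be nonnegative")
    return int(math.floor(base * (1.0 + growth_rate) ** year + 0.5))


def make_entrant_cohort(spec35: PopulationSpec, size: int, seed: int) -> pd.DataFrame:
    """Cohort of ``size`` 35-year-old entrants drawn from the entrant spec."""
    if size < 0:
        raise ValueError("entrant cohort size must be nonnegative")
    table = generate_population(spec35, n=size, seed=seed)
    if size:
        table["age"] = 35.0
        # entrants join disease-free
        for col in ("history_angina", "history_mi", "history_stroke"):
            table[col] = False
    return table


def summarize(table: pd.DataFrame, spec: PopulationSpec | None = None) -> dict:
    """Per-variable summary statistics of a person table.

    Returns a dict with ``continuous`` (mean/sd per numeric risk factor),
    ``shares`` (category shares per categorical variable), ``prevalence``
    (mean of each boolean flag), and ``intakes`` (mean/sd and, when a spec
    is supplied, the fraction at-or-better-than the optimal level).
    """
    if len(table) == 0:
        raise ValueError("cannot summarize an empty table")
    out: dict = {"n": int(len(table)), "continuous": {}, "shares": {},
                 "prevalence": {}, "intakes": {}}
    for var in ("age", "bmi", "sbp", "total_chol", "hdl"):
        x = np.asarray(table[var], dtype=float)
        out["continuous"][var] = {"mean": float(x.mean()), "sd": float(x.std(ddof=0))}
    for var in ("sex", "race", "education", "insurance"):
        shares = table[var].value_counts(normalize=True).to_dict()
        out["shares"][var] = {str(k): float(v) for k, v in shares.items()}
    for col in ("smoker", "diabetes", "htn_treated",
                "history_angina", "history_mi", "history_stroke"):
        out["prevalence"][col] = float(np.asarray(table[col]).mean())
    for col in table.columns:
        if not col.startswith("intake_"):
            continue
        factor = col[len("intake_"):]
        x = np.asarray(table[col], dtype=float)
        entry = {"mean": float(x.mean()), "sd": float(x.std(ddof=0))}
        if spec is not None and factor in spec.intakes:
            ispec = spec.intakes[factor]
            if ispec.direction == "protective":
                entry["optimal_share"] = float((x >= ispec.optimal).mean())
            else:
                entry["optimal_share"] = float((x <= ispec.optimal).mean())
        out["intakes"][factor] = entry
    return out
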