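"""Configuration loading and validation.

All configs are YAML; schemas are pydantic models with unknown keys
rejected.  Anything not supplied falls back to the bundled defaults under
``cardiocost/data/`` (synthetic placeholders where the real analysis
inputs are study-supplied: relative risks, unit costs, payer mix).
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from cardiocost.attribution import PayerMix
from cardiocost.costs import CostParameters
from cardiocost.diet import FactorConfig
from cardiocost.microsim import SimConfig
from cardiocost.population import PopulationSpec

__all__ = ["PipelineConfig", "load_config", "load_defaults", "config_hash"]


def _data_yaml(name: str) -> dict:
    ref = importlib.resources.files("cardiocost.data") / name
    return yaml.safe_load(ref.read_text())


def load_defaults() -> dict:
    """The bundled default config blocks as plain dicts."""
    return {
        "population": _data_yaml("population.yaml"),
        "factors": _data_yaml("factors.yaml"),
        "sim": _data_yaml("sim.yaml"),
        "costs": _data_yaml("costs.yaml"),
        "payer_mix": _data_yaml("payer_mix.yaml"),
    }


class PipelineConfig(BaseModel):
    """End-to-end pipeline configuration."""

    model_config = ConfigDict(extra="forbid", arbitrary_types_allowed=True)

    n: int = Field(default=20000, gt=0)
    seed: int = 7
    #: Monte-Carlo RR redraws for 95% CIs (0 disables)
    ci_draws: int = Field(default=0, ge=0)
    #: US adults aged 35-85, for national scaling
    national_population: float = Field(default=167.4e6, gt=0)
    #: annual direct CVD+diabetes cost (billions USD) the attributable
    #: share is expressed against
    total_direct_cost_billion: float = Field(default=276.3, gt=0)
    population: PopulationSpec
    factors: FactorConfig
    sim: SimConfig
    costs: CostParameters
    payer_mix: PayerMix


def _deep_merge(base: dict, override: dict) -> dict:
    """User config values win over bundled defaults, recursively."""
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a pipeline config, filling unspecified blocks with defaults.

    ``path`` may be None (pure defaults).  Scalar overrides (n, seed, ...)
    can be passed as keyword arguments and win over the file.
    """
    blocks = load_defaults()
    user: dict = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(str(p))
        user = yaml.safe_load(p.read_text()) or {}
        if not isinstance(user, dict):
            raise ValueError(f"{p}: top level must be a mapping")
    merged: dict = {}
    for key in ("population", "factors", "sim", "costs", "payer_mix"):
        merged[key] = _deep_merge(blocks[key], user.pop(key, {}))
    merged.update(user)
    merged.update({k: v for k, v in overrides.items() if v is not None})
    try:
        return PipelineConfig.model_validate(merged)
    except ValidationError as e:
        first = e.errors()[0]
        loc = ".".join(str(x) for x in first["loc"])
        raise ValueError(f"invalid config: {loc}: {first['msg']}") from e


def config_hash(config: PipelineConfig) -> str:
    """Stable sha256 of the full resolved configuration."""
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()
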