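"""YAML/JSON configuration for a full pipeline run.

A config file is a mapping with optional sections — ``economics``,
``forage``, ``ramp`` (list of per-year fractions starting at year 0),
``survey`` (population marginals), ``montecarlo`` (iterations,
distribution, bounds) and ``scenarios`` (list of ``{kind, n}``
entries).  Omitted sections and keys fall back to the study defaults,
so an empty file reproduces the printed 18-scenario roster.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cashflow import EconomicParams, YieldRamp
from .forage import ForageParams
from .montecarlo import DEFAULT_ITERATIONS, BoundsConfig
from .scenarios import ScenarioSpec, make_scenario, printed_scenarios
from .survey import PopulationParams

__all__ = ["RunConfig", "load_config", "config_digest"]


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs, resolved to concrete objects."""

    econ: EconomicParams = field(default_factory=EconomicParams)
    forage: ForageParams = field(default_factory=ForageParams)
    ramp: YieldRamp = field(default_factory=YieldRamp)
    bounds: BoundsConfig = field(default_factory=BoundsConfig)
    population: PopulationParams = field(default_factory=PopulationParams)
    scenarios: tuple[ScenarioSpec, ...] = field(
        default_factory=lambda: tuple(printed_scenarios())
    )
    n_iterations: int = DEFAULT_ITERATIONS
    distribution: str = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be at least 1")
        if self.ramp.horizon < 1:
            raise ValueError("horizon must be at least 1 year")


def _replace_from(obj, section: dict, label: str):
    """dataclasses.replace(obj, **section), rejecting unknown keys by name."""
    known = {f.name for f in dataclasses.fields(obj)}
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown {label} parameter(s): {sorted(unknown)}")
    return dataclasses.replace(obj, **section)


def load_config(path: str | Path | None = None, seed: int | None = None) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML/JSON file (or pure defaults)."""
    data: dict = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"config file not found: {p}")
        text = p.read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config root must be a mapping, got {type(data).__name__}")

    econ = _replace_from(EconomicParams(), data.get("economics", {}), "economics")
    forage_section = dict(data.get("forage", {}))
    if "maturation_factor_by_year" in forage_section:
        forage_section["maturation_factor_by_year"] = tuple(
            forage_section["maturation_factor_by_year"]
        )
    forage = _replace_from(ForageParams(), forage_section, "forage")
    ramp = YieldRamp(tuple(data["ramp"])) if "ramp" in data else YieldRamp()
    bounds = _replace_from(BoundsConfig(), data.get("montecarlo", {}).get("bounds", {}),
                           "montecarlo bounds")
    population = (
        PopulationParams.from_dict(data["survey"]) if "survey" in data else PopulationParams()
    )
    if "scenarios" in data:
        scenarios = tuple(
            make_scenario(entry["kind"], int(entry.get("n", 0)), entry.get("name"))
            for entry in data["scenarios"]
        )
    else:
        scenarios = tuple(printed_scenarios())

    mc = data.get("montecarlo", {})
    return RunConfig(
        econ=econ,
        forage=forage,
        ramp=ramp,
        bounds=bounds,
        population=population,
        scenarios=scenarios,
        n_iterations=int(mc.get("iterations", DEFAULT_ITERATIONS)),
        distribution=mc.get("distribution", "uniform"),
        seed=int(seed if seed is not None else data.get("seed", 0)),
    )


def config_digest(config: RunConfig) -> str:
    """Stable SHA-256 digest of a resolved configuration."""

    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: encode(getattr(obj, f.name)) for f in dataclasses.fields(obj)
                    if f.name != "detail"}
        if isinstance(obj, (tuple, list)):
            return [encode(x) for x in obj]
        if isinstance(obj, dict):
            return {str(k): encode(v) for k, v in sorted(obj.items())}
        if hasattr(obj, "to_dict"):
            return obj.to_dict()
        return obj

    canonical = json.dumps(encode(config), sort_keys=True)
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()
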