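"""Stochastic NPV distributions and scenario ranking.

Deterministic cost-benefit analysis assumes static prices and yields;
in practice both fluctuate.  Each scenario's NPV is therefore bracketed
by a [min, max] interval — the cash flow re-evaluated with product
prices and honey yields at pessimistic/optimistic bounds (mean ∓ 1 sd,
floored at zero) — and resampled by drawing

    NPV_i = U_i × (max − min) + min,   U_i ~ Uniform(0, 1)

for 10,000 iterations.  The mean and standard error of the draws
summarise each scenario, and scenarios are ranked by descending mean
NPV.  The bound derivation is a documented modelling choice, not a
reproduction of any published interval, so downstream comparisons
should treat the means as ordinal.  A triangular sampler with the
deterministic NPV as mode is available as an alternative.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cashflow import EconomicParams, YieldRamp, build_cashflow, npv
from .forage import ForageParams
from .scenarios import ScenarioSpec

__all__ = [
    "BoundsConfig",
    "NPVResult",
    "npv_bounds",
    "sample_npv",
    "sample_npv_triangular",
    "summarize",
    "evaluate_scenarios",
    "rank_scenarios",
    "results_to_frame",
]

DEFAULT_ITERATIONS = 10_000


@dataclass(frozen=True)
class BoundsConfig:
    """How far stochastic inputs swing when bracketing the NPV.

    Price sds are the survey-observed unit-price spreads (USD/kg); the
    honey-yield coefficient of variation is the survey honey sd/mean
    (17.80/13.42).  Lower bounds floor at zero.  Explicit
    ``npv_min``/``npv_max`` overrides skip the construction entirely.
    """

    sd_price_honey: float = 1.72
    sd_price_beeswax: float = 1.13
    sd_price_propolis: float = 2.66
    honey_yield_cv: float = 17.80 / 13.42
    npv_min: float | None = None
    npv_max: float | None = None

    def __post_init__(self) -> None:
        for name in ("sd_price_honey", "sd_price_beeswax", "sd_price_propolis",
                     "honey_yield_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class NPVResult:
    """Deterministic and Monte-Carlo NPV summary of one scenario."""

    name: str
    investment_usd: float
    deterministic_npv: float
    npv_min: float
    npv_max: float
    mc_mean: float
    mc_se: float
    n_iterations: int
    seed: int
    rank: int | None = None


def _shifted_inputs(
    spec: ScenarioSpec,
    econ: EconomicParams,
    forage: ForageParams,
    bounds: BoundsConfig,
    direction: int,
) -> tuple[ScenarioSpec, EconomicParams, ForageParams]:
    """Scenario/economy with stochastic inputs at a ∓1-sd bound (direction ±1)."""
    econ_shift = replace(
        econ,
        price_honey=max(0.0, econ.price_honey + direction * bounds.sd_price_honey),
        price_beeswax=max(0.0, econ.price_beeswax + direction * bounds.sd_price_beeswax),
        price_propolis=max(0.0, econ.price_propolis + direction * bounds.sd_price_propolis),
    )
    yscale = max(0.0, 1.0 + direction * bounds.honey_yield_cv)
    spec_shift = replace(spec, yield_model=spec.yield_model.scaled(yscale))
    forage_shift = replace(
        forage, honey_conversion_efficiency=forage.honey_conversion_efficiency * yscale
    )
    return spec_shift, econ_shift, forage_shift


def npv_bounds(
    spec: ScenarioSpec,
    econ: EconomicParams | None = None,
    forage: ForageParams | None = None,
    ramp: YieldRamp | None = None,
    bounds_cfg: BoundsConfig | None = None,
) -> tuple[float, float]:
    """[min, max] NPV of a scenario under pessimistic/optimistic inputs."""
    econ = econ if econ is not None else EconomicParams()
    forage = forage if forage is not None else ForageParams()
    bounds = bounds_cfg if bounds_cfg is not None else BoundsConfig()

    if bounds.npv_min is not None and bounds.npv_max is not None:
        lo, hi = bounds.npv_min, bounds.npv_max
    else:
        lo = npv(build_cashflow(*_shifted_inputs(spec, econ, forage, bounds, -1), ramp=ramp),
                 econ.discount_rate)
        hi = npv(build_cashflow(*_shifted_inputs(spec, econ, forage, bounds, +1), ramp=ramp),
                 econ.discount_rate)
        if bounds.npv_min is not None:
            lo = bounds.npv_min
        if bounds.npv_max is not None:
            hi = bounds.npv_max
    if lo > hi:
        raise ValueError(f"NPV lower bound {lo:.2f} exceeds upper bound {hi:.2f}")
    return float(lo), float(hi)


def sample_npv(npv_min: float, npv_max: float, n: int, seed: int | np.random.Generator) -> np.ndarray:
    """Uniform NPV draws on [min, max]: U × (max − min) + min."""
    if npv_min > npv_max:
        raise ValueError("npv_min must not exceed npv_max")
    if n < 1:
        raise ValueError("need at least one draw")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.random(n) * (npv_max - npv_min) + npv_min


def sample_npv_triangular(
    npv_min: float, mode: float, npv_max: float, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Triangular NPV draws with the deterministic NPV as the mode."""
    if not npv_min <= mode <= npv_max:
        raise ValueError("mode must lie within [npv_min, npv_max]")
    if n < 1:
        raise ValueError("need at least one draw")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if npv_min == npv_max:
        return np.full(n, npv_min)
    return rng.triangular(npv_min, mode, npv_max, size=n)


def summarize(draws: Sequence[float] | np.ndarray) -> tuple[float, float]:
    """(mean, standard error) of a draw vector; SE needs ≥ 2 draws."""
    arr = np.asarray(draws, dtype=float)
    if arr.size < 2:
        raise ValueError("standard error requires at least two draws")
    return float(arr.mean()), float(arr.std(ddof=1) / np.sqrt(arr.size))


def _scenario_seed(base_seed: int, name: str) -> int:
    # stable per-scenario stream: adding a scenario never perturbs others
    return (int(base_seed) * 2_654_435_761 + zlib.crc32(name.encode("utf-8"))) % (2**31)


def evaluate_scenarios(
    specs: Iterable[ScenarioSpec],
    econ: EconomicParams | None = None,
    forage: ForageParams | None = None,
    ramp: YieldRamp | None = None,
    bounds_cfg: BoundsConfig | None = None,
    n_iterations: int = DEFAULT_ITERATIONS,
    seed: int = 0,
    distribution: str = "uniform",
) -> list[NPVResult]:
    """Deterministic NPV, bounds and Monte-Carlo summary for each scenario.

    Draws are consumed per scenario from a stream keyed on (seed,
    scenario name), in name-sorted order, so the roster composition
    never changes another scenario's draws.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be at least 1")
    if distribution not in ("uniform", "triangular"):
        raise ValueError(f"unknown distribution {distribution!r}")
    econ = econ if econ is not None else EconomicParams()
    results = []
    for spec in sorted(specs, key=lambda s: s.name):
        cf = build_cashflow(spec, econ, forage, ramp)
        det = npv(cf, econ.discount_rate)
        lo, hi = npv_bounds(spec, econ, forage, ramp, bounds_cfg)
        sseed = _scenario_seed(seed, spec.name)
        if distribution == "triangular":
            mode = min(max(det, lo), hi)
            draws = sample_npv_triangular(lo, mode, hi, n_iterations, sseed)
        else:
            draws = sample_npv(lo, hi, n_iterations, sseed)
        if n_iterations >= 2:
            mean, se = summarize(draws)
        else:
            mean, se = float(draws[0]), 0.0
        results.append(
            NPVResult(
                name=spec.name,
                investment_usd=cf.investment_usd,
                deterministic_npv=det,
                npv_min=lo,
                npv_max=hi,
                mc_mean=mean,
                mc_se=se,
                n_iterations=n_iterations,
                seed=sseed,
            )
        )
    return results


def rank_scenarios(results: Sequence[NPVResult]) -> list[NPVResult]:
    """Order results by descending Monte-Carlo mean NPV and assign ranks.

    Ties break toward the lower initial investment, then by name, so
    the ordering is total and independent of input order.
    """
    if len(results) == 0:
        raise ValueError("need at least one result to rank")
    ordered = sorted(results, key=lambda r: (-r.mc_mean, r.investment_usd, r.name))
    return [replace(r, rank=i + 1) for i, r in enumerate(ordered)]


def results_to_frame(results: Sequence[NPVResult]) -> pd.DataFrame:
    """Ranking table: scenario, initial investment, rank, mean NPV, SE."""
    return pd.DataFrame(
        [
            {
                "scenario": r.name,
                "initial_investment_usd": r.investment_usd,
                "rank": r.rank,
                "deterministic_npv_usd": r.deterministic_npv,
                "npv_min_usd": r.npv_min,
                "npv_max_usd": r.npv_max,
                "mean_npv_usd": r.mc_mean,
                "se_usd": r.mc_se,
            }
            for r in results
        ]
    )
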