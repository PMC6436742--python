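"""Year-by-year cash flows for apiary scenarios and their discounting.

The engine turns a :class:`~apisim.scenarios.ScenarioSpec` into a
10-year cash flow: a year-0 investment (hives, smoker, bee suit,
storage buckets, apiary siting labour, tree establishment) followed by
annual net flows of product revenue (honey under a colonisation yield
ramp, a forage honey supplement, beeswax, constant propolis) minus
recurrent costs (inspection and harvest labour, lighting, gumboot
amortisation, marketing at a fixed share of revenue, strainer cloths,
tree weeding).  Net present value discounts those flows at an annual
rate, adds any discounted rest value and subtracts the investment::

    NPV = Σ_{t=1..n} (B_t − C_t) / (1+r)^t + R_n / (1+r)^n − A

Hives fully depreciate over the horizon, so the rest value defaults to
zero.  All amounts are USD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forage import ForageParams, forage_costs, honey_supplement_kg, land_required_ha
from .scenarios import (
    ScenarioSpec,
    beeswax_from_honey,
    hive_investment,
    potential_honey_kg,
)

__all__ = [
    "EconomicParams",
    "YieldRamp",
    "CashFlow",
    "yield_fraction",
    "npv",
    "annual_revenue",
    "consumables_requirement",
    "build_cashflow",
]


@dataclass(frozen=True)
class EconomicParams:
    """Prices, unit costs and cost rules of the apiary economy (USD).

    Defaults are 2014 Northern-Uganda market values: the 10 % discount
    rate is a prevailing bank lending rate, and the exchange rate
    (2700 UGX/USD) only matters at the I/O boundary — everything
    internal is USD.
    """

    discount_rate: float = 0.10
    exchange_rate_ugx_per_usd: float = 2700.0
    price_honey: float = 2.61  # USD/kg
    price_beeswax: float = 3.01
    price_propolis: float = 4.00
    cost_log_hive: float = 3.42  # USD/unit
    cost_ktb_hive: float = 36.64
    cost_langstroth_hive: float = 43.24
    cost_smoker: float = 11.44
    cost_bee_suit: float = 46.21
    cost_gumboots: float = 6.24
    cost_bucket: float = 7.84
    cost_strainer_cloth: float = 0.20
    labour_usd_per_day: float = 2.00
    marketing_rate: float = 0.10  # share of revenue
    bucket_capacity_kg: float = 20.0
    strainers_per_batch: int = 2
    strainer_batch_kg: float = 400.0
    gumboot_replacement_years: int = 3
    gumboot_pairs: int = 1
    lighting_baseline_usd: float = 4.0  # torches & batteries, /yr
    lighting_improved_usd: float = 10.0
    inspections_per_year_baseline: int = 6
    inspections_per_year_improved: int = 48  # four times per month
    inspection_cost_usd: float = 2.00  # per visit
    harvest_seasons_per_year: int = 2
    harvest_days_per_season: float = 1.0  # at the 22-hive reference apiary
    harvest_reference_hives: int = 22
    labour_escalation_rate: float = 0.10  # /yr where a scenario escalates

    def __post_init__(self) -> None:
        if self.discount_rate <= -1:
            raise ValueError("discount_rate must exceed -1")
        if not 0.0 <= self.marketing_rate <= 1.0:
            raise ValueError("marketing_rate must lie in [0, 1]")
        for name in (
            "price_honey", "price_beeswax", "price_propolis",
            "cost_log_hive", "cost_ktb_hive", "cost_langstroth_hive",
            "cost_smoker", "cost_bee_suit", "cost_gumboots", "cost_bucket",
            "cost_strainer_cloth", "labour_usd_per_day",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.bucket_capacity_kg <= 0 or self.strainer_batch_kg <= 0:
            raise ValueError("capacities must be positive")
        if self.gumboot_replacement_years <= 0:
            raise ValueError("gumboot_replacement_years must be positive")


DEFAULT_RAMP_FRACTIONS = (0.0, 0.30, 0.45, 0.60, 0.75, 0.90, 0.90, 0.90, 0.90, 0.90, 0.90)


@dataclass(frozen=True)
class YieldRamp:
    """Fraction of potential honey production realised per project year.

    Hive colonisation depends on wild swarms occupying empty hives, so
    output ramps up over the horizon: nothing in year 0, 30 % in the
    first productive year, rising to a 90 % plateau (the tabulated
    default).  A multiplicative variant — 30 % in year 2 compounding by
    15 % of the previous year's yield through year 6, flat through year
    8, then declining 15 %/yr — is available via
    :meth:`compounding`.
    """

    fraction_by_year: tuple[float, ...] = DEFAULT_RAMP_FRACTIONS

    def __post_init__(self) -> None:
        if not self.fraction_by_year:
            raise ValueError("ramp must cover at least year 0")
        if self.fraction_by_year[0] != 0.0:
            raise ValueError("year-0 fraction must be 0 (no production before colonisation)")
        if any(not 0.0 <= f <= 1.0 for f in self.fraction_by_year):
            raise ValueError("ramp fractions must lie in [0, 1]")

    @property
    def horizon(self) -> int:
        return len(self.fraction_by_year) - 1

    @classmethod
    def compounding(cls, horizon: int = 10) -> "YieldRamp":
        """Benefits start in year 2 at 30 %, ×1.15/yr to year 6, flat to
        year 8, ×0.85/yr in years 9-10."""
        fracs = [0.0] * (horizon + 1)
        level = 0.0
        for t in range(1, horizon + 1):
            if t == 2:
                level = 0.30
            elif 3 <= t <= 6:
                level *= 1.15
            elif t >= 9:
                level *= 0.85
            fracs[t] = min(level, 1.0)
        return cls(tuple(fracs))


def yield_fraction(year: int, ramp: YieldRamp | None = None) -> float:
    """Tabulated realised-production fraction for a project year."""
    r = ramp if ramp is not None else YieldRamp()
    if not 0 <= year <= r.horizon:
        raise ValueError(f"year must lie in [0, {r.horizon}]")
    return r.fraction_by_year[year]


@dataclass(frozen=True)
class CashFlow:
    """Year-indexed net monetary flows of one scenario.

    ``net_flow_usd[t-1]`` is B_t − C_t for project year t;
    ``investment_usd`` is the year-0 outlay A; ``rest_value_usd`` is the
    residual asset value R_n at the end of the horizon (zero under full
    depreciation).  ``detail``, when present, is the per-year
    revenue/cost breakdown.
    """

    horizon_years: int
    investment_usd: float
    net_flow_usd: tuple[float, ...]
    rest_value_usd: float = 0.0
    detail: pd.DataFrame | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.net_flow_usd) != self.horizon_years:
            raise ValueError("net_flow_usd must have one entry per project year")


def npv(cf: CashFlow, rate: float | None = None) -> float:
    """Net present value of a cash flow at an annual discount rate."""
    r = 0.10 if rate is None else rate
    if r <= -1:
        raise ValueError("discount rate must exceed -1")
    flows = np.asarray(cf.net_flow_usd, dtype=float)
    years = np.arange(1, cf.horizon_years + 1)
    discounted = flows / (1.0 + r) ** years
    rest = cf.rest_value_usd / (1.0 + r) ** cf.horizon_years if cf.horizon_years else cf.rest_value_usd
    return float(discounted.sum() + rest - cf.investment_usd)


def annual_revenue(
    honey_kg: float,
    beeswax_kg: float,
    propolis_kg: float,
    params: EconomicParams | None = None,
) -> dict[str, float]:
    """Revenue by product (USD) plus total, at configured unit prices."""
    if min(honey_kg, beeswax_kg, propolis_kg) < 0:
        raise ValueError("product quantities must be non-negative")
    p = params if params is not None else EconomicParams()
    out = {
        "honey": honey_kg * p.price_honey,
        "beeswax": beeswax_kg * p.price_beeswax,
        "propolis": propolis_kg * p.price_propolis,
    }
    out["total"] = sum(out.values())
    return out


def consumables_requirement(
    honey_kg_per_year: float, params: EconomicParams | None = None
) -> tuple[int, int]:
    """(airtight buckets, strainer cloths) needed for an annual honey crop.

    Buckets hold 20 kg each; filtering consumes two cloths per 400 kg
    processed.  Zero honey needs nothing.
    """
    if honey_kg_per_year < 0:
        raise ValueError("honey quantity must be non-negative")
    p = params if params is not None else EconomicParams()
    if honey_kg_per_year == 0:
        return 0, 0
    buckets = math.ceil(honey_kg_per_year / p.bucket_capacity_kg)
    strainers = p.strainers_per_batch * math.ceil(honey_kg_per_year / p.strainer_batch_kg)
    return buckets, strainers


def build_cashflow(
    spec: ScenarioSpec,
    econ: EconomicParams | None = None,
    forage: ForageParams | None = None,
    ramp: YieldRamp | None = None,
    rest_value_usd: float = 0.0,
) -> CashFlow:
    """Assemble the full cash flow of a scenario.

    Year 0 carries the investment; years 1..n carry revenue minus
    recurrent costs.  Inspection frequency and lighting depend on the
    management level; harvest labour and apiary-siting labour scale
    with hive count relative to the 22-hive reference apiary; a
    scenario's escalator flag compounds harvest labour by 10 %/yr.
    Raises if the tree planting exceeds the scenario's land budget.
    """
    econ = econ if econ is not None else EconomicParams()
    forage = forage if forage is not None else ForageParams()
    ramp = ramp if ramp is not None else YieldRamp()
    horizon = ramp.horizon

    if land_required_ha(spec.n_trees, forage) > spec.land_budget_ha:
        raise ValueError(
            f"{spec.n_trees} trees need {land_required_ha(spec.n_trees, forage):.2f} ha, "
            f"exceeding the {spec.land_budget_ha} ha land budget"
        )

    inventory = spec.inventory
    ym = spec.yield_model
    potential_honey = potential_honey_kg(inventory, ym)
    hive_scale = inventory.total / econ.harvest_reference_hives

    # peak annual honey sizes the storage-bucket purchase
    peak_supplement = (
        honey_supplement_kg(spec.n_trees, horizon or 1, forage) if spec.n_trees else 0.0
    )
    peak_honey = potential_honey * max(ramp.fraction_by_year) + peak_supplement
    buckets, _ = consumables_requirement(peak_honey, econ)

    establishment, weeding = forage_costs(spec.n_trees, forage)
    siting_labour = 2 * 2.0 * econ.labour_usd_per_day * hive_scale  # clearing + hanging
    investment = (
        hive_investment(inventory, econ)["total"]
        + econ.cost_smoker
        + econ.cost_bee_suit
        + buckets * econ.cost_bucket
        + siting_labour
        + establishment
    )

    if spec.management == "survey_baseline":
        inspections = econ.inspections_per_year_baseline
        lighting = econ.lighting_baseline_usd
    else:
        inspections = econ.inspections_per_year_improved
        lighting = econ.lighting_improved_usd
    inspection_cost = inspections * econ.inspection_cost_usd
    harvest_base = (
        econ.harvest_seasons_per_year
        * econ.harvest_days_per_season
        * econ.labour_usd_per_day
        * hive_scale
    )
    gumboot_amort = econ.gumboot_pairs * econ.cost_gumboots / econ.gumboot_replacement_years

    rows = []
    net = []
    for t in range(1, horizon + 1):
        frac = ramp.fraction_by_year[t]
        supplement = honey_supplement_kg(spec.n_trees, t, forage) if spec.n_trees else 0.0
        honey = potential_honey * frac + supplement
        if ym.wax_conversion:
            wax = beeswax_from_honey(honey)
        else:
            wax = ym.beeswax_survey_kg * frac
        propolis = spec.propolis_kg_per_year  # held constant over the horizon
        rev = annual_revenue(honey, wax, propolis, econ)

        escal = (1 + econ.labour_escalation_rate) ** (t - 1) if spec.escalate_labour else 1.0
        _, strainer_cloths = consumables_requirement(honey, econ)
        costs = {
            "inspection": inspection_cost,
            "harvest_labour": harvest_base * escal,
            "lighting": lighting,
            "gumboots": gumboot_amort,
            "marketing": econ.marketing_rate * rev["total"],
            "strainers": strainer_cloths * econ.cost_strainer_cloth,
            "tree_weeding": weeding,
        }
        total_cost = sum(costs.values())
        net_t = rev["total"] - total_cost
        net.append(net_t)
        rows.append(
            {
                "year": t,
                "honey_kg": honey,
                "beeswax_kg": wax,
                "propolis_kg": propolis,
                "revenue_honey": rev["honey"],
                "revenue_beeswax": rev["beeswax"],
                "revenue_propolis": rev["propolis"],
                "revenue_total": rev["total"],
                **{f"cost_{k}": v for k, v in costs.items()},
                "cost_total": total_cost,
                "net_flow": net_t,
            }
        )

    detail = pd.DataFrame(rows)
    return CashFlow(
        horizon_years=horizon,
        investment_usd=float(investment),
        net_flow_usd=tuple(float(x) for x in net),
        rest_value_usd=rest_value_usd,
        detail=detail,
    )
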