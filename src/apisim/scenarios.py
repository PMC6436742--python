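"""Intervention scenarios for a smallholder apiary.

A scenario bundles a hive inventory (traditional log, Kenya Top Bar and
Langstroth frame hives), an optional *Calliandra* planting, a honey
yield model and management/cost rules.  The roster mirrors the printed
study design: the survey baseline, a national-average-yield variant,
hive additions of 5/10/15/20 per type, and tree plantings of
500/1000/1500/2000.

Scenarios are addressed by semantic kind (``add_ktb``, ``add_trees``,
...) rather than by number, because the study's own scenario numbering
is ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .cashflow import EconomicParams

__all__ = [
    "HiveInventory",
    "YieldModel",
    "ScenarioSpec",
    "SCENARIO_KINDS",
    "make_scenario",
    "printed_scenarios",
    "hive_investment",
    "potential_honey_kg",
    "beeswax_from_honey",
]

#: baseline apiary: 14 log, 7 KTB, 1 Langstroth (≈ survey means)
BASELINE_INVENTORY_COUNTS = (14, 7, 1)
#: survey-mean apiary-level annual yields (kg/beekeeper/yr)
BASELINE_HONEY_KG = 13.42
BASELINE_BEESWAX_KG = 3.51
BASELINE_PROPOLIS_KG = 0.19
#: national-average per-hive honey yields (kg/hive/yr)
NATIONAL_YIELD_LOG = 8.0
NATIONAL_YIELD_KTB = 12.0
NATIONAL_YIELD_LANGSTROTH = 15.0
#: kg honey needed to render 1 kg pure beeswax
HONEY_PER_KG_BEESWAX = 10.0

SCENARIO_KINDS = (
    "baseline",
    "national_average",
    "add_log",
    "add_ktb",
    "add_langstroth",
    "add_trees",
)


@dataclass(frozen=True)
class HiveInventory:
    """Hive counts per type."""

    log: int = 0
    ktb: int = 0
    langstroth: int = 0

    def __post_init__(self) -> None:
        if min(self.log, self.ktb, self.langstroth) < 0:
            raise ValueError("hive counts must be non-negative")

    @property
    def total(self) -> int:
        return self.log + self.ktb + self.langstroth

    def __add__(self, other: "HiveInventory") -> "HiveInventory":
        return HiveInventory(
            self.log + other.log,
            self.ktb + other.ktb,
            self.langstroth + other.langstroth,
        )


@dataclass(frozen=True)
class YieldModel:
    """How potential annual honey yield follows from a hive inventory.

    ``survey_total`` mode uses an apiary-level total (the survey mean,
    13.42 kg/yr at 22 hives) scaled proportionally with hive count;
    ``per_hive`` mode sums national-average per-hive yields by type.
    Beeswax either carries the survey quantity directly (71 % of wax is
    sold in comb at baseline) or is converted from honey at 10 kg honey
    per kg pure wax.
    """

    mode: str = "per_hive"  # "survey_total" | "per_hive"
    survey_total_kg: float = BASELINE_HONEY_KG
    reference_hives: int = 22
    yield_log: float = NATIONAL_YIELD_LOG
    yield_ktb: float = NATIONAL_YIELD_KTB
    yield_langstroth: float = NATIONAL_YIELD_LANGSTROTH
    beeswax_survey_kg: float = BASELINE_BEESWAX_KG
    wax_conversion: bool = True  # False → use beeswax_survey_kg as-is

    def __post_init__(self) -> None:
        if self.mode not in ("survey_total", "per_hive"):
            raise ValueError(f"unknown yield model mode {self.mode!r}")
        for name in ("survey_total_kg", "yield_log", "yield_ktb", "yield_langstroth",
                     "beeswax_survey_kg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.reference_hives <= 0:
            raise ValueError("reference_hives must be positive")

    def scaled(self, factor: float) -> "YieldModel":
        """Yield model with every honey yield multiplied by ``factor`` ≥ 0."""
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        return replace(
            self,
            survey_total_kg=self.survey_total_kg * factor,
            yield_log=self.yield_log * factor,
            yield_ktb=self.yield_ktb * factor,
            yield_langstroth=self.yield_langstroth * factor,
            beeswax_survey_kg=self.beeswax_survey_kg * factor,
        )


@dataclass(frozen=True)
class ScenarioSpec:
    """A named intervention: inventory changes, planting, yields, cost rules."""

    name: str
    base_inventory: HiveInventory = field(
        default_factory=lambda: HiveInventory(*BASELINE_INVENTORY_COUNTS)
    )
    added_hives: HiveInventory = field(default_factory=HiveInventory)
    n_trees: int = 0
    yield_model: YieldModel = field(default_factory=YieldModel)
    management: str = "improved"  # "survey_baseline" | "improved"
    escalate_labour: bool = False  # +10 %/yr on marketing & harvest labour
    propolis_kg_per_year: float = BASELINE_PROPOLIS_KG
    land_budget_ha: float = 3.7

    def __post_init__(self) -> None:
        if self.n_trees < 0:
            raise ValueError("n_trees must be non-negative")
        if self.management not in ("survey_baseline", "improved"):
            raise ValueError(f"unknown management level {self.management!r}")
        if self.propolis_kg_per_year < 0:
            raise ValueError("propolis_kg_per_year must be non-negative")

    @property
    def inventory(self) -> HiveInventory:
        return self.base_inventory + self.added_hives


def make_scenario(kind: str, n: int = 0, name: str | None = None) -> ScenarioSpec:
    """Build one of the study's scenario kinds.

    ``n`` is the number of added hives for ``add_log`` / ``add_ktb`` /
    ``add_langstroth``, or the number of trees for ``add_trees``; it is
    ignored for ``baseline`` and ``national_average``.  The baseline
    keeps survey yields and management; every other kind assumes
    improved management, national-average per-hive yields and pure-wax
    conversion.
    """
    if kind not in SCENARIO_KINDS:
        raise ValueError(f"unknown scenario kind {kind!r}; expected one of {SCENARIO_KINDS}")
    if n < 0:
        raise ValueError("n must be non-negative")

    if kind == "baseline":
        return ScenarioSpec(
            name=name or "baseline",
            yield_model=YieldModel(mode="survey_total", wax_conversion=False),
            management="survey_baseline",
        )
    improved = dict(
        yield_model=YieldModel(mode="per_hive", wax_conversion=True),
        management="improved",
        escalate_labour=True,
    )
    if kind == "national_average":
        return ScenarioSpec(name=name or "national_average", **improved)
    if kind == "add_trees":
        return ScenarioSpec(name=name or f"{n}_trees", n_trees=n, **improved)
    hive_type = kind.removeprefix("add_")
    added = HiveInventory(**{hive_type: n})
    return ScenarioSpec(name=name or f"{n}_{hive_type}_hives", added_hives=added, **improved)


def printed_scenarios() -> list[ScenarioSpec]:
    """The 18 scenario variants of the study roster."""
    roster = [make_scenario("baseline"), make_scenario("national_average")]
    for kind in ("add_log", "add_ktb", "add_langstroth"):
        roster.extend(make_scenario(kind, n) for n in (5, 10, 15, 20))
    roster.extend(make_scenario("add_trees", n) for n in (500, 1000, 1500, 2000))
    return roster


def hive_investment(inventory: HiveInventory, econ: "EconomicParams") -> dict[str, float]:
    """Year-0 hive purchase cost by type, plus total."""
    out = {
        "log": inventory.log * econ.cost_log_hive,
        "ktb": inventory.ktb * econ.cost_ktb_hive,
        "langstroth": inventory.langstroth * econ.cost_langstroth_hive,
    }
    out["total"] = sum(out.values())
    return out


def potential_honey_kg(inventory: HiveInventory, ym: YieldModel) -> float:
    """Potential annual honey yield (kg) of an inventory under a yield model."""
    if ym.mode == "per_hive":
        return (
            inventory.log * ym.yield_log
            + inventory.ktb * ym.yield_ktb
            + inventory.langstroth * ym.yield_langstroth
        )
    return ym.survey_total_kg * inventory.total / ym.reference_hives


def beeswax_from_honey(honey_kg: float) -> float:
    """Pure beeswax (kg) recoverable alongside a honey harvest (10:1)."""
    if honey_kg < 0:
        raise ValueError("honey_kg must be non-negative")
    return honey_kg / HONEY_PER_KG_BEESWAX
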