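"""Nectar-to-honey forage model for *Calliandra calothyrsus* plantings.

*C. calothyrsus* is a year-round nectar shrub used in East African
agroforestry.  The model converts per-flower nectar secretion into an
annual honey-equivalent sugar yield per plant via a quadratic
refractometer calibration (mg sugar per microlitre of nectar as a
function of percent sugar concentration), then scales to a planting
while discounting for competition from other nectar feeders (insects,
bats) and for incomplete tree maturation in the first two project
years.  Land footprint and planting/maintenance costs round out the
inputs the cash-flow layer needs.

Sugar mass is equated 1:1 with harvestable honey mass; the
``honey_conversion_efficiency`` knob exposes that convention.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ForageParams",
    "sugar_mg_per_ul",
    "annual_sugar_per_plant_kg",
    "honey_supplement_kg",
    "land_required_ha",
    "forage_costs",
]

MG_PER_KG = 1e6
M2_PER_HA = 10_000.0


@dataclass(frozen=True)
class ForageParams:
    """Constants of the nectar-to-honey model.

    Defaults describe an established *C. calothyrsus* shrub flowering
    year round: 17 flowers/plant/day, 35 μl nectar/flower/day at 20 %
    sugar concentration, with 60 % of nectar available to honeybees
    after competition and a maturation discount of 60 % in project
    years 1-2 and 80 % thereafter.
    """

    reg_a0: float = 0.00266  # mg sugar per μl at 0 % concentration
    reg_a1: float = 0.00937
    reg_a2: float = 0.0000585
    nectar_ul_per_flower: float = 35.0  # μl/flower/day
    flowers_per_plant_per_day: float = 17.0
    concentration_pct: float = 20.0  # refractometer reading
    days_per_year: int = 365
    competition_factor: float = 0.60  # share of nectar left for honeybees
    maturation_factor_by_year: tuple[float, ...] = (0.60, 0.60)  # years 1, 2, ...
    maturation_factor_mature: float = 0.80  # years beyond the explicit schedule
    spacing_m2_per_plant: float = 2.25
    seedling_cost_usd: float = 0.10  # per plant, year 0
    planting_cost_usd: float = 0.03  # per plant, year 0
    weeding_cost_usd: float = 0.03  # per plant, annual maintenance
    honey_conversion_efficiency: float = 1.0  # kg honey per kg sugar
    #: per-plant annual sugar is carried at this many decimals when scaling
    #: to a planting (0.046 kg/plant), matching field-guide arithmetic;
    #: None keeps full precision
    plant_sugar_decimals: int | None = 3

    def __post_init__(self) -> None:
        for name in (
            "nectar_ul_per_flower",
            "flowers_per_plant_per_day",
            "concentration_pct",
            "days_per_year",
            "spacing_m2_per_plant",
            "seedling_cost_usd",
            "planting_cost_usd",
            "weeding_cost_usd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        fractions = (
            self.competition_factor,
            self.maturation_factor_mature,
            *self.maturation_factor_by_year,
        )
        for f in fractions:
            if not 0.0 <= f <= 1.0:
                raise ValueError("competition and maturation factors must lie in [0, 1]")
        if self.honey_conversion_efficiency < 0:
            raise ValueError("honey_conversion_efficiency must be non-negative")

    def maturation_factor(self, project_year: int) -> float:
        """Fraction of full nectar output produced in ``project_year`` (1-based)."""
        if project_year < 1:
            raise ValueError("trees are not productive before project year 1")
        sched = self.maturation_factor_by_year
        if project_year <= len(sched):
            return sched[project_year - 1]
        return self.maturation_factor_mature


def sugar_mg_per_ul(concentration_pct: float, params: ForageParams | None = None) -> float:
    """Sugar mass (mg) per microlitre of nectar at the given % concentration.

    Quadratic refractometer calibration a0 + a1·x + a2·x², strictly
    increasing for non-negative x.
    """
    if concentration_pct < 0:
        raise ValueError("concentration must be non-negative")
    p = params if params is not None else ForageParams()
    x = concentration_pct
    return p.reg_a0 + p.reg_a1 * x + p.reg_a2 * x * x


def annual_sugar_per_plant_kg(params: ForageParams | None = None) -> float:
    """Annual sugar yield (kg) of one established plant.

    nectar volume/flower × flowers/day × days/year × sugar concentration
    calibration, converted mg → kg.  Defaults evaluate to 0.046 kg at
    three decimals.
    """
    p = params if params is not None else ForageParams()
    mg = (
        p.nectar_ul_per_flower
        * p.flowers_per_plant_per_day
        * p.days_per_year
        * sugar_mg_per_ul(p.concentration_pct, p)
    )
    return mg / MG_PER_KG


def honey_supplement_kg(
    n_trees: int,
    project_year: int,
    params: ForageParams | None = None,
    apply_competition: bool = True,
) -> float:
    """Honey-equivalent yield (kg) a planting adds in a given project year.

    Per-plant sugar × tree count, discounted by the maturation factor for
    that year and (optionally) by competition from other nectar feeders.
    Year 0 raises: trees carry only costs before their first season.
    """
    if n_trees < 0:
        raise ValueError("n_trees must be non-negative")
    p = params if params is not None else ForageParams()
    per_plant = annual_sugar_per_plant_kg(p)
    if p.plant_sugar_decimals is not None:
        per_plant = round(per_plant, p.plant_sugar_decimals)
    kg = per_plant * n_trees * p.maturation_factor(project_year)
    if apply_competition:
        kg *= p.competition_factor
    return kg * p.honey_conversion_efficiency


def land_required_ha(n_trees: int, params: ForageParams | None = None) -> float:
    """Hectares needed to plant ``n_trees`` at the configured spacing."""
    if n_trees < 0:
        raise ValueError("n_trees must be non-negative")
    p = params if params is not None else ForageParams()
    return n_trees * p.spacing_m2_per_plant / M2_PER_HA


def forage_costs(n_trees: int, params: ForageParams | None = None) -> tuple[float, float]:
    """(establishment USD at year 0, annual maintenance USD) for a planting.

    Establishment covers seedling purchase plus planting labour; the
    annual figure is weeding/maintenance.  Each per-plant component is
    separately configurable on :class:`ForageParams`.
    """
    if n_trees < 0:
        raise ValueError("n_trees must be non-negative")
    p = params if params is not None else ForageParams()
    establishment = n_trees * (p.seedling_cost_usd + p.planting_cost_usd)
    maintenance = n_trees * p.weeding_cost_usd
    return establishment, maintenance
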