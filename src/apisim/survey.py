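"""Synthetic beekeeper household-survey generator and baseline estimation.

Emulates a cross-sectional survey of smallholder beekeepers (the kind
run across agro-ecological zones of Northern Uganda): per-respondent
hive inventories by type (traditional log, Kenya Top Bar, Langstroth),
annual product yields (honey, beeswax, propolis), landholding, years of
beekeeping experience and equipment counts.  Only marginal means and
standard deviations of these quantities are known, so records are drawn
from zero-truncated normal marginals — optionally tied together by a
Gaussian copula when a correlation matrix is supplied — with count
fields rounded half-up to whole numbers.

Because several marginals are strongly right-spread (beeswax
3.51 ± 16.10 kg), truncating a normal centred on the survey mean would
inflate the generated mean well above it.  Each marginal's location is
therefore solved so that the mean of the *truncated* distribution
equals the configured mean, keeping the configured sd as the spread
parameter; recovered sample sds of strongly truncated fields are
accordingly smaller than nominal.

``estimate_baseline`` closes the loop: it recovers per-field means/sds
from a record collection, providing the baseline-scenario parameters
downstream stages consume.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from functools import lru_cache

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

__all__ = [
    "AdopterCategory",
    "BeekeeperRecord",
    "PopulationParams",
    "classify_adopter",
    "generate_survey",
    "estimate_baseline",
    "records_to_frame",
    "frame_to_records",
    "write_records_csv",
    "read_records_csv",
]

#: canonical generation/estimation order of the numeric fields
NUMERIC_FIELDS: tuple[str, ...] = (
    "years_experience",
    "hives_log",
    "hives_ktb",
    "hives_langstroth",
    "honey_kg_per_year",
    "beeswax_kg_per_year",
    "propolis_kg_per_year",
    "land_ha",
)

#: fields rounded half-up to whole counts after truncation
COUNT_FIELDS: frozenset[str] = frozenset(
    {"years_experience", "hives_log", "hives_ktb", "hives_langstroth"}
)

EQUIPMENT_PREFIX = "equip_"


class AdopterCategory(enum.Enum):
    """Experience-based technology-adopter class of a beekeeper."""

    LATE = "late"  # 0-3 years of beekeeping
    EARLY = "early"  # 4-7 years
    INNOVATOR = "innovator"  # 8 years and above


def classify_adopter(years_experience: int) -> AdopterCategory:
    """Partition non-negative years of experience into adopter categories.

    0-3 → late, 4-7 → early, ≥8 → innovator; the boundaries at 0 and 8
    are assigned so the partition is total.
    """
    years = int(years_experience)
    if years < 0:
        raise ValueError("years_experience must be non-negative")
    if years <= 3:
        return AdopterCategory.LATE
    if years <= 7:
        return AdopterCategory.EARLY
    return AdopterCategory.INNOVATOR


@dataclass(frozen=True)
class BeekeeperRecord:
    """One survey respondent."""

    years_experience: int
    hives_log: int
    hives_ktb: int
    hives_langstroth: int
    honey_kg_per_year: float
    beeswax_kg_per_year: float
    propolis_kg_per_year: float
    land_ha: float
    equipment: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in NUMERIC_FIELDS:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for item, count in self.equipment.items():
            if count < 0:
                raise ValueError(f"equipment count for {item!r} must be non-negative")

    @property
    def total_hives(self) -> int:
        return self.hives_log + self.hives_ktb + self.hives_langstroth

    @property
    def adopter_category(self) -> AdopterCategory:
        return classify_adopter(self.years_experience)


def _default_numeric() -> dict[str, tuple[float, float]]:
    # Survey marginals: hive counts, product yields and landholding from the
    # printed distribution tables; experience mean/sd chosen to roughly
    # reproduce the 44/31/25 % late/early/innovator split.
    return {
        "years_experience": (5.0, 4.0),
        "hives_log": (14.49, 12.94),
        "hives_ktb": (7.01, 8.44),
        "hives_langstroth": (1.01, 5.17),
        "honey_kg_per_year": (13.42, 17.80),
        "beeswax_kg_per_year": (3.51, 16.10),
        "propolis_kg_per_year": (0.19, 1.04),
        "land_ha": (3.72, 2.00),
    }


def _default_equipment() -> dict[str, tuple[float, float]]:
    return {
        "smoker": (1.50, 0.48),
        "bee_suit": (1.40, 0.82),
        "gumboots": (1.30, 0.59),
        "bucket": (2.10, 1.84),
    }


@dataclass(frozen=True)
class PopulationParams:
    """Marginal (mean, sd) of every generated survey field.

    ``numeric`` covers the core record fields in :data:`NUMERIC_FIELDS`;
    ``equipment`` maps item names to (mean, sd) count distributions.
    ``sample_size`` records the survey size the marginals describe
    (default 166 respondents).
    """

    numeric: Mapping[str, tuple[float, float]] = field(default_factory=_default_numeric)
    equipment: Mapping[str, tuple[float, float]] = field(default_factory=_default_equipment)
    sample_size: int = 166

    def __post_init__(self) -> None:
        missing = set(NUMERIC_FIELDS) - set(self.numeric)
        if missing:
            raise ValueError(f"numeric params missing fields: {sorted(missing)}")
        for name, (mean, sd) in {**dict(self.numeric), **dict(self.equipment)}.items():
            if mean < 0:
                raise ValueError(f"mean for {name!r} must be non-negative")
            if sd < 0:
                raise ValueError(f"sd for {name!r} must be non-negative")
        if self.sample_size < 0:
            raise ValueError("sample_size must be non-negative")

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "sample_size": self.sample_size,
            "numeric": {k: list(v) for k, v in self.numeric.items()},
            "equipment": {k: list(v) for k, v in self.equipment.items()},
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "PopulationParams":
        return cls(
            numeric={k: (float(m), float(s)) for k, (m, s) in data.get("numeric", {}).items()},
            equipment={
                k: (float(m), float(s)) for k, (m, s) in data.get("equipment", {}).items()
            },
            sample_size=int(data.get("sample_size", 166)),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PopulationParams":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


@lru_cache(maxsize=256)
def _matched_location(mean: float, sd: float, integral: bool = False) -> float:
    """Location μ such that a normal(μ, sd) truncated to [0, ∞) — rounded
    half-up to whole numbers when ``integral`` — has the target mean."""

    def generated_mean(loc: float) -> float:
        a = -loc / sd
        dist = stats.truncnorm(a, np.inf, loc=loc, scale=sd)
        if not integral:
            return float(dist.mean())
        kmax = max(10, int(mean + 12 * sd))
        edges = np.arange(0, kmax) + 0.5  # bucket k covers (k-0.5, k+0.5]
        cdf = dist.cdf(edges)
        probs = np.diff(np.concatenate(([0.0], cdf, [1.0])))
        return float(np.arange(0, kmax + 1) @ probs)

    lo, hi = mean - 50 * sd, mean + sd + 1.0
    return float(optimize.brentq(lambda m: generated_mean(m) - mean, lo, hi, xtol=1e-10))


def _truncnorm_ppf(u: np.ndarray, mean: float, sd: float, integral: bool = False) -> np.ndarray:
    """Quantile of a zero-truncated normal calibrated so the generated
    (optionally rounded) field mean equals ``mean``."""
    if sd == 0 or mean == 0:
        return np.full_like(u, mean, dtype=float)
    loc = _matched_location(mean, sd, integral)
    a = -loc / sd
    return stats.truncnorm.ppf(u, a=a, b=np.inf, loc=loc, scale=sd)


def generate_survey(
    n: int,
    seed: int,
    params: PopulationParams | None = None,
    correlation: np.ndarray | None = None,
) -> list[BeekeeperRecord]:
    """Draw ``n`` synthetic survey records.

    Each field follows a normal distribution truncated at zero, its
    location solved so the truncated mean equals the configured marginal
    mean (sd is the spread parameter); count fields are rounded
    half-up.  When
    ``correlation`` (a positive-definite matrix over the numeric fields,
    in :data:`NUMERIC_FIELDS` order) is given, fields are coupled through
    a Gaussian copula, which preserves the truncated marginals exactly.
    Identical ``(n, seed, params)`` yield identical records.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    p = params if params is not None else PopulationParams()
    rng = np.random.default_rng(seed)

    k = len(NUMERIC_FIELDS)
    if correlation is None:
        u = rng.random((n, k))
    else:
        corr = np.asarray(correlation, dtype=float)
        if corr.shape != (k, k):
            raise ValueError(f"correlation must be {k}x{k} over {NUMERIC_FIELDS}")
        z = rng.multivariate_normal(np.zeros(k), corr, size=n, method="cholesky")
        u = stats.norm.cdf(z)

    columns: dict[str, np.ndarray] = {}
    for j, name in enumerate(NUMERIC_FIELDS):
        mean, sd = p.numeric[name]
        is_count = name in COUNT_FIELDS
        vals = _truncnorm_ppf(u[:, j], mean, sd, integral=is_count)
        if is_count:
            vals = _round_half_up(vals)
        columns[name] = vals

    equip_cols: dict[str, np.ndarray] = {}
    for item in sorted(p.equipment):
        mean, sd = p.equipment[item]
        vals = _truncnorm_ppf(rng.random(n), mean, sd, integral=True)
        equip_cols[item] = _round_half_up(vals)

    records = []
    for i in range(n):
        records.append(
            BeekeeperRecord(
                years_experience=int(columns["years_experience"][i]),
                hives_log=int(columns["hives_log"][i]),
                hives_ktb=int(columns["hives_ktb"][i]),
                hives_langstroth=int(columns["hives_langstroth"][i]),
                honey_kg_per_year=float(columns["honey_kg_per_year"][i]),
                beeswax_kg_per_year=float(columns["beeswax_kg_per_year"][i]),
                propolis_kg_per_year=float(columns["propolis_kg_per_year"][i]),
                land_ha=float(columns["land_ha"][i]),
                equipment={item: int(vals[i]) for item, vals in equip_cols.items()},
            )
        )
    return records


def estimate_baseline(records: Sequence[BeekeeperRecord]) -> PopulationParams:
    """Per-field sample mean and sd of a record collection.

    The population sd (ddof=0) is used so a single record yields sd 0
    and its own values as means.  Raises on an empty collection.
    """
    if len(records) == 0:
        raise ValueError("cannot estimate baseline parameters from zero records")
    frame = records_to_frame(records)
    numeric = {
        name: (float(frame[name].mean()), float(frame[name].std(ddof=0)))
        for name in NUMERIC_FIELDS
    }
    equipment = {}
    for col in frame.columns:
        if col.startswith(EQUIPMENT_PREFIX):
            equipment[col[len(EQUIPMENT_PREFIX):]] = (
                float(frame[col].mean()),
                float(frame[col].std(ddof=0)),
            )
    return PopulationParams(numeric=numeric, equipment=equipment, sample_size=len(records))


# -- tabular I/O -------------------------------------------------------


def records_to_frame(records: Iterable[BeekeeperRecord]) -> pd.DataFrame:
    """Flatten records into a DataFrame (equipment as ``equip_*`` columns)."""
    rows = []
    for r in records:
        row = {name: getattr(r, name) for name in NUMERIC_FIELDS}
        row["total_hives"] = r.total_hives
        row["adopter_category"] = r.adopter_category.value
        for item, count in sorted(r.equipment.items()):
            row[EQUIPMENT_PREFIX + item] = count
        rows.append(row)
    if not rows:
        cols = [*NUMERIC_FIELDS, "total_hives", "adopter_category"]
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)


def frame_to_records(frame: pd.DataFrame) -> list[BeekeeperRecord]:
    records = []
    equip_items = [c for c in frame.columns if c.startswith(EQUIPMENT_PREFIX)]
    for _, row in frame.iterrows():
        records.append(
            BeekeeperRecord(
                years_experience=int(row["years_experience"]),
                hives_log=int(row["hives_log"]),
                hives_ktb=int(row["hives_ktb"]),
                hives_langstroth=int(row["hives_langstroth"]),
                honey_kg_per_year=float(row["honey_kg_per_year"]),
                beeswax_kg_per_year=float(row["beeswax_kg_per_year"]),
                propolis_kg_per_year=float(row["propolis_kg_per_year"]),
                land_ha=float(row["land_ha"]),
                equipment={item[len(EQUIPMENT_PREFIX):]: int(row[item]) for item in equip_items},
            )
        )
    return records


def write_records_csv(records: Iterable[BeekeeperRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_records_csv(path: str | Path) -> list[BeekeeperRecord]:
    return frame_to_records(pd.read_csv(path))
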