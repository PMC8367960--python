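"""Forage yield, standard dry forage, animal units and grazing capacity.

The rangeland chain is:

    Y  = Yp × A                    per-species yield (quintal/year) from
                                   above-ground biomass Yp (g dry matter/m²)
                                   over the grazing area A (km²);
    F  = Σ Yi × Ui × Ci            standard dry forage after the
                                   utilization rate Ui (default 50%) and a
                                   meadow conversion coefficient Ci (1);
    Cc = F / (I × D)               grazing capacity in cow units (CU),
                                   with daily intake I = 7.5 kg dry matter
                                   per CU and D = 153 grazing days
                                   (May–September).

Livestock are expressed in cow units through an animal-unit table (one
adult milking cow of 250 kg eating 7.5 kg/day = 1 CU; every animal eats
3% of its body weight as dry forage).  The balance total CU − Cc is the
grazing pressure that must be removed to bring the meadow to capacity.

Unit notes: 1 quintal = 100 kg = 1e5 g; 1 km² = 1e6 m², so 1 g/m² over
1 km² is 1e6 g = 10 quintal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats as _scipy_stats

from ._rounding import round_half_up

QUINTAL_PER_G_PER_M2_KM2 = 10.0  # 1 g/m^2 x 1 km^2 = 1e6 g = 10 quintal
KG_PER_QUINTAL = 100.0
FORAGE_FRACTION_OF_BODY_WEIGHT = 0.03


class ForageError(ValueError):
    """Raised on invalid forage/grazing inputs."""


@dataclass(frozen=True)
class GrazingParameters:
    """Constants of the grazing-capacity calculation.

    ``grazing_area`` is the suitable grazing extent in km² (4.235 km²
    reproduces the published per-species yields).  ``utilization_rate``
    is the fraction of yield that can be taken without degrading the
    sward; ``conversion_coefficient`` is 1 for meadow.
    """

    grazing_area: float = 4.235  # km^2
    utilization_rate: float = 0.5
    conversion_coefficient: float = 1.0
    daily_intake: float = 7.5  # kg dry matter per cow unit per day
    grazing_days: int = 153  # May-September

    def __post_init__(self) -> None:
        if not 0.0 <= self.utilization_rate <= 1.0:
            raise ForageError("utilization_rate must be in [0, 1]")
        if self.daily_intake <= 0:
            raise ForageError("daily_intake must be > 0")
        if self.grazing_days < 1:
            raise ForageError("grazing_days must be >= 1")
        if self.grazing_area < 0:
            raise ForageError("grazing_area must be >= 0")


@dataclass(frozen=True)
class GrazingAssessment:
    standard_forage_quintal: int
    standard_forage_kg: float
    capacity_cu: int
    total_cu: int
    deficit_cu: int


def forage_yield(biomass_g_per_m2: float, area_km2: float) -> float:
    """Yield Y (quintal/year) of one species: biomass Yp × grazing area A."""
    if biomass_g_per_m2 < 0 or area_km2 < 0:
        raise ForageError("biomass and area must be non-negative")
    return biomass_g_per_m2 * area_km2 * QUINTAL_PER_G_PER_M2_KM2


def total_forage_yield(species: pd.DataFrame, area_km2: float) -> float:
    """Sum of per-species yields (quintal/year) over the palatable species.

    ``species`` needs columns ``biomass_g_per_m2`` and, optionally,
    ``palatable`` (boolean; rows flagged False are excluded — palatability
    is an input flag, never inferred).
    """
    if "biomass_g_per_m2" not in species.columns:
        raise ForageError("species table missing column 'biomass_g_per_m2'")
    rows = species
    if "palatable" in rows.columns:
        rows = rows.loc[rows["palatable"].astype(bool)]
    return float(sum(forage_yield(b, area_km2) for b in rows["biomass_g_per_m2"]))


def standard_forage(total_yield_quintal: float, ui: float = 0.5, ci: float = 1.0) -> int:
    """Standard dry forage F = yield × Ui × Ci, truncated to whole quintal.

    Truncation (not rounding) matches whole-quintal reporting:
    10,003 × 0.5 × 1 = 5001.5 -> 5001.
    """
    if total_yield_quintal < 0:
        raise ForageError("total yield must be >= 0")
    if not 0.0 <= ui <= 1.0:
        raise ForageError("utilization rate must be in [0, 1]")
    return math.trunc(total_yield_quintal * ui * ci)


def grazing_capacity(f_quintal: float, intake_kg_day: float = 7.5, days: int = 153) -> int:
    """Cow units per year the meadow can bear: Cc = F / (I × D), half-up."""
    if intake_kg_day <= 0 or days <= 0:
        raise ForageError("intake and grazing days must be > 0")
    if f_quintal < 0:
        raise ForageError("standard forage must be >= 0")
    f_kg = f_quintal * KG_PER_QUINTAL
    return int(round_half_up(f_kg / (intake_kg_day * days)))


def forage_requirement(body_weight_kg: float) -> float:
    """Daily dry-forage demand: 3% of body weight, at 2 decimals."""
    if body_weight_kg <= 0:
        raise ForageError("body weight must be > 0")
    return round_half_up(FORAGE_FRACTION_OF_BODY_WEIGHT * body_weight_kg, 2)


def to_cow_units(
    census: pd.DataFrame,
    au_table: pd.DataFrame,
    derive_au: bool = False,
    intake_kg_day: float = 7.5,
) -> dict[str, int]:
    """Convert a livestock census into cow units per origin group.

    ``census`` has columns animal, count and (optionally) origin;
    ``au_table`` has animal, animal_unit and forage_req_kg_day.  By
    default the tabulated animal-unit column is used verbatim; with
    ``derive_au=True`` the unit is recomputed as forage requirement /
    daily cow intake, which exposes the small inconsistency between the
    two published columns (e.g. horse 9.38/7.5 = 1.25 vs tabulated 1.18).
    Per-origin CU sums are rounded half-up; ``total`` sums the rounded
    groups.
    """
    for col in ("animal", "count"):
        if col not in census.columns:
            raise ForageError(f"census missing column '{col}'")
    if (census["count"] < 0).any():
        raise ForageError("census counts must be non-negative")
    au = au_table.set_index("animal")
    unknown = set(census["animal"]) - set(au.index)
    if unknown:
        raise ForageError(f"animals missing from the animal-unit table: {sorted(unknown)}")
    if derive_au:
        units = au["forage_req_kg_day"] / intake_kg_day
    else:
        units = au["animal_unit"]
    work = census.copy()
    work["cu"] = work["count"].to_numpy(float) * units.loc[work["animal"]].to_numpy(float)
    if "origin" not in work.columns:
        work["origin"] = "all"
    out = {
        str(origin): int(round_half_up(grp["cu"].sum()))
        for origin, grp in work.groupby("origin", sort=True)
    }
    out["total"] = sum(out.values())
    return out


def grazing_balance(total_cu: float, capacity_cu: float) -> int:
    """Cow units in excess of capacity, floored at zero when under capacity."""
    if total_cu < 0 or capacity_cu < 0:
        raise ForageError("cow units must be non-negative")
    return int(round_half_up(max(0.0, total_cu - capacity_cu)))


def cu_trend(census_totals: pd.DataFrame) -> float:
    """OLS slope of total cow units against calendar year (CU per year).

    ``census_totals`` has columns year and cu, one row per year.
    """
    for col in ("year", "cu"):
        if col not in census_totals.columns:
            raise ForageError(f"census totals missing column '{col}'")
    if len(census_totals) < 2:
        raise ForageError("need at least two years for a trend")
    if census_totals["cu"].nunique() == 1:
        return 0.0
    res = _scipy_stats.linregress(
        census_totals["year"].to_numpy(float), census_totals["cu"].to_numpy(float)
    )
    return float(res.slope)


def assess_grazing(
    total_yield_quintal: float,
    total_cu: int,
    params: GrazingParameters = GrazingParameters(),
) -> GrazingAssessment:
    """Full chain: yield -> standard forage -> capacity -> surplus CU."""
    f = standard_forage(total_yield_quintal, params.utilization_rate, params.conversion_coefficient)
    cc = grazing_capacity(f, params.daily_intake, params.grazing_days)
    return GrazingAssessment(
        standard_forage_quintal=f,
        standard_forage_kg=f * KG_PER_QUINTAL,
        capacity_cu=cc,
        total_cu=int(total_cu),
        deficit_cu=grazing_balance(total_cu, cc),
    )
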