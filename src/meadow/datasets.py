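"""Packaged reference tables for the Dayara bugyal assessment.

These small CSV/YAML fixtures encode the published field tables the
pipeline consumes: the palatable forage species with their biomass and
yields, the per-zone quadrat vegetation statistics, the soil-chemistry
means with standard errors, the animal-unit conversion table, and the
banded scoring criteria.  Two files are synthetic constructions and say
so in their names: the livestock census (only the 881-CU 2019 total is
published; the per-animal decomposition is ours) and the per-zone
vegetation cover (never published; values chosen once to be realistic).
"""

from __future__ import annotations

import io
from importlib import resources

import pandas as pd

from .scorecard import ScoringCriterion, load_criteria

__all__ = [
    "load_forage_species",
    "load_zone_vegetation",
    "load_soil_chemistry",
    "load_animal_units",
    "load_livestock_census",
    "load_vegetation_cover",
    "load_scoring_criteria",
]


def _read_csv(name: str) -> pd.DataFrame:
    text = resources.files("meadow.fixtures").joinpath(name).read_text(encoding="utf-8")
    return pd.read_csv(io.StringIO(text))


def load_forage_species() -> pd.DataFrame:
    """The 37 dominant palatable species with density, biomass and yield.

    ``yield_printed_quintal`` is the published per-species yield;
    ``ambiguous`` flags rows whose printed digits are internally
    inconsistent (yield far from biomass × area) and should be excluded
    from print-matching checks.
    """
    df = _read_csv("forage_species.csv")
    df["palatable"] = df["palatable"].astype(bool)
    df["ambiguous"] = df["ambiguous"].astype(bool)
    return df


def load_zone_vegetation() -> pd.DataFrame:
    """Published density/frequency/abundance per species for zones R, GTZ, UTZ."""
    return _read_csv("zone_vegetation.csv")


def load_soil_chemistry() -> pd.DataFrame:
    """Soil chemistry and herb density per zone, as mean ± standard error."""
    return _read_csv("soil_chemistry.csv")


def load_animal_units() -> pd.DataFrame:
    """Animal-unit table: body weight, daily forage requirement, cow-unit factor."""
    return _read_csv("animal_units.csv")


def load_livestock_census() -> pd.DataFrame:
    """Synthetic 2019 livestock census consistent with the 881-CU total.

    Only the aggregate cow-unit figure is published; this decomposition
    (migratory horses and goats, local cows and sheep) is constructed so
    that :func:`meadow.forage.to_cow_units` returns exactly 881.
    """
    return _read_csv("livestock_census_synthetic.csv")


def load_vegetation_cover() -> pd.DataFrame:
    """Synthetic per-zone vegetation cover (%); no published values exist."""
    return _read_csv("vegetation_cover_synthetic.csv")


def load_scoring_criteria() -> dict[str, ScoringCriterion]:
    """The packaged banded scoring profile (validated for band totality)."""
    return load_criteria()
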