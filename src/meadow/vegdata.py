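"""Quadrat vegetation analytics: density, frequency, abundance.

A survey lays ``n`` quadrats of fixed area (by default 30 quadrats of
1 m²) in a zone and counts the individuals of every herb species in each
quadrat.  The three classical descriptors are then

* density    = total individuals of the species / number of quadrats laid
               (per m² for 1 m² quadrats),
* frequency  = 100 × quadrats occupied / quadrats laid  (percent),
* abundance  = total individuals / quadrats occupied,

so that density = (frequency/100) × abundance up to rounding.  Zone-level
summaries add the densities over species and name the dominant community
as the top-k species by density joined with em-dashes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._rounding import round_half_up

OBSERVATION_COLUMNS = ["zone", "plot", "quadrat", "species", "count"]
STATS_COLUMNS = [
    "species",
    "density",
    "frequency_pct",
    "abundance",
    "total_individuals",
    "occupied_quadrats",
]


class VegDataError(ValueError):
    """Raised when quadrat observations violate the survey design."""


@dataclass(frozen=True)
class SurveyDesign:
    """Sampling layout of one zone's vegetation survey.

    ``quadrat_ids`` may list the legal quadrat labels; when ``None`` any
    label is accepted as long as no more than ``n_quadrats`` distinct
    quadrats appear.  Quadrats with no individuals are legal and still
    count in the denominator, which is why ``n_quadrats`` is carried
    explicitly instead of being inferred from the data.
    """

    n_quadrats: int = 30
    quadrat_area: float = 1.0  # m^2
    zones: tuple[str, ...] = ()
    quadrat_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_quadrats < 1:
            raise VegDataError("n_quadrats must be >= 1")
        if self.quadrat_area <= 0:
            raise VegDataError("quadrat_area must be > 0")
        if self.quadrat_ids is not None and len(self.quadrat_ids) != self.n_quadrats:
            raise VegDataError(
                f"quadrat_ids lists {len(self.quadrat_ids)} labels "
                f"but n_quadrats is {self.n_quadrats}"
            )


@dataclass(frozen=True)
class ZoneVegetationSummary:
    zone_id: str
    total_herb_density: float
    dominant_community: str
    species_richness: int
    dominant_species: tuple[str, ...] = field(default=(), repr=False)


def compute_species_stats(
    observations: pd.DataFrame, design: SurveyDesign
) -> pd.DataFrame:
    """Per-species density / frequency / abundance for one zone.

    ``observations`` must carry columns zone, plot, quadrat, species, count
    (extra columns are ignored).  Species absent from every quadrat simply
    do not appear; an empty observation set yields an empty frame.  Values
    are returned at full precision; see :func:`round_stats` for 2-decimal
    presentation.
    """
    missing = [c for c in OBSERVATION_COLUMNS if c not in observations.columns]
    if missing:
        raise VegDataError(f"observations missing columns: {missing}")
    if (observations["count"] < 0).any():
        raise VegDataError("counts must be non-negative")
    obs = observations.loc[observations["count"] > 0]
    if obs.empty:
        return pd.DataFrame(columns=STATS_COLUMNS)
    zones = obs["zone"].unique()
    if len(zones) > 1:
        raise VegDataError(
            f"observations span multiple zones {sorted(map(str, zones))}; "
            "compute one zone at a time"
        )
    seen_quadrats = obs["quadrat"].unique()
    if design.quadrat_ids is not None:
        unknown = set(seen_quadrats) - set(design.quadrat_ids)
        if unknown:
            raise VegDataError(f"quadrat ids not in design: {sorted(map(str, unknown))}")
    elif len(seen_quadrats) > design.n_quadrats:
        raise VegDataError(
            f"{len(seen_quadrats)} distinct quadrats observed but design "
            f"has only {design.n_quadrats}"
        )
    dup = obs.duplicated(subset=["zone", "plot", "quadrat", "species"])
    if dup.any():
        raise VegDataError("duplicate (zone, plot, quadrat, species) rows")

    area_total = design.n_quadrats * design.quadrat_area
    grouped = obs.groupby("species", sort=True)
    total = grouped["count"].sum()
    occupied = grouped["quadrat"].nunique()
    out = pd.DataFrame(
        {
            "species": total.index,
            "density": total.to_numpy(float) / area_total,
            "frequency_pct": 100.0 * occupied.to_numpy(float) / design.n_quadrats,
            "abundance": total.to_numpy(float) / occupied.to_numpy(float),
            "total_individuals": total.to_numpy(int),
            "occupied_quadrats": occupied.to_numpy(int),
        }
    ).reset_index(drop=True)
    return out


def zone_summary(stats: pd.DataFrame, k: int = 4, zone_id: str = "") -> ZoneVegetationSummary:
    """Zone totals and dominant-community label from species statistics.

    The dominant community is the ``k`` highest-density species in
    descending density order, ties broken alphabetically, joined with
    em-dashes the way plant sociology names communities.
    """
    if stats.empty:
        raise VegDataError("no vegetation data for zone summary")
    if k < 1:
        raise VegDataError("k must be >= 1")
    ordered = stats.sort_values(
        ["density", "species"], ascending=[False, True], kind="mergesort"
    )
    top = tuple(ordered["species"].head(k))
    return ZoneVegetationSummary(
        zone_id=zone_id or str(stats.get("zone", pd.Series([""])).iloc[0] or ""),
        total_herb_density=float(stats["density"].sum()),
        dominant_community="—".join(top),
        species_richness=int(len(stats)),
        dominant_species=top,
    )


def round_stats(stats: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Half-up rounded copy of density/frequency/abundance for presentation."""
    if decimals < 0:
        raise VegDataError("decimals must be >= 0")
    out = stats.copy()
    for col in ("density", "frequency_pct", "abundance"):
        if col in out.columns:
            out[col] = [round_half_up(v, decimals) for v in out[col]]
    return out
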