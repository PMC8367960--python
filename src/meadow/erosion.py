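"""Check-dam sediment accounting by the core-density method.

Each check dam traps a measurable wedge of debris.  Its stored volume V
(m³) is surveyed directly; the bulk density of the fill is measured in
triplicate with a cylindrical iron core (2.5 cm radius × 30 cm height by
default), giving ρb in g/cm³.  Because 1 g/cm³ equals exactly 1 t/m³,
the arrested mass per dam is simply

    Md = V × mean(ρb)        (tonnes)

and the area-normalised erosion-control rate is the total over dams
divided by the drained extent in hectares (t ha⁻¹ yr⁻¹ when the volumes
accrue over one year).  This is pure accounting of retained sediment —
no erosion modelling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from ._rounding import round_half_up


class ErosionError(ValueError):
    """Raised on invalid sediment-accounting inputs."""


@dataclass(frozen=True)
class CoreSpec:
    radius_cm: float = 2.5
    height_cm: float = 30.0

    def __post_init__(self) -> None:
        if self.radius_cm <= 0 or self.height_cm <= 0:
            raise ErosionError("core dimensions must be positive")

    @property
    def volume_cm3(self) -> float:
        return math.pi * self.radius_cm**2 * self.height_cm


@dataclass(frozen=True)
class CheckDamRecord:
    dam_id: str
    gully: str
    debris_volume_m3: float
    core_densities: tuple[float, ...]  # g/cm^3, usually a triplicate

    @property
    def debris_mass_t(self) -> float:
        return debris_mass(self.debris_volume_m3, self.core_densities)


@dataclass(frozen=True)
class ErosionControlSummary:
    n_dams: int
    total_mass_t: float  # tonnes per year, 2 decimals
    area_ha: float
    rate_t_ha_yr: float  # 1 decimal


def core_density(dry_mass_g: float, core: CoreSpec = CoreSpec()) -> float:
    """Bulk density (g/cm³) of one core sample: dry mass / core volume."""
    if dry_mass_g < 0:
        raise ErosionError("dry mass must be >= 0")
    return dry_mass_g / core.volume_cm3


def debris_mass(volume_m3: float, densities: Sequence[float]) -> float:
    """Arrested mass of one dam (t): volume × mean core density."""
    if volume_m3 < 0:
        raise ErosionError("debris volume must be >= 0")
    densities = list(densities)
    if not densities:
        raise ErosionError("need at least one core-density measurement")
    if any(d < 0 for d in densities):
        raise ErosionError("densities must be >= 0")
    return volume_m3 * (sum(densities) / len(densities))


def erosion_summary(
    dams: Iterable[CheckDamRecord] | pd.DataFrame, area_ha: float
) -> ErosionControlSummary:
    """Total arrested sediment and per-hectare control rate.

    ``dams`` is either CheckDamRecord objects or a frame with columns
    dam, gully, volume_m3 and one or more density columns rho1, rho2, ...
    An empty dam set yields a zero summary with a warning rather than an
    error, so a freshly instrumented gully can still be reported.
    """
    if area_ha <= 0:
        raise ErosionError("area_ha must be > 0")
    if isinstance(dams, pd.DataFrame):
        records = records_from_frame(dams)
    else:
        records = list(dams)
    if not records:
        warnings.warn("no check dams supplied; reporting a zero summary", stacklevel=2)
        return ErosionControlSummary(0, 0.0, area_ha, 0.0)
    total = sum(r.debris_mass_t for r in records)
    return ErosionControlSummary(
        n_dams=len(records),
        total_mass_t=round_half_up(total, 2),
        area_ha=area_ha,
        rate_t_ha_yr=round_half_up(total / area_ha, 1),
    )


def records_from_frame(frame: pd.DataFrame) -> list[CheckDamRecord]:
    """Parse a checkdams table (dam,gully,volume_m3,rho1[,rho2,...])."""
    rho_cols = [c for c in frame.columns if c.startswith("rho")]
    for col in ("dam", "gully", "volume_m3"):
        if col not in frame.columns:
            raise ErosionError(f"check-dam table missing column '{col}'")
    if not rho_cols:
        raise ErosionError("check-dam table has no density columns (rho1, rho2, ...)")
    return [
        CheckDamRecord(
            dam_id=str(row["dam"]),
            gully=str(row["gully"]),
            debris_volume_m3=float(row["volume_m3"]),
            core_densities=tuple(float(row[c]) for c in rho_cols if pd.notna(row[c])),
        )
        for _, row in frame.iterrows()
    ]
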