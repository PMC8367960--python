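"""Project configuration with the published constants as defaults.

Every stage reads its own named area — the grazing extent (4.235 km²),
the tourism geographical/fragile areas (3.94 km² / 12,000 m²) and the
erosion accounting extent (338 ha) are distinct, documented constants,
never a shared "the area".  Validation is strict: unknown keys are
rejected so a typo cannot silently fall back to a default, and all
violations are reported at once.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class GrazingConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    grazing_area: float = 4.235  # km²; reproduces the per-species yields
    eq4_note_area: float = 3.235  # km²; quoted alongside the capacity formula, unused
    utilization_rate: float = 0.5
    conversion_coefficient: float = 1.0
    daily_intake: float = 7.5  # kg dry matter per cow unit per day
    grazing_days: int = 153  # May–September
    derive_animal_units: bool = False  # recompute AU = requirement / intake

    @model_validator(mode="after")
    def _check(self) -> "GrazingConfig":
        errors = []
        if self.grazing_area <= 0:
            errors.append("grazing_area must be > 0")
        if not 0.0 <= self.utilization_rate <= 1.0:
            errors.append("utilization_rate must be in [0, 1]")
        if self.daily_intake <= 0:
            errors.append("daily_intake must be > 0")
        if self.grazing_days < 1:
            errors.append("grazing_days must be >= 1")
        if errors:
            raise ValueError("; ".join(errors))
        return self


class TourismConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    total_area: float = 3_940_000.0  # m²
    fragile_area: float = 12_000.0  # m²
    tourism_fractions: tuple[float, ...] = (0.12, 0.15)
    area_per_tourist: float = 5.0  # m²
    open_hours: float = 6.0
    visit_hours: float = 3.0
    heavy_rain_mm: float = 250.0
    heavy_snow_cm: float = 8.0
    rain_months: tuple[int, ...] = (3, 4, 5, 6, 7, 8, 9, 10, 11)
    snow_months: tuple[int, ...] = (12, 1, 2)
    daily_cap: float = 200.0  # court-ordered visitors/day for bugyal areas

    @model_validator(mode="after")
    def _check(self) -> "TourismConfig":
        errors = []
        if self.fragile_area > self.total_area:
            errors.append("fragile_area exceeds total_area")
        if not all(0.0 < f <= 1.0 for f in self.tourism_fractions):
            errors.append("tourism_fractions must be in (0, 1]")
        if self.area_per_tourist <= 0:
            errors.append("area_per_tourist must be > 0")
        if self.open_hours <= 0 or self.visit_hours <= 0:
            errors.append("open_hours and visit_hours must be > 0")
        if self.daily_cap < 0:
            errors.append("daily_cap must be >= 0")
        if errors:
            raise ValueError("; ".join(errors))
        return self


class ErosionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    area_ha: float = 338.0  # the 3.38 km² meadow extent

    @model_validator(mode="after")
    def _check(self) -> "ErosionConfig":
        if self.area_ha <= 0:
            raise ValueError("area_ha must be > 0")
        return self


class ScorecardConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    mid_score: float = 1.5  # score for the "average" band
    max_score: float = 16.0  # evaluation-index denominator
    criteria_path: str | None = None  # None -> packaged profile

    @model_validator(mode="after")
    def _check(self) -> "ScorecardConfig":
        errors = []
        if not 0.0 <= self.mid_score <= 3.0:
            errors.append("mid_score must be in [0, 3]")
        if self.max_score <= 0:
            errors.append("max_score must be > 0")
        if errors:
            raise ValueError("; ".join(errors))
        return self


class VegConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_quadrats: int = 30
    quadrat_area: float = 1.0  # m²
    dominant_k: int = 4  # species named in the dominant community

    @model_validator(mode="after")
    def _check(self) -> "VegConfig":
        errors = []
        if self.n_quadrats < 1:
            errors.append("n_quadrats must be >= 1")
        if self.quadrat_area <= 0:
            errors.append("quadrat_area must be > 0")
        if self.dominant_k < 1:
            errors.append("dominant_k must be >= 1")
        if errors:
            raise ValueError("; ".join(errors))
        return self


class ProjectConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    veg: VegConfig = Field(default_factory=VegConfig)
    grazing: GrazingConfig = Field(default_factory=GrazingConfig)
    tourism: TourismConfig = Field(default_factory=TourismConfig)
    erosion: ErosionConfig = Field(default_factory=ErosionConfig)
    scorecard: ScorecardConfig = Field(default_factory=ScorecardConfig)


def load_config(path: str | Path | None = None) -> ProjectConfig:
    """Load a YAML project config; an empty or absent file gives defaults.

    Unknown keys and invalid values raise with every violation listed.
    """
    if path is None:
        return ProjectConfig()
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if raw is None:
        return ProjectConfig()
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return ProjectConfig.model_validate(raw)
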