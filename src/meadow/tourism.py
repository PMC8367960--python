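"""Tourist carrying capacity: PCC, weather correction factors, RCC.

The Cifuentes protected-area framework sizes visitation in two stages.
Physical carrying capacity

    PCC = (A / Au) × Rf

takes the area open to tourism A (a configured fraction of the
geographical area minus ecologically fragile ground), the space one
visitor needs Au (5 m² here, conservative for a sensitive alpine
meadow), and the rotation factor Rf = daily open hours / visit length
(6 h / 3 h = 2).  Real carrying capacity discounts PCC multiplicatively
by correction factors, one per limiting condition:

    Cfx = 1 − Lmx / Tmx,     RCC = PCC × Cf1 × Cf2 × ... × Cfn

Here the limiting conditions are heavy-rain days (> 250 mm/day, within a
March–November rain season) and heavy-snow days (> 8 cm/day, within a
December–February snow season).  Correction factors enter the product at
two decimals (truncated, the convention that reproduces the published
0.59 and 0.72); raw values are retained for diagnostics.  The daily RCC
is the annual RCC divided by 365 and floored, and is compared against a
regulatory daily cap where one applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats as _scipy_stats

from ._rounding import round_half_up, trunc_decimals


class TourismError(ValueError):
    """Raised on invalid carrying-capacity inputs."""


@dataclass(frozen=True)
class TourismAreaConfig:
    total_area: float = 3_940_000.0  # m^2
    fragile_area: float = 12_000.0  # m^2, excluded before the tourism fraction
    tourism_fraction: float = 0.12  # published scenarios: 0.12 and 0.15
    area_per_tourist: float = 5.0  # m^2 (Au)
    open_hours: float = 6.0
    visit_hours: float = 3.0

    def __post_init__(self) -> None:
        if self.fragile_area > self.total_area:
            raise TourismError("fragile_area exceeds total_area")
        if not 0.0 < self.tourism_fraction <= 1.0:
            raise TourismError("tourism_fraction must be in (0, 1]")
        if self.area_per_tourist <= 0:
            raise TourismError("area_per_tourist must be > 0")
        if self.open_hours <= 0 or self.visit_hours <= 0:
            raise TourismError("open and visit hours must be > 0")

    @property
    def available_area(self) -> float:
        return self.total_area - self.fragile_area

    @property
    def tourism_area(self) -> float:
        """A: the part of the available area opened to tourism (m²)."""
        return self.tourism_fraction * self.available_area

    @property
    def rotation_factor(self) -> float:
        return self.open_hours / self.visit_hours


@dataclass(frozen=True)
class CorrectionFactor:
    """One limiting condition: Cfx = 1 − limiting days / total days."""

    name: str
    limiting_days: int
    total_days: int
    value: float = field(init=False)

    def __post_init__(self) -> None:
        if self.total_days <= 0:
            raise TourismError(f"{self.name}: total_days must be > 0")
        if not 0 <= self.limiting_days <= self.total_days:
            raise TourismError(f"{self.name}: limiting_days must be in [0, total_days]")
        object.__setattr__(self, "value", 1.0 - self.limiting_days / self.total_days)

    @property
    def value_2dp(self) -> float:
        """Two-decimal (truncated) value used in the capacity product."""
        return trunc_decimals(self.value, 2)


@dataclass(frozen=True)
class TourismCapacityResult:
    available_area: float
    tourism_area: float
    pcc: float
    correction_factors: tuple[CorrectionFactor, ...]
    rcc_year: int
    rcc_day: int
    compliant: bool | None = None


@dataclass(frozen=True)
class ComplianceReport:
    rcc_day: int
    current_daily_visits: float
    cap: float
    effective_limit: float
    compliant: bool
    headroom: float


def pcc(config: TourismAreaConfig) -> float:
    """Physical carrying capacity (visits/year): (A / Au) × Rf."""
    return config.tourism_area / config.area_per_tourist * config.rotation_factor


# month windows, as calendar month numbers
RAIN_MONTHS = (3, 4, 5, 6, 7, 8, 9, 10, 11)
SNOW_MONTHS = (12, 1, 2)
HEAVY_RAIN_MM = 250.0
HEAVY_SNOW_CM = 8.0


def correction_factor_from_weather(
    records: pd.DataFrame,
    variable: str,
    threshold: float | None = None,
    month_window: tuple[int, ...] | None = None,
    name: str | None = None,
) -> CorrectionFactor:
    """Derive a correction factor from daily weather records.

    ``records`` has columns date (parseable), rain_mm and snow_cm.
    ``variable`` is "rain" or "snow"; the default thresholds and month
    windows are heavy rain > 250 mm/day over March–November and heavy
    snow > 8 cm/day over December–February.  Tmx is the number of days
    in the window, Lmx the number exceeding the threshold.
    """
    if variable == "rain":
        col, threshold_, window_ = "rain_mm", HEAVY_RAIN_MM, RAIN_MONTHS
    elif variable == "snow":
        col, threshold_, window_ = "snow_cm", HEAVY_SNOW_CM, SNOW_MONTHS
    else:
        raise TourismError(f"variable must be 'rain' or 'snow', got {variable!r}")
    threshold = threshold_ if threshold is None else threshold
    month_window = window_ if month_window is None else tuple(month_window)
    if col not in records.columns or "date" not in records.columns:
        raise TourismError(f"weather records need columns 'date' and '{col}'")
    dates = pd.to_datetime(records["date"])
    in_window = dates.dt.month.isin(month_window)
    window = records.loc[in_window.to_numpy()]
    if window.empty:
        raise TourismError(f"no weather records fall in the {variable} window")
    if (window[col] < 0).any():
        raise TourismError(f"negative {col} amounts")
    total = int(len(window))
    limiting = int((window[col] > threshold).sum())
    return CorrectionFactor(name or variable, limiting, total)


def correction_factor(name: str, limiting_days: int, total_days: int) -> CorrectionFactor:
    """Correction factor from supplied day totals (no daily data needed)."""
    return CorrectionFactor(name, limiting_days, total_days)


def rcc(
    pcc_value: float,
    correction_factors: tuple[CorrectionFactor, ...] | list[CorrectionFactor],
    config: TourismAreaConfig | None = None,
    daily_cap: float | None = None,
) -> TourismCapacityResult:
    """Real carrying capacity from PCC and the correction-factor product.

    The product uses each factor at two decimals; the annual result is
    rounded half-up and the daily result is the annual value divided by
    365, floored.  With no factors RCC equals PCC.
    """
    if pcc_value < 0:
        raise TourismError("PCC must be >= 0")
    product = 1.0
    for cf in correction_factors:
        if not 0.0 <= cf.value <= 1.0:
            raise TourismError(f"correction factor {cf.name} outside [0, 1]")
        product *= cf.value_2dp
    rcc_year = int(round_half_up(pcc_value * product))
    rcc_day = rcc_year // 365
    compliant = None if daily_cap is None else rcc_day <= daily_cap
    return TourismCapacityResult(
        available_area=config.available_area if config else float("nan"),
        tourism_area=config.tourism_area if config else float("nan"),
        pcc=pcc_value,
        correction_factors=tuple(correction_factors),
        rcc_year=rcc_year,
        rcc_day=rcc_day,
        compliant=compliant,
    )


def compliance(
    rcc_day: int, current_daily_visits: float, cap: float = 200.0
) -> ComplianceReport:
    """Check current visitation against min(regulatory cap, daily RCC).

    The binding limit is whichever of the court-ordered daily cap and the
    capacity-derived daily RCC is smaller; headroom is reported against
    that limit.
    """
    if rcc_day < 0 or current_daily_visits < 0 or cap < 0:
        raise TourismError("inputs must be non-negative")
    limit = min(cap, float(rcc_day))
    return ComplianceReport(
        rcc_day=rcc_day,
        current_daily_visits=current_daily_visits,
        cap=cap,
        effective_limit=limit,
        compliant=current_daily_visits <= limit,
        headroom=limit - current_daily_visits,
    )


def project_visitors(series: pd.DataFrame, target_year: int) -> tuple[int, float]:
    """Linear projection of annual visitor counts.

    Fits OLS of count on year and evaluates at ``target_year``.  Returns
    (projected count rounded to an integer, slope in visitors/year).
    """
    for col in ("year", "count"):
        if col not in series.columns:
            raise TourismError(f"visitor series missing column '{col}'")
    if len(series) < 2:
        raise TourismError("need at least two observed years to project")
    if (series["count"] < 0).any():
        raise TourismError("visitor counts must be non-negative")
    years = series["year"].to_numpy(float)
    counts = series["count"].to_numpy(float)
    if series["count"].nunique() == 1:
        return int(round_half_up(float(counts[0]))), 0.0
    res = _scipy_stats.linregress(years, counts)
    projected = res.intercept + res.slope * target_year
    return int(round_half_up(float(projected))), float(res.slope)
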