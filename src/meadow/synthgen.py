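"""Seeded synthetic-data generators for every pipeline input.

No field data are deposited for this assessment, so each analysis stage
is exercised on generated inputs whose statistical structure matches the
study conditions: quadrat occupancy and abundance hitting target density
and frequency per species, Bernoulli heavy-rain/heavy-snow day series,
linear livestock and visitor trends with Gaussian noise, Gaussian soil
chemistry around published zone means, uniform check-dam volumes and
densities rescaled to a target total mass, and multinomial survey
ratings.

Each generator draws from its own substream derived from a single root
seed, so adding a generator never shifts another's draws, and identical
seed + configuration yields byte-identical output files.  ``exact`` mode
(the default for quadrats) places integer totals deterministically so
the analysis stage recovers the target values exactly; stochastic mode
is meant for Monte-Carlo property checks.
"""

from __future__ import annotations

import json
import zlib
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field
from scipy.optimize import brentq
from scipy.stats import truncnorm

from ._rounding import round_half_up

AGE_GROUPS = ("20-40", "40-60", ">60")
SE_VARIABLES = (
    "cost_effectiveness",
    "economic_efficiency",
    "procedural_equity",
    "social_preference",
    "adoption_lag",
    "replicability",
    "technical_sophistication",
    "cultural_values",
    "social_norms",
    "policy_legislation",
    "governance_mechanism",
)


class SynthGenError(ValueError):
    """Raised on infeasible generator targets."""


def substream(seed: int, label: str) -> np.random.Generator:
    """Independent RNG substream for one generator, derived from the root seed."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(label.encode())]))


# ---------------------------------------------------------------------------
# quadrat vegetation


def _ztp_lambda(mean: float) -> float:
    """Rate of a zero-truncated Poisson with the given mean (> 1)."""
    if mean <= 1.0 + 1e-9:
        return 0.0
    return float(brentq(lambda lam: lam / -np.expm1(-lam) - mean, 1e-9, max(10.0, 5 * mean)))


def _draw_ztp(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """Zero-truncated Poisson draws by resampling zeros."""
    if lam <= 0:
        return np.ones(size, dtype=int)
    out = np.zeros(size, dtype=int)
    todo = np.arange(size)
    while todo.size:
        draws = rng.poisson(lam, todo.size)
        ok = draws > 0
        out[todo[ok]] = draws[ok]
        todo = todo[~ok]
    return out


def gen_quadrats(
    targets: pd.DataFrame,
    n_quadrats: int = 30,
    seed: int = 0,
    exact: bool = True,
    zone: str | None = None,
    plot: str = "P1",
) -> pd.DataFrame:
    """Quadrat observations hitting per-species density/frequency targets.

    ``targets`` has columns species, density, frequency_pct (and
    optionally zone; each zone is generated independently).  Each species
    occupies round(frequency/100 × n) quadrats chosen uniformly.  In
    exact mode the integer total round(density × n) is spread as evenly
    as possible over the occupied quadrats, so the quadrat analytics
    recover density and frequency exactly; otherwise per-quadrat counts
    are zero-truncated Poisson with mean total/occupied.
    """
    for col in ("species", "density", "frequency_pct"):
        if col not in targets.columns:
            raise SynthGenError(f"targets missing column '{col}'")
    if (targets["density"] < 0).any():
        raise SynthGenError("target densities must be non-negative")
    if (targets["frequency_pct"] > 100).any() or (targets["frequency_pct"] < 0).any():
        raise SynthGenError("target frequencies must be within [0, 100]")
    if "zone" in targets.columns and zone is None:
        frames = [
            gen_quadrats(grp.drop(columns="zone"), n_quadrats, seed, exact, str(z), plot)
            for z, grp in targets.groupby("zone", sort=True)
        ]
        return pd.concat(frames, ignore_index=True)
    zone = zone or "Z1"
    rng = substream(seed, f"quadrats/{zone}")
    quadrat_ids = [f"Q{i + 1:02d}" for i in range(n_quadrats)]
    rows: list[dict[str, object]] = []
    for _, trg in targets.sort_values("species").iterrows():
        total = int(round_half_up(float(trg["density"]) * n_quadrats))
        occupied = int(round_half_up(float(trg["frequency_pct"]) / 100.0 * n_quadrats))
        if total == 0 or occupied == 0:
            if total != occupied:
                raise SynthGenError(
                    f"{trg['species']}: density and frequency targets disagree "
                    f"(total {total}, occupied {occupied})"
                )
            continue  # species absent
        if total < occupied:
            raise SynthGenError(
                f"{trg['species']}: total {total} individuals cannot occupy "
                f"{occupied} quadrats (abundance below 1)"
            )
        chosen = rng.choice(n_quadrats, size=occupied, replace=False)
        if exact:
            base, rem = divmod(total, occupied)
            counts = np.full(occupied, base, dtype=int)
            counts[:rem] += 1
        else:
            counts = _draw_ztp(rng, _ztp_lambda(total / occupied), occupied)
        for q, c in zip(chosen, counts):
            rows.append(
                {
                    "zone": zone,
                    "plot": plot,
                    "quadrat": quadrat_ids[q],
                    "species": str(trg["species"]),
                    "count": int(c),
                }
            )
    out = pd.DataFrame(rows, columns=["zone", "plot", "quadrat", "species", "count"])
    return out.sort_values(["zone", "species", "quadrat"], kind="mergesort").reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# weather

RAIN_MONTHS = (3, 4, 5, 6, 7, 8, 9, 10, 11)
SNOW_MONTHS = (12, 1, 2)


def gen_weather(
    start: str,
    end: str,
    heavy_rain_prob: float,
    heavy_snow_prob: float,
    seed: int = 0,
    heavy_rain_mm: float = 250.0,
    heavy_snow_cm: float = 8.0,
) -> pd.DataFrame:
    """Daily weather with Bernoulli heavy-rain/heavy-snow exceedances.

    Within March–November each day is a heavy-rain day (amount above the
    threshold) with probability ``heavy_rain_prob``, otherwise a light
    day below it; within December–February heavy-snow days occur with
    probability ``heavy_snow_prob``.  Amounts are exponential above and
    uniform below the thresholds — only the exceedance structure matters
    for the correction factors.
    """
    for p in (heavy_rain_prob, heavy_snow_prob):
        if not 0.0 <= p <= 1.0:
            raise SynthGenError("heavy-day probabilities must be in [0, 1]")
    dates = pd.date_range(start, end, freq="D")
    if dates.empty:
        raise SynthGenError("empty date range")
    rng = substream(seed, "weather")
    rain = np.zeros(len(dates))
    snow = np.zeros(len(dates))
    months = dates.month
    rain_mask = np.isin(months, RAIN_MONTHS)
    snow_mask = np.isin(months, SNOW_MONTHS)
    heavy_rain = rain_mask & (rng.random(len(dates)) < heavy_rain_prob)
    heavy_snow = snow_mask & (rng.random(len(dates)) < heavy_snow_prob)
    rain[rain_mask] = rng.uniform(0.0, 0.2 * heavy_rain_mm, rain_mask.sum())
    rain[heavy_rain] = heavy_rain_mm + rng.exponential(0.2 * heavy_rain_mm, heavy_rain.sum())
    snow[snow_mask] = rng.uniform(0.0, heavy_snow_cm, snow_mask.sum())
    snow[heavy_snow] = heavy_snow_cm + rng.exponential(0.5 * heavy_snow_cm, heavy_snow.sum())
    return pd.DataFrame(
        {
            "date": dates.strftime("%Y-%m-%d"),
            "rain_mm": np.round(rain, 1),
            "snow_cm": np.round(snow, 1),
        }
    )


# ---------------------------------------------------------------------------
# livestock and visitors


def gen_livestock(
    years: Sequence[int],
    intercept: float,
    slope: float,
    noise_sigma: float,
    au_table: pd.DataFrame,
    seed: int = 0,
    year0: int | None = None,
) -> pd.DataFrame:
    """Livestock census whose cow-unit totals follow a noisy linear trend.

    Yearly CU targets are intercept + slope × (year − year0) + Gaussian
    noise, rounded to integers.  Each target is decomposed into animal
    counts consistent with the animal-unit table: migratory horses and
    goats plus local sheep take fixed shares, and local cows (1 CU each)
    absorb the integer remainder so the cow-unit conversion returns the
    target exactly.  Infeasible (negative) cow counts are clipped at zero
    with a warning.
    """
    if not len(years):
        raise SynthGenError("need at least one census year")
    rng = substream(seed, "livestock")
    year0 = int(year0 if year0 is not None else min(years))
    au = au_table.set_index("animal")["animal_unit"]
    rows: list[dict[str, object]] = []
    for year in years:
        target = intercept + slope * (year - year0) + rng.normal(0.0, noise_sigma)
        target_cu = max(0, int(round_half_up(target)))
        horses = int(0.25 * target_cu / au["horse"])
        goats = int(0.15 * target_cu / au["goat"])
        sheep = int(0.15 * target_cu / au["sheep"])
        migratory_cu = int(round_half_up(horses * au["horse"] + goats * au["goat"]))
        sheep_cu = int(round_half_up(sheep * au["sheep"]))
        cows = target_cu - migratory_cu - sheep_cu
        if cows < 0:
            import warnings

            warnings.warn(
                f"{year}: cow count clipped at 0 (decomposition overshoots "
                f"the {target_cu} CU target)",
                stacklevel=2,
            )
            cows = 0
        rows += [
            {"year": year, "animal": "horse", "count": horses, "origin": "migratory"},
            {"year": year, "animal": "goat", "count": goats, "origin": "migratory"},
            {"year": year, "animal": "cow", "count": cows, "origin": "local"},
            {"year": year, "animal": "sheep", "count": sheep, "origin": "local"},
        ]
    return pd.DataFrame(rows)


def gen_visitors(
    years: Sequence[int],
    intercept: float,
    slope: float,
    noise_sigma: float,
    seed: int = 0,
    year0: int | None = None,
) -> pd.DataFrame:
    """Annual visitor counts on a noisy linear trend, clipped at zero."""
    if not len(years):
        raise SynthGenError("need at least one visitor year")
    rng = substream(seed, "visitors")
    year0 = int(year0 if year0 is not None else min(years))
    counts = [
        max(0, int(round_half_up(intercept + slope * (y - year0) + rng.normal(0.0, noise_sigma))))
        for y in years
    ]
    return pd.DataFrame({"year": list(years), "count": counts})


# ---------------------------------------------------------------------------
# check dams


def gen_checkdams(
    n: int = 38,
    volume_range: tuple[float, float] = (1.0, 6.0),
    density_range: tuple[float, float] = (1.1, 1.6),
    target_total: float = 169.64,
    seed: int = 0,
    n_gullies: int = 3,
) -> pd.DataFrame:
    """Check dams with uniform volumes/densities rescaled to a target mass.

    Volumes and triplicate core densities are drawn uniformly in their
    ranges, then all volumes are scaled by one factor so the summed
    debris mass equals ``target_total`` exactly.  Dams are assigned
    round-robin to gullies.
    """
    if n < 1:
        raise SynthGenError("need at least one dam")
    if target_total < 0:
        raise SynthGenError("target_total must be >= 0")
    rng = substream(seed, "checkdams")
    volumes = rng.uniform(*volume_range, n)
    rhos = rng.uniform(*density_range, (n, 3))
    masses = volumes * rhos.mean(axis=1)
    scale = 0.0 if target_total == 0 else target_total / masses.sum()
    volumes = volumes * scale
    return pd.DataFrame(
        {
            "dam": [f"D{i + 1:02d}" for i in range(n)],
            "gully": [f"G{i % n_gullies + 1}" for i in range(n)],
            "volume_m3": volumes,
            "rho1": rhos[:, 0],
            "rho2": rhos[:, 1],
            "rho3": rhos[:, 2],
        }
    )


# ---------------------------------------------------------------------------
# soil chemistry

_SOIL_BOUNDS = {
    "soil_ph": (0.0, 14.0),
}


def _soil_bounds(variable: str) -> tuple[float, float]:
    if variable in _SOIL_BOUNDS:
        return _SOIL_BOUNDS[variable]
    if variable.endswith("_pct"):
        return (0.0, 100.0)
    return (0.0, np.inf)


def gen_soil(
    zone_stats: pd.DataFrame, n_replicates: int = 3, seed: int = 0
) -> pd.DataFrame:
    """Replicate soil measurements: truncated Gaussians around zone means.

    ``zone_stats`` has columns zone, variable, mean, se; draws use the
    tabulated dispersion as the per-replicate standard deviation and are
    truncated to each variable's physical range (pH within 0–14,
    percentages within 0–100, otherwise non-negative).
    """
    for col in ("zone", "variable", "mean", "se"):
        if col not in zone_stats.columns:
            raise SynthGenError(f"zone stats missing column '{col}'")
    if (zone_stats["se"] < 0).any():
        raise SynthGenError("standard errors must be non-negative")
    rng = substream(seed, "soil")
    rows: list[dict[str, object]] = []
    for _, rec in zone_stats.sort_values(["zone", "variable"]).iterrows():
        mean, se = float(rec["mean"]), float(rec["se"])
        lo, hi = _soil_bounds(str(rec["variable"]))
        if se == 0:
            draws = np.full(n_replicates, mean)
        else:
            a, b = (lo - mean) / se, (hi - mean) / se
            draws = truncnorm.rvs(a, b, loc=mean, scale=se, size=n_replicates, random_state=rng)
        for i, v in enumerate(draws):
            rows.append(
                {
                    "zone": rec["zone"],
                    "variable": rec["variable"],
                    "replicate": i + 1,
                    "value": float(v),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# survey


def gen_survey(
    probs_per_variable: Mapping[str, Sequence[float]],
    n_respondents_per_village: int = 60,
    villages: Sequence[str] = ("Barsu", "Raithal"),
    seed: int = 0,
) -> pd.DataFrame:
    """Multinomial low/moderate/high survey ratings per variable.

    Each village contributes ``n_respondents_per_village`` respondents,
    spread over three age groups; every respondent rates every variable,
    drawing L/M/H with that variable's probability vector.
    """
    for var, p in probs_per_variable.items():
        p = np.asarray(p, dtype=float)
        if p.shape != (3,) or (p < 0).any() or not np.isclose(p.sum(), 1.0):
            raise SynthGenError(f"{var}: rating probabilities must be 3 values summing to 1")
    rng = substream(seed, "survey")
    rows: list[dict[str, object]] = []
    rid = 0
    for village in villages:
        for _ in range(n_respondents_per_village):
            rid += 1
            age = AGE_GROUPS[rng.integers(0, len(AGE_GROUPS))]
            for var, p in probs_per_variable.items():
                rating = ("L", "M", "H")[rng.choice(3, p=np.asarray(p, dtype=float))]
                rows.append(
                    {
                        "respondent": f"R{rid:03d}",
                        "village": village,
                        "age_group": age,
                        "variable": var,
                        "rating": rating,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full dataset


class GeneratorConfig(BaseModel):
    """Defaults mirror the study conditions the analysis assumes."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    n_quadrats: int = 30
    weather_start: str = "2017-01-01"
    weather_end: str = "2019-12-31"
    heavy_rain_prob: float = 369 / 909
    heavy_snow_prob: float = 51 / 186
    livestock_years: tuple[int, ...] = tuple(range(2007, 2020))
    livestock_intercept: float = 881.0  # CU in the anchor year
    livestock_slope: float = -20.0  # CU per year
    livestock_sigma: float = 10.0
    livestock_year0: int = 2019
    visitor_years: tuple[int, ...] = (2015, 2016, 2017, 2018, 2019)
    visitor_intercept: float = 19_710.0  # ~54/day in the anchor year
    visitor_slope: float = 2850.0
    visitor_sigma: float = 300.0
    visitor_year0: int = 2019
    n_dams: int = 38
    dam_volume_range: tuple[float, float] = (1.0, 6.0)
    dam_density_range: tuple[float, float] = (1.1, 1.6)
    dam_target_total: float = 169.64
    soil_replicates: int = 3
    survey_respondents_per_village: int = 60
    survey_probs: dict[str, tuple[float, float, float]] = Field(
        default_factory=lambda: {v: (0.1, 0.3, 0.6) for v in SE_VARIABLES}
    )
    quadrat_exact: bool = True


def generate_all(config: GeneratorConfig, outdir: str | Path) -> dict[str, Path]:
    """Write every synthetic input CSV plus a manifest of config + seed."""
    from . import datasets

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    files: dict[str, Path] = {}

    quadrats = gen_quadrats(
        datasets.load_zone_vegetation(),
        n_quadrats=config.n_quadrats,
        seed=seed,
        exact=config.quadrat_exact,
    )
    weather = gen_weather(
        config.weather_start,
        config.weather_end,
        config.heavy_rain_prob,
        config.heavy_snow_prob,
        seed=seed,
    )
    livestock = gen_livestock(
        config.livestock_years,
        config.livestock_intercept,
        config.livestock_slope,
        config.livestock_sigma,
        datasets.load_animal_units(),
        seed=seed,
        year0=config.livestock_year0,
    )
    visitors = gen_visitors(
        config.visitor_years,
        config.visitor_intercept,
        config.visitor_slope,
        config.visitor_sigma,
        seed=seed,
        year0=config.visitor_year0,
    )
    dams = gen_checkdams(
        config.n_dams,
        config.dam_volume_range,
        config.dam_density_range,
        config.dam_target_total,
        seed=seed,
    )
    soil = gen_soil(datasets.load_soil_chemistry(), config.soil_replicates, seed=seed)
    survey = gen_survey(
        config.survey_probs,
        config.survey_respondents_per_village,
        seed=seed,
    )
    for name, frame in {
        "quadrats": quadrats,
        "weather": weather,
        "livestock": livestock,
        "visitors": visitors,
        "checkdams": dams,
        "soil": soil,
        "survey": survey,
    }.items():
        path = outdir / f"{name}.csv"
        frame.to_csv(path, index=False, float_format="%.6g")
        files[name] = path
    manifest = outdir / "manifest.json"
    manifest.write_text(
        json.dumps({"seed": seed, "config": config.model_dump()}, indent=2, sort_keys=True,
                   default=list)
        + "\n",
        encoding="utf-8",
    )
    files["manifest"] = manifest
    return files
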