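"""Multi-criteria restoration scorecard.

Restoration success is judged over three categories — direct management
measures (M: grazing, tourism, erosion control), environmental
desirability (E: vegetation and soil chemistry), and socio-economic
feasibility (SE: village-survey ratings).  Each measured variable is
placed in one of three quality bands (satisfactory / average / not
satisfactory) against published threshold criteria and scored on a 0–3
scale (3 for satisfactory, 0 for not satisfactory, a configurable
mid-score — default 1.5 — for average).  Then

    category index     = Σ variable scores / (3 × n variables)   ∈ [0, 1]
    evaluation index   = Σ category score totals / max_score × 100,

with ``max_score`` a configured ceiling (default 16, the published
convention), clamped to [0, 100].  Survey responses rated low/moderate/
high map onto the same 0 / 1.5 / 3 scale.  An ecosystem index compares
zones (reference, treated, degraded) on the M + E variables only,
reporting each zone's percent score with its standard error.

Band conventions: bands are closed intervals checked in quality order
(satisfactory first), so a value on a shared boundary always lands in
the better band; the shipped criteria profile is validated at load time
to cover each variable's full domain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from math import inf, isfinite, sqrt
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from ._rounding import round_half_up

LEVELS = ("satisfactory", "average", "not_satisfactory")
DEFAULT_MID_SCORE = 1.5
MAX_VARIABLE_SCORE = 3.0
DEFAULT_MAX_SCORE = 16.0
RATING_SCORES = {"L": 0.0, "M": DEFAULT_MID_SCORE, "H": MAX_VARIABLE_SCORE}


class ScorecardError(ValueError):
    """Raised on invalid scoring inputs or a malformed criteria profile."""


@dataclass(frozen=True)
class Band:
    level: str
    lo: float
    hi: float  # closed interval [lo, hi]; hi may be +inf

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ScorecardError(f"unknown band level {self.level!r}")
        if self.lo > self.hi:
            raise ScorecardError(f"band {self.level}: lo {self.lo} > hi {self.hi}")

    def contains(self, value: float) -> bool:
        return self.lo <= value <= self.hi


@dataclass(frozen=True)
class ScoringCriterion:
    variable: str
    category: str  # M, E or SE
    direction: str  # higher-better | lower-better | target-band
    bands: tuple[Band, ...]
    unit: str = ""
    domain: tuple[float, float] = (0.0, inf)

    def __post_init__(self) -> None:
        self._validate_totality()

    def _validate_totality(self) -> None:
        """The union of bands must cover the whole value domain."""
        lo, hi = self.domain
        intervals = sorted((b.lo, b.hi) for b in self.bands)
        if not intervals:
            raise ScorecardError(f"{self.variable}: no bands defined")
        covered = lo
        for b_lo, b_hi in intervals:
            if b_lo > covered:
                raise ScorecardError(
                    f"{self.variable}: band gap between {covered} and {b_lo}"
                )
            covered = max(covered, b_hi)
        if covered < hi:
            raise ScorecardError(
                f"{self.variable}: values above {covered} fall outside all bands"
            )

    def classify(self, value: float) -> str:
        """Band level for a value; boundary values go to the better band."""
        if not isfinite(value):
            raise ScorecardError(f"{self.variable}: value must be finite")
        lo, hi = self.domain
        if not lo <= value <= hi:
            raise ScorecardError(
                f"{self.variable}: value {value} outside domain [{lo}, {hi}]"
            )
        for level in LEVELS:  # quality order: better band wins boundaries
            for band in self.bands:
                if band.level == level and band.contains(value):
                    return level
        raise ScorecardError(f"{self.variable}: value {value} matched no band")


@dataclass(frozen=True)
class VariableScore:
    variable: str
    raw_value: float
    level: str
    score: float
    category: str = ""


@dataclass(frozen=True)
class CategoryIndex:
    category: str
    variable_scores: tuple[VariableScore, ...]
    total: float  # Σ variable scores (the category's raw score sum)
    index: float  # Σ scores / (3 × n), in [0, 1]


@dataclass(frozen=True)
class EcosystemZoneScore:
    zone: str
    percent_score: float  # mean over replicates
    standard_error: float
    replicate_scores: tuple[float, ...] = field(default=(), repr=False)


@dataclass(frozen=True)
class SurveyAggregate:
    variable_scores: dict[str, float]  # mean 0-3 score per SE variable
    n_respondents: int
    rating_proportions: pd.DataFrame  # by village / age group / rating


def score_variable(
    value: float,
    criterion: ScoringCriterion,
    mid_score: float = DEFAULT_MID_SCORE,
) -> VariableScore:
    """Score a measured value against its banded criterion (0–3 scale)."""
    if not 0.0 <= mid_score <= MAX_VARIABLE_SCORE:
        raise ScorecardError("mid_score must be within [0, 3]")
    level = criterion.classify(value)
    score = {
        "satisfactory": MAX_VARIABLE_SCORE,
        "average": mid_score,
        "not_satisfactory": 0.0,
    }[level]
    return VariableScore(
        variable=criterion.variable,
        raw_value=value,
        level=level,
        score=score,
        category=criterion.category,
    )


def category_index(
    scores: Sequence[VariableScore], category: str = ""
) -> CategoryIndex:
    """Category index: sum of variable scores over the maximum 3 × n."""
    if not scores:
        raise ScorecardError("category index needs at least one variable score")
    total = float(sum(s.score for s in scores))
    return CategoryIndex(
        category=category or scores[0].category,
        variable_scores=tuple(scores),
        total=total,
        index=total / (MAX_VARIABLE_SCORE * len(scores)),
    )


def evaluation_index(
    categories: Iterable[CategoryIndex | float], max_score: float = DEFAULT_MAX_SCORE
) -> float:
    """Restoration evaluation index (percent of the configured maximum).

    Sums the categories' raw score totals (floats are accepted as
    pre-summed totals), divides by ``max_score`` and scales to percent,
    clamped to [0, 100].
    """
    if max_score <= 0:
        raise ScorecardError("max_score must be > 0")
    raw = sum(c.total if isinstance(c, CategoryIndex) else float(c) for c in categories)
    return min(100.0, max(0.0, raw / max_score * 100.0))


def aggregate_survey(
    responses: pd.DataFrame,
    expected_variables: Sequence[str] | None = None,
    rating_scores: Mapping[str, float] = RATING_SCORES,
) -> SurveyAggregate:
    """Aggregate low/moderate/high survey ratings into 0–3 variable scores.

    ``responses`` has columns respondent, village, age_group, variable,
    rating.  Each rating maps to a score (L→0, M→1.5, H→3 by default) and
    scores are averaged per variable over respondents.  Variables listed
    in ``expected_variables`` but absent from the responses are excluded
    with a warning rather than scored zero.  Rating proportions per
    village and age group are reported alongside for survey diagnostics.
    """
    needed = {"respondent", "village", "age_group", "variable", "rating"}
    missing = needed - set(responses.columns)
    if missing:
        raise ScorecardError(f"survey responses missing columns: {sorted(missing)}")
    if responses.empty:
        raise ScorecardError("no survey responses")
    bad = set(responses["rating"]) - set(rating_scores)
    if bad:
        raise ScorecardError(f"unknown ratings {sorted(bad)}; expected {sorted(rating_scores)}")
    work = responses.copy()
    work["score"] = work["rating"].map(rating_scores)
    means = work.groupby("variable", sort=True)["score"].mean()
    if expected_variables is not None:
        absent = [v for v in expected_variables if v not in means.index]
        if absent:
            warnings.warn(
                f"survey variables with no responses excluded: {absent}", stacklevel=2
            )
    props = (
        work.groupby(["village", "age_group", "rating"], sort=True)["respondent"]
        .count()
        .rename("n")
        .reset_index()
    )
    props["proportion"] = props.groupby(["village", "age_group"])["n"].transform(
        lambda s: s / s.sum()
    )
    return SurveyAggregate(
        variable_scores={str(k): float(v) for k, v in means.items()},
        n_respondents=int(work["respondent"].nunique()),
        rating_proportions=props,
    )


def ecosystem_index(
    zone: str,
    replicate_values: pd.DataFrame,
    criteria: Mapping[str, ScoringCriterion],
    mid_score: float = DEFAULT_MID_SCORE,
) -> EcosystemZoneScore:
    """Percent ecosystem score of one zone from replicate measurements.

    ``replicate_values`` has columns replicate, variable, value; each
    replicate must supply every variable it is scored on (a missing
    variable is an error, not a silent shrink, because replicates are
    compared on a common denominator).  Per replicate the percent score
    is Σ scores / (3 × n variables) × 100; the zone mean and its standard
    error over replicates are reported.
    """
    for col in ("replicate", "variable", "value"):
        if col not in replicate_values.columns:
            raise ScorecardError(f"replicate values missing column '{col}'")
    if replicate_values.empty:
        raise ScorecardError(f"zone {zone}: no replicate values")
    variables = sorted(replicate_values["variable"].unique())
    unknown = [v for v in variables if v not in criteria]
    if unknown:
        raise ScorecardError(f"zone {zone}: no criterion for variables {unknown}")
    percents: list[float] = []
    for rep, grp in replicate_values.groupby("replicate", sort=True):
        have = set(grp["variable"])
        absent = [v for v in variables if v not in have]
        if absent:
            raise ScorecardError(f"zone {zone}, replicate {rep}: missing {absent}")
        total = sum(
            score_variable(float(row["value"]), criteria[row["variable"]], mid_score).score
            for _, row in grp.iterrows()
        )
        percents.append(total / (MAX_VARIABLE_SCORE * len(variables)) * 100.0)
    mean = sum(percents) / len(percents)
    if len(percents) > 1:
        var = sum((p - mean) ** 2 for p in percents) / (len(percents) - 1)
        se = sqrt(var / len(percents))
    else:
        se = 0.0
    return EcosystemZoneScore(
        zone=zone,
        percent_score=mean,
        standard_error=se,
        replicate_scores=tuple(percents),
    )


def rank_zones(
    scores: Sequence[EcosystemZoneScore],
) -> list[dict[str, object]]:
    """Zones in descending ecosystem score with mean ± SE and tie flags.

    Equal scores keep their input order and are flagged as tied; no
    hypothesis testing is attempted here.
    """
    if len(scores) < 2:
        raise ScorecardError("ranking needs at least two zones")
    ordered = sorted(
        enumerate(scores), key=lambda pair: (-pair[1].percent_score, pair[0])
    )
    values = [s.percent_score for _, s in ordered]
    return [
        {
            "rank": i + 1,
            "zone": s.zone,
            "percent_score": round_half_up(s.percent_score, 2),
            "standard_error": round_half_up(s.standard_error, 2),
            "tied": values.count(s.percent_score) > 1,
        }
        for i, (_, s) in enumerate(ordered)
    ]


def load_criteria(path: str | Path | None = None) -> dict[str, ScoringCriterion]:
    """Load a banded criteria profile from YAML (the packaged one by default).

    Profile schema::

        variables:
          soil_ph:
            category: E
            direction: target-band
            unit: pH
            domain: [0, 14]
            bands:
              satisfactory: [[4.7, 5.3]]
              average: [[4.0, 4.7], [5.3, 14]]
              not_satisfactory: [[0, 4.0]]

    Interval bounds are closed; ``.inf`` marks an open upper domain.
    Every criterion is totality-checked on load.
    """
    if path is None:
        source = resources.files("meadow.fixtures").joinpath("scoring_criteria.yaml")
        raw = yaml.safe_load(source.read_text(encoding="utf-8"))
    else:
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(raw, dict) or "variables" not in raw:
        raise ScorecardError("criteria profile must define a 'variables' mapping")
    out: dict[str, ScoringCriterion] = {}
    for name, entry in raw["variables"].items():
        bands = tuple(
            Band(level=level, lo=float(lo), hi=float(hi))
            for level, intervals in entry["bands"].items()
            for lo, hi in intervals
        )
        domain = tuple(float(x) for x in entry.get("domain", (0.0, inf)))
        out[name] = ScoringCriterion(
            variable=name,
            category=entry.get("category", ""),
            direction=entry.get("direction", "target-band"),
            bands=bands,
            unit=entry.get("unit", ""),
            domain=(domain[0], domain[1]),
        )
    return out
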