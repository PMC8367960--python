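# Methods

This note records the models, parameter choices, numerical conventions
and known limitations behind the package. Everything quantitative here
is computed by the code and its tests; nothing is asserted that the
suite does not itself check.

## Quadrat vegetation analytics

Statistics pool all 30 quadrats of a zone (quadrat area 1 m²). Plot
structure is carried as metadata only; the per-zone tables the package
reproduces report a single value per species per zone. Quadrats with no
individuals are legal and stay in the denominator, which is why the
survey design carries `n_quadrats` explicitly rather than inferring it
from the data. Frequencies are computed over 30 quadrats — that choice
reproduces the published values exactly (e.g. 22/30 → 73.33%), whereas
a triplicate denominator of 90 would not.

Species observed in no quadrat are omitted rather than reported with an
undefined 0/0 abundance. Dominant-community labels order species by
descending density with alphabetical tie-breaks (no published rule
exists; alphabetical is deterministic and explainable). All statistics
are stored un-rounded; a single half-up rounding helper produces the
2-decimal presentation used for table comparisons.

## Grazing capacity

Unit chain: 1 g/m² over 1 km² is 10⁶ g = 10 quintal, so yield in
quintals is `biomass × area_km2 × 10`. The grazing area defaults to
4.235 km² because that constant reproduces the published per-species
yields; a differently-printed 3.235 km² figure accompanies the capacity
formula in the source material and is carried in the config as
`eq4_note_area`, documented as unused.

Rounding conventions, chosen to match how the published chain prints:
standard forage truncates to whole quintals (10,003 × 0.5 → 5001);
capacities and cow-unit totals round half-up to integers. Per-origin
census groups are rounded before summing.

The animal-unit table is internally inconsistent: the tabulated AU
column does not everywhere equal forage requirement / 7.5 (horse:
9.38/7.5 = 1.25 vs tabulated 1.18). Default behaviour uses the
tabulated column verbatim so census totals reproduce; `derive_au=True`
(CLI `--au-derive`) recomputes AU from the requirement to expose the
discrepancy. Palatability is an input flag on the species table, never
inferred from the data.

Trend estimation (cow units and visitors against calendar year) is
ordinary least squares via `scipy.stats.linregress`; constant series
return a slope of exactly zero.

## Tourist carrying capacity

`PCC = (A/Au) × Rf` with A the configured tourism fraction of
(total − fragile) area. Correction factors are truncated — not
half-up rounded — to two decimals before entering the RCC product:
truncation is the only convention consistent with both published
factors (1 − 369/909 = 0.594 → 0.59 and 1 − 51/186 = 0.7258 → 0.72).
Raw factor values are retained on the `CorrectionFactor` object for
diagnostics. Annual RCC rounds half-up; daily RCC is annual / 365,
floored (the published 274/day implies a 365-day divisor, not an
open-season one). The 15%-scenario annual figure is printed in two
variants one apart (100,116 / 100,117); half-up rounding yields 100,117
and comparisons allow ±1.

The recorded season-day totals (909 rain-window days, 186 snow-window
days over 2017–2019) do not match the Gregorian calendar for those
windows (825 / 271). They are therefore accepted as supplied totals via
`correction_factor(limiting, total)`; `correction_factor_from_weather`
computes true calendar counts when daily records exist. Thresholds
(250 mm, 8 cm), month windows and the 200/day regulatory cap are all
config entries.

Compliance uses the binding limit `min(cap, RCC_day)` and reports
headroom against it.

## Check-dam sediment accounting

`Md = V × mean(ρb)` with g/cm³ ≡ t/m³, so a 1 m³ dam at 1 g/cm³ holds
exactly 1 t. The default core is 2.5 cm radius × 30 cm height
(589.049 cm³). Per-dam volumes are not published, so the synthetic
generator produces 38 dams across 3 gullies with uniform volumes and
triplicate densities, rescaled by a single factor so the summed mass
hits a configurable target (169.64 t by default); the headline
0.5 t/ha/yr rate over 338 ha is thus a generator-calibration property,
checked as such. The 338 ha accounting area (the 3.38 km² meadow
extent) is a config key distinct from the grazing and tourism areas.
An empty dam set yields a zero summary with a warning, not an error.

## Restoration scorecard

Bands are closed intervals checked in quality order (satisfactory,
average, not-satisfactory), which implements "a shared boundary belongs
to the better band" (pH exactly 4.7 is satisfactory; 285 CU is
satisfactory; WHC exactly 50% is satisfactory). The published criteria
leave the high side of the two target-band variables uncovered
(pH > 5.3, WHC > 60%); the shipped profile assigns those regions to
"average" — off-target but not failing — so every criterion covers its
full domain, a property validated at load time.

The score for the "average" band is not published; the default 1.5 is
the midpoint of the 0–3 scale and is configurable (`mid_score`).
Survey ratings map L/M/H → 0/1.5/3 on the same scale. Missing survey
variables shrink the category denominator rather than scoring zero.

The evaluation-index maximum of 16 cannot be derived from the variable
taxonomy (3 categories × 3 = 9; 22 variables × 3 = 66); it is kept as a
configurable convention defaulting to 16, and the published 69.31 =
11.09/16 × 100 value is used only as an arithmetic consistency check.
Because category totals can exceed 16, the index is clamped to
[0, 100].

The ecosystem zone comparison scores the management + environment
variables per replicate on a common denominator (a missing variable in
a replicate is an error, not a silent shrink) and reports mean ± SE per
zone. Management variables are area-wide and repeat across zones.
Vegetation cover per zone is never published; the packaged values
(75/55/25% for reference/treated/degraded) are synthetic, labelled so,
and the reference > treated > degraded ordering already holds on the
soil variables alone. No hypothesis testing is performed — ranking
stops at ordering with tie flags.

## Synthetic-data generators

Each generator draws from a substream derived from one root seed (via
`SeedSequence([seed, crc32(label)])`), so adding a generator never
shifts another's draws; identical seed + config produce byte-identical
files. Study-condition defaults: 30 quadrats; heavy-day probabilities
369/909 and 51/186 over 2017–2019; livestock anchored at 881 CU in
2019 with a −20 CU/yr trend (σ = 10); visitors anchored at ~54/day in
2019 with a +2850/yr trend (σ = 300, 2015–2019); 38 dams targeting
169.64 t; soil replicates drawn as truncated Gaussians (pH in [0, 14],
percentages in [0, 100]) using the tabulated dispersion as the
per-replicate spread; survey ratings multinomial with default
(0.1, 0.3, 0.6) over L/M/H for 60 respondents in each of two villages.

Quadrat generation in exact mode places `round(density × n)`
individuals into `round(frequency/100 × n)` uniformly chosen quadrats
as evenly as possible, so the analytics recover the targets exactly —
this is the default for fixtures. Stochastic mode draws zero-truncated
Poisson counts (rate solved so the expected total matches the target)
and is used for Monte-Carlo recovery checks. Livestock decomposition
lets local cows (1 CU each) absorb the integer remainder so the rounded
cow-unit pipeline returns the yearly target exactly; infeasible
negative cow counts clip to zero with a warning.

What the generators do *not* emulate: spatial structure of quadrat
placement, within-season forage dynamics, weather autocorrelation,
respondent-level correlation across survey variables. Passing tests
therefore demonstrate the arithmetic chain and its calibration, not
ecological realism of the inputs.

## Problem sizes and limitations

All computations are desk-scale: the test suite runs in a few seconds
and the acceptance script in under a second (tourism arithmetic on
scalar inputs; Monte-Carlo checks use ≤ 200 replicates of 30-quadrat
surveys). Known limitations: one ambiguous row in the packaged forage
table (its printed digits are internally inconsistent and it is flagged
`ambiguous`); the published category indices (0.8 / 0.56) and zone
scores (88 / 72 / 55.61) depend on unavailable per-variable data and
are reproduced only as orderings and consistency identities; no
erosion-process modelling, no diversity indices beyond richness, no
ANOVA/discriminant analysis.
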