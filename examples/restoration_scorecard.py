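"""Banded scoring and the per-zone ecosystem comparison.

Scores the treated zone's soil chemistry against the published threshold
bands (3 = satisfactory, 1.5 = average, 0 = not satisfactory), builds
the environmental category index, and ranks the three zones on their
ecosystem percent scores.
"""

import pandas as pd

from meadow import datasets, scorecard

criteria = datasets.load_scoring_criteria()
soil = datasets.load_soil_chemistry()

gtz = soil.query("zone == 'GTZ' and variable in @criteria")
scores = [
    scorecard.score_variable(row["mean"], criteria[row["variable"]])
    for _, row in gtz.iterrows()
]
for s in scores:
    print(f"{s.variable:28s} {s.raw_value:7.2f} -> {s.level:16s} score {s.score}")
ci = scorecard.category_index(scores, "E")
print(f"\nE category index: {ci.total:.1f}/{3 * len(scores)} = {ci.index:.2f}")

cover = datasets.load_vegetation_cover().set_index("zone")
zone_scores = []
for zone, grp in soil.groupby("zone"):
    rows = [
        {"replicate": 1, "variable": r["variable"], "value": r["mean"]}
        for _, r in grp.iterrows()
        if r["variable"] in criteria
    ]
    rows.append({"replicate": 1, "variable": "vegetation_cover_pct",
                 "value": cover.loc[zone, "vegetation_cover_pct"]})
    zone_scores.append(scorecard.ecosystem_index(str(zone), pd.DataFrame(rows), criteria))

print("\nzone ranking:")
for entry in scorecard.rank_zones(zone_scores):
    print(f"  {entry['rank']}. {entry['zone']:4s} {entry['percent_score']}%")
# The untouched reference zone scores highest, the geotextile-treated
# zone sits in between, and the untreated degraded zone scores lowest -
# the treatment has moved the site partway back toward reference state.
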