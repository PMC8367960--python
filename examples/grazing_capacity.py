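"""Grazing chain: forage yield -> standard forage -> capacity -> balance.

Loads the 37 palatable forage species, computes the meadow's dry-forage
yield over the 4.235 km² grazing area, halves it at the 50% utilization
rate, converts to cow units over the 153-day season, and compares with
the 2019 livestock load.
"""

from meadow import datasets, forage

species = datasets.load_forage_species()
total_yield = forage.total_forage_yield(species, area_km2=4.235)
f = forage.standard_forage(total_yield, ui=0.5, ci=1.0)
capacity = forage.grazing_capacity(f, intake_kg_day=7.5, days=153)

census = datasets.load_livestock_census()
cu = forage.to_cow_units(census, datasets.load_animal_units())
surplus = forage.grazing_balance(cu["total"], capacity)

print(f"total forage yield:  {total_yield:.0f} quintal/yr")
print(f"standard dry forage: {f} quintal/yr")
print(f"grazing capacity:    {capacity} cow units/yr")
print(f"grazed load 2019:    {cu['total']} CU "
      f"({cu['migratory']} migratory + {cu['local']} local)")
print(f"surplus:             {surplus} CU above capacity")
# The meadow can carry ~436 cow units but ~881 graze it: about 445 CU
# would need to be shifted elsewhere to bring grazing within capacity.
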