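# Banded scoring criteria for the restoration scorecard.
# Intervals are closed; membership is checked in quality order
# (satisfactory, average, not_satisfactory) so shared boundaries land in
# the better band. The high side of the pH and water-holding-capacity
# target bands is assigned to "average" (off-target, not failing) so the
# profile covers each variable's full domain.
variables:
  grazing_cu:
    category: M
    direction: lower-better
    unit: cow units
    domain: [0, .inf]
    bands:
      satisfactory: [[0, 285]]
      average: [[285, 857]]
      not_satisfactory: [[857, .inf]]
  tourists_per_day:
    category: M
    direction: lower-better
    unit: tourists/day
    domain: [0, .inf]
    bands:
      satisfactory: [[0, 65]]
      average: [[65, 200]]
      not_satisfactory: [[200, .inf]]
  erosion_t_ha_yr:
    category: M
    direction: lower-better
    unit: t/ha/yr
    domain: [0, .inf]
    bands:
      satisfactory: [[0, 5]]
      average: [[5, 35]]
      not_satisfactory: [[35, .inf]]
  vegetation_cover_pct:
    category: E
    direction: higher-better
    unit: "%"
    domain: [0, 100]
    bands:
      satisfactory: [[60, 100]]
      average: [[30, 60]]
      not_satisfactory: [[0, 30]]
  soil_ph:
    category: E
    direction: target-band
    unit: pH
    domain: [0, 14]
    bands:
      satisfactory: [[4.7, 5.3]]
      average: [[4.0, 4.7], [5.3, 14]]
      not_satisfactory: [[0, 4.0]]
  organic_carbon_pct:
    category: E
    direction: higher-better
    unit: "%"
    domain: [0, 100]
    bands:
      satisfactory: [[7.5, 100]]
      average: [[5.0, 7.5]]
      not_satisfactory: [[0, 5.0]]
  nitrogen_pct:
    category: E
    direction: higher-better
    unit: "%"
    domain: [0, 100]
    bands:
      satisfactory: [[0.75, 100]]
      average: [[0.50, 0.75]]
      not_satisfactory: [[0, 0.50]]
  phosphorus_pct:
    category: E
    direction: higher-better
    unit: "%"
    domain: [0, 100]
    bands:
      satisfactory: [[0.50, 100]]
      average: [[0.25, 0.50]]
      not_satisfactory: [[0, 0.25]]
  potassium_pct:
    category: E
    direction: higher-better
    unit: "%"
    domain: [0, 100]
    bands:
      satisfactory: [[2, 100]]
      average: [[1, 2]]
      not_satisfactory: [[0, 1]]
  water_holding_capacity_pct:
    category: E
    direction: target-band
    unit: "%"
    domain: [0, 100]
    bands:
      satisfactory: [[50, 60]]
      average: [[40, 50], [60, 100]]
      not_satisfactory: [[0, 40]]
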