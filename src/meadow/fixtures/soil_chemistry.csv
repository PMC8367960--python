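zone,variable,mean,se
R,total_herb_density,19.77,0.04
R,soil_ph,5.15,0.24
R,organic_carbon_pct,6.64,0.26
R,nitrogen_pct,0.133,0.01
R,phosphorus_pct,0.35,0.04
R,potassium_pct,0.81,0.02
R,water_holding_capacity_pct,56.96,0.13
GTZ,total_herb_density,10.56,0.02
GTZ,soil_ph,4.96,0.28
GTZ,organic_carbon_pct,4.83,0.04
GTZ,nitrogen_pct,0.09,0.03
GTZ,phosphorus_pct,0.29,0.03
GTZ,potassium_pct,0.78,0.04
GTZ,water_holding_capacity_pct,49.85,0.13
UTZ,total_herb_density,3.7,0.05
UTZ,soil_ph,4.69,0.21
UTZ,organic_carbon_pct,3.76,0.14
UTZ,nitrogen_pct,0.047,0.02
UTZ,phosphorus_pct,0.14,0.01
UTZ,potassium_pct,0.26,0.02
UTZ,water_holding_capacity_pct,47.76,0.59
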