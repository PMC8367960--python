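zone,species,density,frequency_pct,abundance
R,Achillea millefolium,1.40,73.33,1.91
R,Allium humile,0.70,36.67,1.91
R,Anaphalis contorta,0.77,43.33,1.77
R,Anemone obtusiloba,1.47,70.00,2.10
R,Arctium lappa,0.40,26.67,1.50
R,Artemisia vestita,1.13,63.33,1.79
R,Bistorta affinis,0.60,40.00,1.50
R,Cyananthus lobatus,0.87,50.00,1.73
R,Danthonia cachemyriana,1.70,90.00,1.89
R,Epilobium laxum,0.67,43.33,1.54
R,Geranium wallichianum,0.37,23.33,1.57
R,Kobresia nepalensis,0.90,33.33,2.70
R,Morina longifolia,0.43,23.33,1.86
R,Poa alpina,0.80,46.67,1.71
R,Potentilla argyrophylla,0.80,46.67,1.71
R,Potentilla atrosanguinea,1.13,63.33,1.79
R,Prunella vulgaris,1.27,53.33,2.38
R,Sibbaldia parviflora,1.93,83.33,2.32
R,Tanacetum longifolium,0.73,43.33,1.69
R,Taraxacum officinale,1.23,53.33,2.31
R,Viola biflora,0.47,36.67,1.27
GTZ,Achillea millefolium,0.97,56.67,1.71
GTZ,Allium humile,0.23,23.33,1.00
GTZ,Anemone obtusiloba,0.50,40.00,1.25
GTZ,Artemisia vestita,0.93,53.33,1.75
GTZ,Danthonia cachemyriana,0.80,60.00,1.33
GTZ,Epilobium laxum,0.60,46.67,1.29
GTZ,Impatiens sulcata,0.30,23.33,1.29
GTZ,Morina longifolia,0.13,13.33,1.00
GTZ,Poa alpina,0.43,30.00,1.44
GTZ,Polygonum polystachyum,0.50,36.67,1.36
GTZ,Potentilla argyrophylla,0.57,40.00,1.42
GTZ,Potentilla atrosanguinea,0.60,40.00,1.50
GTZ,Prunella vulgaris,0.77,40.00,1.92
GTZ,Senecio chrysanthemoides,0.60,40.00,1.50
GTZ,Sibbaldia parviflora,1.23,73.33,1.68
GTZ,Tanacetum longifolium,0.27,20.00,1.33
GTZ,Taraxacum officinale,1.13,56.67,2.00
UTZ,Achillea millefolium,0.43,30.00,1.44
UTZ,Anemone obtusiloba,0.30,20.00,1.50
UTZ,Artemisia vestita,0.40,33.33,1.20
UTZ,Danthonia cachemyriana,0.63,33.33,1.90
UTZ,Epilobium laxum,0.27,20.00,1.33
UTZ,Potentilla argyrophylla,0.40,23.33,1.71
UTZ,Rumex nepalensis,0.57,33.33,1.70
UTZ,Taraxacum officinale,0.40,30.00,1.33
UTZ,Polygonum polystachyum,0.30,23.33,1.29
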