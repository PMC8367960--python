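species,density,biomass_g_per_m2,yield_printed_quintal,palatable,ambiguous
Aconogonum tortuosum,0.4,4.2,177.86,True,False
Anemone obtusiloba,0.23,2.68,113.49,True,False
Arnebia benthamii,0.06,12.85,42.04,True,True
Bistorta vivipara,9.8,16.8,711.43,True,False
Bupleurum longicaule,0.2,1.3,55.05,True,False
Carex nubigena,4.42,1.5,63.52,True,False
Carex setigera,0.82,7.2,304.90,True,False
Cyananthus lobatus,0.57,6.1,258.32,True,False
Dactylorhiza hatagirea,0.23,1.3,55.05,True,False
Danthonia cachemyriana,0.33,60.2,2549.30,True,False
Epilobium latifolium,0.24,1.1,46.58,True,False
Eritrichium canum,0.62,1.2,50.82,True,False
Euphorbia stracheyi,0.2,1.4,59.29,True,False
Galium rotundifolium,0.23,0.2,8.47,True,False
Gentiana argentea,0.23,0.8,33.88,True,False
Geranium wallichianum,0.3,0.9,38.11,True,False
Geum elatum,0.2,1.2,50.82,True,False
Impatiens scabrida,0.31,1.3,55.05,True,False
Origanum vulgare,1.22,4.3,182.09,True,False
Oxygraphis polypetala,0.02,1.4,59.29,True,False
Parnassia nubicola,0.27,3.4,143.98,True,False
Picrorhiza kurrooa,0.08,1.2,50.82,True,False
Poa alpina,0.23,1.1,46.58,True,False
Polygonum polystachyum,0.4,1.8,76.22,True,False
Potentilla argyrophylla,0.5,2.2,93.16,True,False
Potentilla atrosanguinea,0.3,2.1,88.93,True,False
Potentilla fulgens,0.13,1.7,71.99,True,False
Primula denticulata,0.4,2.9,122.81,True,False
Prunella vulgaris,4.43,6.3,266.79,True,False
Ranunculus hyperboreus,0.4,6.1,258.32,True,False
Rumex nepalensis,1.19,10.8,457.35,True,False
Salix lindleyana,0.01,22.6,957.04,True,False
Taraxacum officinale,9.79,15.04,636.90,True,False
Trachydium roylei,19.33,22.2,940.11,True,False
Trifolium repens,0.53,4.2,177.86,True,False
Valeriana hardwickii,0.04,0.5,21.17,True,False
Viola biflora,4.24,4.2,177.86,True,False
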