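animal,body_weight_kg,forage_req_kg_day,animal_unit
cow,250,7.5,1.0
horse,312.5,9.38,1.18
goat,35.78,1.07,0.23
sheep,32.74,0.98,0.22
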