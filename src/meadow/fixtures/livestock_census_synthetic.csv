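year,animal,count,origin
2019,horse,200,migratory
2019,goat,500,migratory
2019,cow,400,local
2019,sheep,590,local
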