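zone,vegetation_cover_pct
R,75
GTZ,55
UTZ,25
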