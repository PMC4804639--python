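panel,k,sensitivity_pct,specificity_pct,plr,nlr
large_effect,1,95.2,51.4,2.0,0.1
large_effect,2,81.0,80.0,4.1,0.2
large_effect,3,42.9,91.4,5.0,0.6
all_aoi1,5,61.9,85.7,4.3,0.4
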