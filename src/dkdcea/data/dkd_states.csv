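name,tags,is_absorbing,utility,excess_mortality_annual,cost_productivity_annual,provenance
CKD,CKD,0,0.80,0.04,12000,synthetic-placeholder
ESRD1,ESRD|RRT,0,0.57,0.12,18000,synthetic-placeholder
ESRD2,ESRD|RRT|KTX,0,0.70,0.05,15000,synthetic-placeholder
ESRD2.2,ESRD|RRT|KTX,0,0.73,0.03,8000,synthetic-placeholder
Dead,,1,0.0,0.0,0,structural
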