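state,cost_healthcare_annual_base,cost_healthcare_annual_uk,cost_healthcare_annual_ireland,cost_healthcare_annual_italy,provenance
CKD,27000,25200,25800,28800,synthetic-placeholder (anchored between the cited $20k/yr CKD-stage and $80k/yr dialysis costs)
ESRD1,80000,72000,76000,84000,published anchor ($80k/yr dialysis); country spread synthetic-placeholder
ESRD2,95000,88000,92000,99000,synthetic-placeholder
ESRD2.2,24000,21000,22500,25500,synthetic-placeholder
Dead,0,0,0,0,structural
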