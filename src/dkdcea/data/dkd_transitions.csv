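from_state,to_state,probability_annual,provenance
CKD,ESRD1,0.055,synthetic-placeholder
CKD,ESRD2,0.004,synthetic-placeholder
ESRD1,ESRD2,0.035,synthetic-placeholder
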