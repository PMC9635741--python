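treatment,from_state,to_state,hr,provenance
MSC,CKD,ESRD1,0.83,published (estimated HR 0.83 for progression to ESRD)
MSC,CKD,ESRD2,0.83,published (estimated HR 0.83 for progression to ESRD)
SGLT2i,CKD,ESRD1,0.66,synthetic-placeholder (renoprotective class effect)
SGLT2i,CKD,ESRD2,0.66,synthetic-placeholder (renoprotective class effect)
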