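treatment,country,one_off_cost,per_cycle_cost,cost_state_tags,provenance
MSC,base,6000,0,,synthetic-placeholder dose cost (calibrated to the published per-arm cost ordering)
MSC,uk,6000,0,,synthetic-placeholder dose cost (calibrated to the published per-arm cost ordering)
MSC,ireland,6000,0,,synthetic-placeholder dose cost (calibrated to the published per-arm cost ordering)
MSC,italy,6000,0,,synthetic-placeholder dose cost (calibrated to the published per-arm cost ordering)
SGLT2i,base,0,45,CKD,synthetic-placeholder monthly drug cost
SGLT2i,uk,0,40,CKD,synthetic-placeholder monthly drug cost
SGLT2i,ireland,0,42,CKD,synthetic-placeholder monthly drug cost
SGLT2i,italy,0,185,CKD,synthetic-placeholder (relatively higher SGLT2i price in Italy; calibrated to the published jurisdictional ordering)
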