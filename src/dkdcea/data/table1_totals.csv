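scenario,strategy,cost_usd,qalys,provenance
base,SGLT2i,158131,6.46,published (per-arm totals as printed)
base,MSC,158770,6.39,published (per-arm totals as printed)
base,Usual Care,159978,6.28,published (per-arm totals as printed)
age40,SGLT2i,1909729,29.95,published (per-arm totals as printed)
age40,MSC,1948430,29.45,published (per-arm totals as printed)
age40,Usual Care,1997307,28.93,published (per-arm totals as printed)
uk,SGLT2i,150957,6.24,published (per-arm totals as printed)
uk,MSC,152407,6.17,published (per-arm totals as printed)
uk,Usual Care,153295,6.08,published (per-arm totals as printed)
ireland,SGLT2i,150777,6.26,published (per-arm totals as printed)
ireland,MSC,152558,6.18,published (per-arm totals as printed)
ireland,Usual Care,153479,6.09,published (per-arm totals as printed)
italy,MSC,172991,6.84,published (per-arm totals as printed)
italy,SGLT2i,174460,6.93,published (per-arm totals as printed)
italy,Usual Care,174911,6.73,published (per-arm totals as printed)
female,SGLT2i,172109,7.00,published (per-arm totals as printed)
female,MSC,172940,6.93,published (per-arm totals as printed)
female,Usual Care,175079,6.84,published (per-arm totals as printed)
male,SGLT2i,144268,5.93,published (per-arm totals as printed)
male,MSC,144779,5.85,published (per-arm totals as printed)
male,Usual Care,145167,5.75,published (per-arm totals as printed)
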