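# Persistence screening module (illustrative reconstruction).
# The numeric thresholds are the OECD 301 ready-biodegradability pass
# levels (60 % ThCO2 / ThOD, 70 % DOC) and the Annex XIII freshwater
# half-life criteria (P > 40 d, vP > 60 d); override by editing this file.
MODULE Persistence

QUESTIONS
ThCO2 (numeric) [%] "Degradation after 28 d as % of theoretical CO2 evolution"
  ? Ready-biodegradability endpoint; the pass level is 60 % of ThCO2.
ThOD (numeric) [%] "Degradation after 28 d as % of theoretical oxygen demand"
  ? Ready-biodegradability endpoint; the pass level is 60 % of ThOD.
DOC (numeric) [%] "Removal of dissolved organic carbon after 28 d"
  ? Ready-biodegradability endpoint; the pass level is 70 % DOC removal.
halflife_water (numeric) [d] "Degradation half-life in fresh water"

DECISIONS
Biodegradation "Biodegradation screening"
  NotReadilyBiodegradable "not readily biodegradable"
P "P criterion fulfilled"
vP "vP criterion fulfilled"

RULES
r_biodeg: IF ThCO2 < 60 OR ThOD < 60 OR DOC < 70 THEN NotReadilyBiodegradable P7
r_p_screen: IF ThCO2 < 60 OR ThOD < 60 OR DOC < 70 THEN P P5
r_p_halflife: IF halflife_water > 40 THEN P P7
r_vp: IF halflife_water > 60 THEN vP P7

INIT: ThCO2, ThOD, DOC, halflife_water
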