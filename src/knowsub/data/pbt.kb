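# Combining module: PBT / vPvB from the persistence, bioaccumulation and
# toxicity sub-decisions.
MODULE PBT
DEPENDS: Persistence, Bioaccumulation, Toxicity

DECISIONS
PBT "PBT substance (persistent, bioaccumulative, toxic)"
vPvB "vPvB substance (very persistent, very bioaccumulative)"

RULES
r_pbt: IF DECISION[P] = established AND DECISION[B] = established AND DECISION[T] = established THEN PBT P7
r_vpvb: IF DECISION[vP] = established AND DECISION[vB] = established THEN vPvB P7
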