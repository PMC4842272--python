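# Bioaccumulation assessment module (illustrative reconstruction).
# Workflow-driven: with a measured BCF the Annex XIII cut-offs apply
# (BCF >= 2000 -> B, BCF >= 5000 -> vB); without one, a log Kow screen can
# only suggest B.
MODULE Bioaccumulation

QUESTIONS
BCF_available (one_choice: yes | no) "Is a measured bioconcentration factor available?"
BCF (numeric) [L/kg] "Bioconcentration factor in aquatic species"
  ? Ratio of the concentration in the organism to the concentration in water at steady state.
logKow (numeric) "Octanol-water partition coefficient (log Kow)"

DECISIONS
BioaccumulationPotential "Bioaccumulation potential"
  B "B criterion fulfilled"
  vB "vB criterion fulfilled"
  NotB "not bioaccumulative"

FLOW BioFlow
start s0
ask a_avail BCF_available
ask a_bcf BCF
ask a_kow logKow
decide d_vb vB established
decide d_b B established
decide d_notb NotB established
decide d_b_sugg B suggested
exit done
edge s0 -> a_avail
edge a_avail -> a_bcf IF BCF_available = yes
edge a_avail -> a_kow IF BCF_available = no
edge a_bcf -> d_vb IF BCF >= 5000
edge a_bcf -> d_b IF BCF >= 2000 AND BCF < 5000
edge a_bcf -> d_notb IF BCF < 2000
edge d_vb -> d_b
edge d_b -> done
edge d_notb -> done
edge a_kow -> d_b_sugg IF logKow >= 4.5
edge a_kow -> done IF logKow < 4.5
edge d_b_sugg -> done
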