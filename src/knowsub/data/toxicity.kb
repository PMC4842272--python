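# Toxicity screening module (illustrative reconstruction).
# T criterion per Annex XIII convention: chronic NOEC < 0.01 mg/L, or a
# CMR classification.
MODULE Toxicity

QUESTIONS
chronic_NOEC (numeric) [mg/L] "Long-term no-observed-effect concentration (aquatic)"
cmr_category (one_choice: none | carcinogenic | mutagenic | reprotoxic) "CMR classification"

DECISIONS
T "T criterion fulfilled"
NotT "T criterion not fulfilled"

RULES
r_noec: IF chronic_NOEC < 0.01 THEN T P7
r_cmr: IF cmr_category in {carcinogenic, mutagenic, reprotoxic} THEN T P7
r_not_t: IF chronic_NOEC >= 0.01 AND cmr_category = none THEN NotT P7

INIT: chronic_NOEC, cmr_category
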