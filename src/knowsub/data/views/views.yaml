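# Bundled dynamic views: name -> SPARQL file + description.
pbt_class:
  query: pbt_class.rq
  description: All substances carrying the persistent, bioaccumulative and toxic property (class-membership pattern).
non_pbt:
  query: non_pbt.rq
  description: Complement of the PBT class via NOT EXISTS.
pbt_screening:
  query: pbt_screening.rq
  description: Substances currently screened as PBT (derived decision mirrored into the graph).
decision_overview:
  query: decision_overview.rq
  description: Every mirrored decision state per substance.
memos:
  query: memos.rq
  description: Decision memos per substance with creation dates.
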