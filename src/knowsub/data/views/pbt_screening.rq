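PREFIX ks: <https://knowsub.dev/ks/>
SELECT ?label ?ec ?cas WHERE {
  ?s a ks:Substance ; ks:hasLabel ?label ; ks:hasDecision ?d .
  ?d ks:aboutDecision ks:PBT ; ks:hasState "established" .
  OPTIONAL { ?s ks:hasEcNumber ?ec }
  OPTIONAL { ?s ks:hasCasNumber ?cas }
}
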