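PREFIX ks: <https://knowsub.dev/ks/>
SELECT ?label ?decision ?state WHERE {
  ?s a ks:Substance ; ks:hasLabel ?label ; ks:hasDecision ?d .
  ?d ks:aboutDecision ?decision ; ks:hasState ?state .
}
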