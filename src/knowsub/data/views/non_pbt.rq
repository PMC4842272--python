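PREFIX ks: <https://knowsub.dev/ks/>
SELECT ?label WHERE {
  ?s a ks:Substance ; ks:hasLabel ?label .
  FILTER NOT EXISTS {
    ?s ks:hasChemProperty ks:persistent .
    ?s ks:hasChemProperty ks:bioaccumulative .
    ?s ks:hasChemProperty ks:toxic .
  }
}
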