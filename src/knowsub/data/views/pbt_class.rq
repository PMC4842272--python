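PREFIX ks: <https://knowsub.dev/ks/>
SELECT ?label WHERE {
  ?s a ks:Substance ;
     ks:hasChemProperty ks:persistent, ks:bioaccumulative, ks:toxic ;
     ks:hasLabel ?label .
}
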