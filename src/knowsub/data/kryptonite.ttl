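# Worked example: the fantasy substance Kryptonite with the three hazard
# properties persistent, bioaccumulative and toxic.
# The CAS and EC numbers are SYNTHETIC: deliberately fictional values from
# the all-nines range, chosen only to be checksum-valid for the identifier
# quality checks.  They do not denote any real substance.
@prefix ks: <https://knowsub.dev/ks/> .
@prefix rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .

ks:Substance a rdfs:Class .
ks:ChemProperty a rdfs:Class .

ks:persistent a ks:ChemProperty ; ks:hasLabel "persistent" .
ks:bioaccumulative a ks:ChemProperty ; ks:hasLabel "bioaccumulative" .
ks:toxic a ks:ChemProperty ; ks:hasLabel "toxic" .

ks:Kryptonite a ks:Substance ;
    ks:hasLabel "Kryptonite" ;
    ks:hasCasNumber "9999999-99-5" ;
    ks:hasEcNumber "999-999-2" ;
    ks:hasMemoText "Fictional demonstration substance; identifiers are SYNTHETIC." ;
    ks:hasChemProperty ks:persistent, ks:bioaccumulative, ks:toxic .
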