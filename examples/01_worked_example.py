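"""The bundled worked example: a PBT substance in the RDF graph.

Loads the Kryptonite ontology, asserts its three hazard properties and
runs the class-membership SELECT plus its NOT-EXISTS complement.
"""

from knowsub import SubstanceRecord, kryptonite_store

store = kryptonite_store()
for prop in ("persistent", "bioaccumulative", "toxic"):
    store.assert_property("Kryptonite", prop)  # idempotent

# a companion substance that is only persistent, to populate the complement
store.add_substance(SubstanceRecord(label="Water", cas_number="7732-18-5"))
store.assert_property("Water", "persistent")

pbt = store.query(
    """
    SELECT ?label WHERE {
      ?s a ks:Substance ;
         ks:hasChemProperty ks:persistent, ks:bioaccumulative, ks:toxic ;
         ks:hasLabel ?label .
    }
    """
)
print("PBT substances:", [row[0] for row in pbt.rows])

complement = store.query(
    """
    SELECT ?label WHERE {
      ?s a ks:Substance ; ks:hasLabel ?label .
      FILTER NOT EXISTS {
        ?s ks:hasChemProperty ks:persistent .
        ?s ks:hasChemProperty ks:bioaccumulative .
        ?s ks:hasChemProperty ks:toxic .
      }
    }
    """
)
print("not PBT:       ", [row[0] for row in complement.rows])
# Only Kryptonite carries all three properties; every other substance falls
# into the NOT-EXISTS complement — the two sets partition the store.
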