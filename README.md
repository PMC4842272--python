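# knowsub

A substance-centric knowledge engine for regulatory hazard screening, of
the kind used by chemicals agencies working under the EU REACH regulation.
Everything the system knows about a chemical substance — identifiers,
measured endpoints, expert answers, memos and derived hazard decisions —
lives in one RDF graph and one timestamped fact log, so that screening
decisions such as *PBT* (persistent, bioaccumulative and toxic) and *vPvB*
are always derivable, explainable and reconstructable for any point in the
past.

It is a library first (the `knowsub` Python package), with an `examples/`
directory of narrative scripts and a thin `knowsub` command-line tool for
the operations an assessor would run from a shell.

## What it does

- **Substance graph** (`knowsub.store`): substances are `ks:Substance`
  resources with datatype properties for their identifier set (EC number,
  CAS number, IUPAC name, SMILES, internal names, label) and
  `ks:hasChemProperty` links to hazard property terms. SPARQL SELECT/ASK
  runs directly against the graph; class membership such as "PBT substance
  = has persistent ∧ bioaccumulative ∧ toxic" is computed both by scan and
  by a mechanically generated query, and the two are cross-checked.
- **Identifier QC** (`knowsub.identifiers`): CAS numbers are validated
  against the standard mod-10 check digit
  (Σ dᵢ·i over the body digits, numbered from the right) and EC numbers
  against the mod-11 scheme (Σ dᵢ·i numbered from the left; remainder 10
  admits no check digit). A quality dashboard reports bad checksums,
  duplicated identifier values and contraindicative identifier sets.
- **Decision knowledge** (`knowsub.kb`, `knowsub.parser`): decision
  modules hold question/decision hierarchies, non-monotonic scoring rules
  (categories N7…P7 mapping to ∓1, 2, 5, 10, 20, 40, 80) and acyclic
  guarded workflows, written in a plain-text `.kb` dialect. Conditions are
  evaluated under Kleene three-valued logic; a rule never fires on an
  undefined condition.
- **Inference** (`knowsub.engine`): stateless full re-evaluation derives a
  `DecisionState` (established ≥ 42, suggested ≥ 10, excluded ≤ −42 on the
  summed score) for every decision, in module dependency order, so the PBT
  module reuses the P, B and T sub-decisions. Retraction, explanations
  ("the responsible facts with entry date") and workflow reasoning traces
  come with it.
- **Interview** (`knowsub.interview`): an agenda-driven question/answer
  session per module that only asks indicated, unanswered questions.
- **Provenance** (`knowsub.provenance`): append-only fact history and the
  decision time machine `decisions_at(t)`; decision memos mirrored into
  the graph.
- **Views and IO** (`knowsub.views`): named SPARQL views rendered fresh on
  every access, RFC-4180 CSV/TSV export, bulk CSV import with
  checksum-based rejection and merge-by-identifier.
- **Fixtures** (`knowsub.fixtures`): seeded generators for synthetic
  substances, fact logs and random rule registries, plus the bundled
  worked example around the fantasy substance *Kryptonite* (all its
  identifiers are clearly marked SYNTHETIC).

## Worked example

```python
from knowsub import evaluate, explain, kryptonite_example, kryptonite_facts, retract

store, registry, answers = kryptonite_example()
states = evaluate(registry, answers)
for d in ("P", "B", "T", "PBT"):
    print(d, states[d].state.value, states[d].score)
```

prints

```
P established 100
B established 0
T established 80
PBT established 80
```

P is established by rule scores (the ready-biodegradability thresholds
ThCO2 45 % < 60 %, ThOD 40 % < 60 %, DOC 50 % < 70 % contribute +20, the
water half-life of 70 d > 40 d contributes +80); B is decided directly by
the bioaccumulation workflow (a measured BCF of 5300 L/kg exceeds the
2000/5000 cut-offs, so score stays 0); T follows from the chronic NOEC of
0.005 mg/L < 0.01; and the PBT module combines the three sub-decisions.
Retracting the BCF fact withdraws B and, with it, PBT:

```python
after = evaluate(registry, retract(answers, "BCF"))
print(after["B"].state.value, after["PBT"].state.value)   # undefined undefined
```

The scripts in `examples/` walk through each capability (SPARQL worked
example, identifier QC, derivation and explanation, interview, time
machine, import/views) and print what the numbers mean.

## Command line

```bash
knowsub query store.ttl query.rq       # SPARQL against a Turtle store
knowsub qc store.ttl --report qc.csv   # identifier quality dashboard
knowsub derive store.ttl --substance Kryptonite --facts facts.csv
knowsub interview store.ttl --module Bioaccumulation --substance Kryptonite
knowsub view pbt_screening store.ttl   # render a bundled dynamic view
knowsub import store.ttl substances.csv
knowsub page store.ttl --substance Kryptonite
```

Spreadsheet interchange is CSV/TSV only — no binary workbook formats.

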