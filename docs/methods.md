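# Methods

This note documents the models and procedures behind `knowsub`, the
parameters that matter, the numerical and design choices made where the
design was genuinely open, and what the synthetic fixtures do and do not
show about real regulatory data.

## Knowledge representation

The system separates two layers deliberately:

1. **Relational knowledge** lives in an RDF graph. Substances, their
   identifiers, chemical hazard properties, memos and *derived* decisions
   are triples under a single namespace (prefix `ks:`, default
   `https://knowsub.dev/ks/`). SPARQL reaches every information state of
   the system, which is what makes dynamic views possible.
2. **Derivational knowledge** lives in decision modules: scoring rules
   and workflows over a shared terminology of questions and decisions.
   Derivation results are *mirrored* into the graph
   (`ks:hasDecision` → a per-substance state node with `ks:aboutDecision`
   and `ks:hasState`), so queries and views can treat derived states like
   any other data.

Class membership ("PBT substance = hasChemProperty persistent ∧
bioaccumulative ∧ toxic") is computed by scanning the
intersection-of-property-values pattern and, independently, by a
mechanically generated SPARQL query. A full OWL-DL reasoner is not used:
the screening workload exercises exactly this intersection pattern, and
the scan is deterministic, cheap at desk scale (thousands of substances)
and trivially auditable. Consequently, OWL constructs beyond this pattern
(property chains, complements, cardinality) are out of scope.

SPARQL leaves result order unspecified; `knowsub` imposes lexicographic
ordering over the stringified cells. This is stricter than the standard
but buys reproducible tests and byte-identical exports.

## Identifier checksums

- **CAS**: format `2–7 digits – 2 digits – 1 check digit`. Number the body
  digits 1, 2, 3, … starting at the rightmost non-check digit; the check
  digit is Σ dᵢ·i mod 10. Exactly one check digit is valid per body.
- **EC**: format `3 digits – 3 digits – 1 check digit`. Number the six
  body digits 1…6 left to right; the check digit is Σ dᵢ·i mod 11. A
  remainder of 10 has no valid check digit — such bodies cannot occur in
  the inventory, and the validator reports them as checksum failures.
- **SMILES** is treated purely as an identifier: the check is syntactic
  (token alphabet, balanced parentheses, paired ring-closure digits), not
  chemical. Structure interpretation would need a chemistry toolkit and
  would not change any downstream decision here.

"Contraindicative identifiers" are interpreted as ≥ 2 distinct values for
a scheme expected to be single-valued (CAS, EC, IUPAC, SMILES); internal
names stay multi-valued. Duplicate and contraindication detection query
the graph; checksum arithmetic stays in code.

## Three-valued conditions and scoring rules

Conditions over question answers use Kleene semantics with the truth
ordering false < undefined < true: AND is the minimum, OR the maximum, NOT
reflects around undefined, and any comparison on an unanswered (or
explicitly "Unknown") question is undefined. Rules **never fire on
undefined** — there is no closed-world defaulting. Two consequences are
load-bearing:

- *Monotonicity*: adding answers can only resolve undefined, never flip a
  knownness-free condition between true and false, so interviews cannot
  invalidate earlier inferences except through explicit revision.
- *Explanation soundness*: removing non-responsible facts can only unfire
  rules, so re-evaluating with just an explanation's responsible facts
  reproduces the explained state.

The one deliberately two-valued atom is `KNOWN[q]` (true iff answered):
it is the escape hatch for genuinely non-monotone knowledge ("if no
measured value is known, fall back to …"), and conditions using it are
exempt from the two guarantees above. The bundled modules and the random
registries used for oracle testing avoid it.

Scoring categories follow the heuristic d3web convention: N7…N1 and
P1…P7 with magnitudes 80, 40, 20, 10, 5, 2, 1 (negative/positive). Fired
rule scores sum per target decision; the summed score maps to a state via
thresholds **established ≥ 42, suggested ≥ 10, excluded ≤ −42**, else
undefined. The thresholds are configurable per registry
(`ScoreThresholds`). Two P5 rules (+20 each) therefore only *suggest* a
decision; establishing needs a P7 or three independent medium-strength
rules — the conservatism is intentional for screening.

## Workflows and conflict resolution

Workflows are directed acyclic graphs of start/ask/decide/exit nodes with
guarded edges. Traversal is deterministic: at each node the outgoing
edges are tested in declaration order and the first true guard is taken
(an unguarded edge counts as true); traversal stops at exit or when every
guard is false or undefined. Multiple simultaneously-true guards take the
first and log a warning. Acyclicity is enforced at parse time — it makes
traversal and the reasoning trace finite and reproducible.

Where a workflow decide-node and rule scores target the same decision,
the workflow state wins, with one safety-first exception: a rule-derived
*excluded* (score ≤ −42) is never overridden upward to suggested or
established; the conflict is logged. Both choices are reconstructions —
production systems differ here — and are isolated in one function
(`engine._apply_decide`) so a different policy is a local change.

Cross-module reuse goes through `DECISION[d] = state` atoms, which may
only reference decisions of modules listed in `depends_on`;
`validate_registry` rejects same-module references. With that
stratification, one dependency-ordered pass is an exact fixpoint — no
iteration, no oscillation — which is what makes the order-invariance and
fixpoint properties provable rather than empirical.

## Truth maintenance

Non-monotonicity is implemented as **stateless full re-evaluation**:
every call to `evaluate()` recomputes all decisions from the current fact
set. Retracting a fact is set subtraction followed by re-evaluation, so
`evaluate(facts ∖ {f})` is *definitionally* equal to a session that never
saw `f`, and the result cannot depend on fact insertion order. An
incremental truth-maintenance system would be preferable somewhere past
tens of thousands of rules; at desk scale (hundreds of rules, a few dozen
facts per substance) a full pass costs well under a millisecond.

## Interview agenda

The agenda is workflow-reachability first: the ask nodes currently
reachable from a flow's start via true-guard edges, in flow declaration
order, followed by the module's `INIT` questions (for rule-only modules,
all declared questions in declaration order). Undefined guards block
reachability, so a question only enters the agenda once the answers that
make it relevant exist. Ties break by declaration order. Questions
answered anywhere — including in other modules — are never re-asked.
Revision of an answer mid-interview simply replaces the fact and re-runs
inference; there is no partial-invalidation bookkeeping to get wrong.

## Provenance and the time machine

Facts are append-only: a correction is a new fact with a later timestamp,
never an edit. Timestamps are ISO-8601 UTC instants; a monotonically
increasing sequence number assigned by the history breaks same-instant
ties, making replay of a shuffled log deterministic. `decisions_at(t)`
evaluates the registry against the latest fact per question with
timestamp ≤ t — it is right-continuous (at the instant of a fact, the
fact counts) and `decisions_at(now)` coincides with the live evaluation.
The knowledge base itself is assumed fixed across time; versioning the
registry alongside the facts is a known limitation.

Each fact optionally carries a Klimisch reliability score (1–4), recorded
and persisted but not weighted into the inference — reliability-weighted
scoring would need domain calibration this package does not presume.

## Bundled example modules

The four modules (Persistence, Bioaccumulation, Toxicity, PBT) are
illustrative reconstructions; their numeric thresholds are stated
regulatory conventions, marked in the module files and overridable there:

| parameter | default | unit | rationale |
|---|---|---|---|
| ThCO2 / ThOD pass level | 60 | % | OECD 301 ready-biodegradability |
| DOC removal pass level | 70 | % | OECD 301 |
| half-life in fresh water, P / vP | 40 / 60 | d | REACH Annex XIII |
| BCF cut-off, B / vB | 2000 / 5000 | L/kg | REACH Annex XIII |
| chronic NOEC, T | 0.01 | mg/L | REACH Annex XIII |
| log Kow screen (suggests B) | 4.5 | — | screening surrogate without a BCF |

Persistence is rule-based (the ready-biodegradability screen is an OR
over the three endpoints), Bioaccumulation is workflow-based, and PBT
combines the three sub-decisions — deliberately exercising both knowledge
representations and the cross-module reuse path. A production knowledge
base is far larger (hundreds of decisions, hundreds of questions, many
more modules); the reconstruction keeps the *shapes* that matter for the
engine, not the content.

The worked-example substance Kryptonite is fictional; its CAS
(9999999-99-5) and EC (999-999-2) values are drawn from the all-nines
range, checksum-valid by construction, and labelled SYNTHETIC in the
fixture file.

## Synthetic data: what it emulates, what it does not

`generate_substances` emulates a registration table: unique labels,
unique checksum-valid CAS/EC identifiers, with an exactly controlled
fraction (`round(n × invalid_id_rate)`) of injected checksum-invalid CAS
numbers. `generate_random_registry` emulates rule bases: numeric and
one-choice questions, random knownness-free conditions of depth ≤ 3,
random score categories. Both are pure functions of their seed.

They do **not** emulate: realistic chemical structures or identifier
distributions, correlated endpoints (a real substance's ThCO2 and ThOD
agree), missing-not-at-random data, or the scale and heterogeneity of a
production knowledge base. Passing tests therefore demonstrate the
*engine's* correctness (oracle agreement, order invariance, soundness,
round trips), not the regulatory validity of any bundled threshold.

## Numerical and degenerate-input choices

- Scores are integers throughout; no floating-point accumulation.
- Numeric comparisons on non-numeric answers raise an evaluation error
  rather than coercing; boolean answers are not numbers.
- An empty workflow fact set yields a trace that stops at the first
  undefined guard; a module with no rules and no flows derives nothing.
- CSV export is RFC-4180 with CRLF line endings and minimal quoting;
  byte-identical across renders of an unchanged store.
- Bulk import merges by CAS first, then EC, then exact label — mirroring
  how duplicate registrations are grouped in practice — and rejects rows
  whose CAS/EC fails its checksum rather than silently importing them.
- Problem sizes in the test and acceptance runs (50 random stores ≤ 100
  substances, 10,000 checksum bodies, 1,000 random fact sets, 200
  explanation cases) are chosen so the full suite completes in seconds
  while each property is exercised across its branch structure.

## Known limitations

- No OWL reasoning beyond the intersection pattern; no named graphs or
  remote SPARQL endpoints.
- Single-user, in-process: no concurrent editing, authorization roles or
  wiki front-end.
- The registry is not versioned in the time machine.
- SMILES validation is syntactic only; no InChI, no structure-based
  duplicate detection.
- Binary spreadsheet formats are out of scope; CSV/TSV is the interchange
  format.
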