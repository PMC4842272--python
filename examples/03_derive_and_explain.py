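"""Deriving hazard decisions, explaining them, and retracting a fact.

The scoring rules and workflows of the four bundled modules combine the
answer script into P/B/T sub-decisions and the final PBT state; the
explanation lists the responsible facts, and retracting the BCF value
non-monotonically withdraws everything that depended on it.
"""

from knowsub import evaluate, explain, kryptonite_example, kryptonite_facts, retract

_, registry, answers = kryptonite_example()
states = evaluate(registry, answers)
print("derived decisions:")
for decision_id in sorted(states):
    st = states[decision_id]
    if st.state.value != "undefined":
        print(f"  {decision_id}: {st.state.value} (score {st.score})")

facts = kryptonite_facts()  # same answers, as timestamped facts
exp = explain(registry, facts, "PBT")
print("\nresponsible facts for PBT:")
for question, value, timestamp in exp.responsible_facts:
    print(f"  {question} = {value!r} (entered {timestamp.date().isoformat()})")

reduced = retract(answers, "BCF")
after = evaluate(registry, reduced)
print("\nafter retracting BCF:")
print("  B:  ", after["B"].state.value)
print("  PBT:", after["PBT"].state.value)
# Without the bioconcentration factor the B criterion cannot be derived,
# so the combined PBT decision falls back to undefined as well.
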