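"""A scripted interactive interview on the bioaccumulation module.

The agenda follows the workflow front: only questions that are currently
reachable are asked, so answering "is a BCF available?" with yes opens the
BCF question and skips the log Kow screen entirely.
"""

from knowsub import answer, next_question, start_interview

from knowsub.fixtures import bundled_registry

registry = bundled_registry()
script = {"BCF_available": "yes", "BCF": 5300}

session = start_interview(registry, "Bioaccumulation")
while (qid := next_question(session)) is not None:
    value = script[qid]
    prompt = registry.all_questions()[qid].prompt
    print(f"Q: {prompt}\nA: {value}")
    answer(session, qid, value)

print("\ninterview finished; derived decisions:")
for decision_id, st in sorted(session.decisions().items()):
    if st.state.value != "undefined":
        print(f"  {decision_id}: {st.state.value}")
# A measured BCF of 5300 L/kg exceeds both Annex XIII cut-offs, so the
# workflow establishes vB and, by implication, B.
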