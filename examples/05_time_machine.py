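"""The decision time machine: what was valid when.

A ThCO2 measurement of 45 % (below the 60 % pass level) first establishes
"not readily biodegradable"; a later corrected value of 65 % withdraws it.
decisions_at() reconstructs either state from the timestamped fact log.
"""

from datetime import datetime, timedelta, timezone

from knowsub import Fact, FactHistory, decisions_at
from knowsub.fixtures import bundled_registry

registry = bundled_registry()
t0 = datetime(2015, 6, 1, tzinfo=timezone.utc)
substance = "urn:demo:s1"

history = FactHistory()
history.record_fact(Fact(substance, "ThCO2", 45, timestamp=t0, author="alice"))
history.record_fact(
    Fact(substance, "ThCO2", 65, timestamp=t0 + timedelta(days=10), author="bob")
)

for label, when in [
    ("before any fact ", t0 - timedelta(days=1)),
    ("after 1st entry ", t0 + timedelta(days=5)),
    ("after correction", t0 + timedelta(days=20)),
]:
    state = decisions_at(registry, history, substance, when)["NotReadilyBiodegradable"]
    print(f"{label}: NotReadilyBiodegradable = {state.state.value}")
# The middle line shows the historical state; the correction by a second
# assessor is a new fact, never an edit, so the audit trail stays intact.
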