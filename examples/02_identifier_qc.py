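"""Identifier validation and the quality dashboard.

CAS numbers carry a mod-10 check digit, EC numbers a mod-11 check digit;
the dashboard additionally reports duplicated identifier values and
substances with contradictory (multiple) values for a single-valued scheme.
"""

from knowsub import (
    SubstanceRecord,
    SubstanceStore,
    run_quality_checks,
    validate_cas,
    validate_ec,
)

for text in ("7732-18-5", "7732-18-4", "not-a-cas"):
    r = validate_cas(text)
    print(f"CAS {text!r}: well_formed={r.well_formed} checksum_ok={r.checksum_ok} {r.message}")
r = validate_ec("200-001-8")
print(f"EC  '200-001-8': checksum_ok={r.checksum_ok}")

store = SubstanceStore()
store.add_substance(SubstanceRecord(label="A", cas_number="7732-18-5"))
store.add_substance(SubstanceRecord(label="B", cas_number="7732-18-5"))  # duplicate
store.add_substance(SubstanceRecord(label="C", cas_number="7732-18-4"))  # bad checksum

print("\ndashboard findings:")
for finding in run_quality_checks(store).findings:
    print(f"  {finding.kind.value}: {finding.detail}")
# One bad_checksum finding for C and one duplicate_identifier finding
# listing both A and B — exactly what a registrar needs to clean up.
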