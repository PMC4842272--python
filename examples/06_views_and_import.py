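"""Bulk import, decision mirroring and dynamic SPARQL views.

Generates a synthetic substance table, imports it, mirrors Kryptonite's
derived decisions into the graph and renders the PBT screening view —
which is re-executed on every render, so it always reflects the latest
state.  Views export as RFC-4180 CSV.
"""

import tempfile
from pathlib import Path

from knowsub import (
    FactHistory,
    FixtureSpec,
    evaluate,
    generate_substances,
    import_substances,
    kryptonite_example,
    load_bundled_views,
    mirror_decisions,
    render_view,
)
from knowsub.views import format_table

store, registry, answers = kryptonite_example()
workdir = Path(tempfile.mkdtemp())

csv_path = workdir / "substances.csv"
generate_substances(FixtureSpec(n_substances=5, seed=2), csv_path=csv_path)
summary = import_substances(store, FactHistory(), csv_path)
print(f"import: created={summary.created} merged={summary.merged} "
      f"rejected={len(summary.rejected)}")

mirror_decisions(store, "Kryptonite", evaluate(registry, answers))

view = load_bundled_views()["pbt_screening"]
print("\npbt_screening view:")
print(format_table(render_view(store, view)))
# Only Kryptonite has a mirrored established PBT decision; the five
# synthetic imports appear in the store but not in the screening list.
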