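"""Dynamic views, tabular export, bulk import and the substance info page.

A dynamic view is a named SPARQL SELECT rendered as a table.  Views are
executed fresh against the current store state on every render — there is
no caching, so a view always reflects the latest facts and mirrored
decisions.  Tables export as RFC-4180 CSV (or TSV); spreadsheet interchange
is deliberately text-based, binary workbook formats are out of scope.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from datetime import datetime, timezone
from importlib import resources

import pandas as pd
import yaml

from .engine import Fact, Source, evaluate
from .errors import FormatError, ValidationError, ViewError
from .identifiers import validate_cas, validate_ec
from .parser import Registry
from .provenance import FactHistory, MemoLog
from .store import ResultTable, SubstanceRecord, SubstanceStore

_RESERVED_COLUMNS = ("label", "ec", "cas", "iupac", "smiles", "internal_names", "comment")


@dataclass(frozen=True)
class ViewDefinition:
    """A named SPARQL SELECT rendered as a table."""

    name: str
    sparql: str
    description: str = ""


def load_bundled_views() -> dict[str, ViewDefinition]:
    """The views shipped with the package (see data/views/*.rq)."""
    root = resources.files("knowsub.data").joinpath("views")
    manifest = yaml.safe_load(root.joinpath("views.yaml").read_text("utf-8"))
    out = {}
    for name, entry in manifest.items():
        sparql = root.joinpath(entry["query"]).read_text("utf-8")
        out[name] = ViewDefinition(name, sparql, entry.get("description", ""))
    return out


def render_view(store: SubstanceStore, view: ViewDefinition) -> ResultTable:
    """Execute a view against the current store state (no caching)."""
    try:
        return store.query(view.sparql)
    except Exception as exc:
        raise ViewError(f"view {view.name!r} failed: {exc}") from exc


def export_table(table: ResultTable, path, fmt: str = "csv") -> None:
    """Write a table as RFC-4180 CSV or TSV; round-trip safe."""
    if fmt not in ("csv", "tsv"):
        raise ValidationError(f"unsupported export format {fmt!r}")
    text = format_table(table, fmt)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write(text)


def format_table(table: ResultTable, fmt: str = "csv") -> str:
    buffer = io.StringIO()
    writer = csv.writer(
        buffer, delimiter="," if fmt == "csv" else "\t", lineterminator="\r\n"
    )
    writer.writerow(table.columns)
    for row in table.rows:
        writer.writerow(["" if c is None else c for c in row])
    return buffer.getvalue()


@dataclass
class ImportSummary:
    created: int = 0
    merged: int = 0
    facts_recorded: int = 0
    rejected: list[tuple[int, str]] = None  # (row number, reason)

    def __post_init__(self):
        if self.rejected is None:
            self.rejected = []


def _find_existing(store: SubstanceStore, record: SubstanceRecord) -> str | None:
    """Merge key priority: CAS, then EC, then exact label."""
    for pred, value in (
        ("hasCasNumber", record.cas_number),
        ("hasEcNumber", record.ec_number),
        ("hasLabel", record.label),
    ):
        if not value:
            continue
        table = store.query(
            f'SELECT ?s WHERE {{ ?s a ks:Substance ; ks:{pred} "{value}" . }}'
        )
        if table.rows:
            return str(table.rows[0][0])
    return None


def import_substances(
    store: SubstanceStore, history: FactHistory, path
) -> ImportSummary:
    """Bulk-import substances (and optional question answers) from CSV.

    The header must contain ``label``; ``ec``, ``cas``, ``iupac``,
    ``smiles`` and ``internal_names`` (``;``-separated) are recognized
    identifier columns, every other column is treated as a question id
    whose non-empty cells become import-sourced facts.  Rows whose CAS or
    EC number fails its checksum are rejected with a reason.  Re-importing
    merges by identifier instead of duplicating.
    """
    frame = pd.read_csv(path, dtype=str).fillna("")
    # identifier columns are matched case-insensitively; any other column
    # keeps its exact spelling — it is a question id
    frame.columns = [
        c.strip().lower() if c.strip().lower() in _RESERVED_COLUMNS else c.strip()
        for c in frame.columns
    ]
    if "label" not in frame.columns:
        raise FormatError("import file must declare a 'label' column")
    question_columns = [c for c in frame.columns if c not in _RESERVED_COLUMNS]
    summary = ImportSummary()
    now = datetime.now(timezone.utc)
    for idx, row in enumerate(frame.itertuples(index=False), start=2):
        data = dict(zip(frame.columns, row))
        cas = data.get("cas", "").strip() or None
        ec = data.get("ec", "").strip() or None
        if cas and not validate_cas(cas).checksum_ok:
            summary.rejected.append((idx, f"bad_checksum: CAS {cas!r}"))
            continue
        if ec and not validate_ec(ec).checksum_ok:
            summary.rejected.append((idx, f"bad_checksum: EC {ec!r}"))
            continue
        record = SubstanceRecord(
            label=data.get("label", "").strip(),
            cas_number=cas,
            ec_number=ec,
            iupac_name=data.get("iupac", "").strip() or None,
            smiles=data.get("smiles", "").strip() or None,
            internal_names=[
                n.strip()
                for n in data.get("internal_names", "").split(";")
                if n.strip()
            ],
        )
        if record.is_empty():
            summary.rejected.append((idx, "empty row"))
            continue
        existing = _find_existing(store, record)
        if existing is None:
            uri = store.add_substance(record)
            summary.created += 1
        else:
            uri = existing
            summary.merged += 1
        for column in question_columns:
            cell = data.get(column, "").strip()
            if not cell:
                continue
            try:
                value: object = float(cell) if "." in cell else int(cell)
            except ValueError:
                value = cell
            history.record_fact(
                Fact(
                    substance=uri,
                    question=column,
                    value=value,
                    timestamp=now,
                    author="import",
                    source=Source.import_,
                )
            )
            summary.facts_recorded += 1
    return summary


def export_substances(store: SubstanceStore, path) -> None:
    """Write the substance identifier table as CSV (inverse of import)."""
    rows = []
    for uri in store.substances():
        rec = store.get_substance(uri)
        rows.append(
            (
                rec.label,
                rec.ec_number,
                rec.cas_number,
                rec.iupac_name,
                rec.smiles,
                ";".join(rec.internal_names),
            )
        )
    table = ResultTable(
        columns=["label", "ec", "cas", "iupac", "smiles", "internal_names"],
        rows=rows,
    ).sort()
    export_table(table, path, "csv")


# -- substance info page --------------------------------------------------


def info_page(
    store: SubstanceStore,
    registry: Registry | None,
    history: FactHistory | None,
    substance: str,
    memo_log: MemoLog | None = None,
) -> str:
    """Render the comprehensive substance summary as markdown.

    Sections in fixed order: identifiers, current decisions (grouped by
    module, final decisions of combining modules first), memos (newest
    first), fact history summary.
    """
    uri = str(store.substance_uri(substance))
    record = store.get_substance(uri)
    lines = [f"# {record.label or uri}", ""]

    lines.append("## Identifiers")
    for name, value in (
        ("EC number", record.ec_number),
        ("CAS number", record.cas_number),
        ("IUPAC name", record.iupac_name),
        ("SMILES", record.smiles),
    ):
        if value:
            lines.append(f"- {name}: {value}")
    for name in record.internal_names:
        lines.append(f"- internal name: {name}")
    props = sorted(store.properties_of(uri))
    if props:
        lines.append(f"- chemical properties: {', '.join(props)}")
    lines.append("")

    lines.append("## Current decisions")
    decided = False
    if registry is not None and history is not None:
        states = evaluate(registry, history.current_facts(uri))
        # modules that combine others (non-empty depends_on) first: their
        # decisions are the final ones a reader wants at first glance
        ordered = sorted(
            registry.modules.values(),
            key=lambda m: (0 if m.depends_on else 1, m.name),
        )
        for module in ordered:
            entries = [
                states[d.id]
                for d in module.decisions
                if states[d.id].state.value != "undefined"
            ]
            if not entries:
                continue
            decided = True
            lines.append(f"### {module.name}")
            for st in entries:
                lines.append(f"- {st.decision}: **{st.state.value}** (score {st.score})")
    if not decided:
        lines.append("none derived")
    lines.append("")

    lines.append("## Memos")
    memos = memo_log.for_substance(uri) if memo_log is not None else []
    if memos:
        for memo in memos:
            suffix = (
                f" — attached decision: {memo.attached_decision}"
                if memo.attached_decision
                else ""
            )
            lines.append(
                f"- [{memo.created_at.date().isoformat()}] **{memo.title}**"
                f"{suffix}: {memo.body}"
            )
    else:
        lines.append("none")
    lines.append("")

    lines.append("## Fact history")
    facts = history.current_facts(uri) if history is not None else []
    if facts:
        for fact in facts:
            lines.append(
                f"- {fact.question} = {fact.value!r} "
                f"({fact.timestamp.date().isoformat()}, {fact.author or fact.source.value})"
            )
    else:
        lines.append("no facts recorded")
    return "\n".join(lines) + "\n"
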