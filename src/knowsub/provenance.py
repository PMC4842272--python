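"""Fact history, the decision time machine, and decision memos.

Every answer about a substance is kept as an append-only, timestamped,
attributed fact; corrections are new facts, never edits, so the change
history (who entered what, when) stays transparent.  Timestamps are UTC
instants; a monotonically increasing sequence number breaks same-instant
ties.  The time machine reconstructs the decisions that were valid at any
earlier instant by evaluating the registry against the latest fact per
question at that time.

Memos are free-text notes attached to a substance, optionally carrying a
formal decision id; they are mirrored into the RDF store so dynamic SPARQL
views can reach them.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone

from rdflib import Literal, URIRef

from .engine import Fact, Source, evaluate
from .errors import ChronologyError, LinkError, NotFoundError
from .kb import UNKNOWN
from .parser import Registry
from .store import SubstanceStore

FACT_LOG_COLUMNS = [
    "substance",
    "question",
    "value",
    "timestamp",
    "seq",
    "author",
    "source",
    "reliability",
]


def _encode_value(value) -> str:
    if value is UNKNOWN:
        return json.dumps("Unknown")
    if isinstance(value, tuple):
        value = list(value)
    return json.dumps(value)


def _decode_value(text: str):
    value = json.loads(text)
    if value == "Unknown":
        return UNKNOWN
    if isinstance(value, list):
        return tuple(value)
    return value


class FactHistory:
    """Append-only, time-ordered fact log keyed by (substance, question)."""

    def __init__(self):
        self._entries: dict[tuple[str, str], list[Fact]] = {}
        self._seq = 0

    def record_fact(self, fact: Fact) -> Fact:
        """Append a fact; its timestamp may not precede the key's latest.

        The history assigns the tie-breaking sequence number; the stamped
        fact is returned.
        """
        key = (fact.substance, fact.question)
        entries = self._entries.setdefault(key, [])
        if entries and fact.timestamp < entries[-1].timestamp:
            raise ChronologyError(
                f"fact for {key} at {fact.timestamp.isoformat()} precedes "
                f"existing entry at {entries[-1].timestamp.isoformat()}"
            )
        stamped = replace(fact, seq=self._seq)
        self._seq += 1
        entries.append(stamped)
        return stamped

    def entries(self, substance: str, question: str) -> list[Fact]:
        return list(self._entries.get((substance, question), []))

    def all_facts(self) -> list[Fact]:
        out = [f for entries in self._entries.values() for f in entries]
        out.sort(key=lambda f: (f.timestamp, f.seq))
        return out

    def substances(self) -> list[str]:
        return sorted({s for s, _ in self._entries})

    def current_facts(self, substance: str) -> list[Fact]:
        """Latest fact per question for a substance."""
        return [
            entries[-1]
            for (subst, _), entries in sorted(self._entries.items())
            if subst == substance and entries
        ]

    def facts_at(self, substance: str, instant: datetime) -> list[Fact]:
        """Latest fact per question with timestamp <= instant."""
        out = []
        for (subst, _), entries in sorted(self._entries.items()):
            if subst != substance:
                continue
            eligible = [f for f in entries if f.timestamp <= instant]
            if eligible:
                out.append(eligible[-1])
        return out

    # -- CSV persistence --------------------------------------------------

    def save_csv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(FACT_LOG_COLUMNS)
            for f in self.all_facts():
                writer.writerow(
                    [
                        f.substance,
                        f.question,
                        _encode_value(f.value),
                        f.timestamp.isoformat(),
                        f.seq,
                        f.author,
                        f.source.value,
                        "" if f.reliability is None else f.reliability,
                    ]
                )

    @classmethod
    def load_csv(cls, path) -> "FactHistory":
        history = cls()
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            rows = sorted(
                reader, key=lambda r: (r["timestamp"], int(r["seq"] or 0))
            )
            for row in rows:
                history.record_fact(
                    Fact(
                        substance=row["substance"],
                        question=row["question"],
                        value=_decode_value(row["value"]),
                        timestamp=datetime.fromisoformat(row["timestamp"]),
                        author=row["author"],
                        source=Source(row["source"]),
                        reliability=int(row["reliability"])
                        if row["reliability"]
                        else None,
                    )
                )
        return history


def record_fact(history: FactHistory, fact: Fact) -> FactHistory:
    """Functional wrapper around :meth:`FactHistory.record_fact`."""
    history.record_fact(fact)
    return history


def decisions_at(
    registry: Registry, history: FactHistory, substance: str, instant: datetime
):
    """Decision map that was valid at ``instant`` (the time machine).

    Equals a fresh evaluation of the time-filtered fact log; with
    ``instant = now`` it equals the live evaluation.
    """
    return evaluate(registry, history.facts_at(substance, instant))


# -- memos ----------------------------------------------------------------


@dataclass(frozen=True)
class Memo:
    id: str
    substance: str
    title: str
    body: str = ""
    attached_decision: str | None = None
    author: str = ""
    created_at: datetime = field(
        default_factory=lambda: datetime.now(timezone.utc)
    )


class MemoLog:
    def __init__(self):
        self._memos: dict[str, Memo] = {}

    def for_substance(self, substance_uri: str) -> list[Memo]:
        """Memos for a substance, newest first."""
        memos = [m for m in self._memos.values() if m.substance == substance_uri]
        memos.sort(key=lambda m: (m.created_at, m.id), reverse=True)
        return memos

    def get(self, memo_id: str) -> Memo:
        if memo_id not in self._memos:
            raise NotFoundError(f"no memo with id {memo_id!r}")
        return self._memos[memo_id]

    def add(self, memo: Memo):
        self._memos[memo.id] = memo

    def __len__(self):
        return len(self._memos)

    def save_csv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["id", "substance", "title", "body", "attached_decision", "author", "created_at"]
            )
            for m in sorted(self._memos.values(), key=lambda m: (m.created_at, m.id)):
                writer.writerow(
                    [
                        m.id,
                        m.substance,
                        m.title,
                        m.body,
                        m.attached_decision or "",
                        m.author,
                        m.created_at.isoformat(),
                    ]
                )

    @classmethod
    def load_csv(cls, path) -> "MemoLog":
        log = cls()
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                log.add(
                    Memo(
                        id=row["id"],
                        substance=row["substance"],
                        title=row["title"],
                        body=row["body"],
                        attached_decision=row["attached_decision"] or None,
                        author=row["author"],
                        created_at=datetime.fromisoformat(row["created_at"]),
                    )
                )
        return log


def add_memo(
    store: SubstanceStore,
    memo_log: MemoLog,
    memo: Memo,
    registry: Registry | None = None,
) -> str:
    """Persist a memo and mirror it into the RDF store.

    The substance must exist; an attached decision must exist in the
    registry when one is given.
    """
    subject = store.substance_uri(memo.substance)
    if memo.attached_decision is not None and registry is not None:
        if memo.attached_decision not in registry.all_decisions():
            raise LinkError(
                f"memo {memo.id!r} attaches unknown decision "
                f"{memo.attached_decision!r}"
            )
    memo = replace(memo, substance=str(subject))
    memo_log.add(memo)
    ns = store.ns
    node = URIRef(f"{subject}--memo--{memo.id}")
    g = store.graph
    g.remove((node, None, None))
    g.add((subject, ns.hasMemo, node))
    g.add((node, ns.memoTitle, Literal(memo.title)))
    if memo.body:
        g.add((node, ns.memoBody, Literal(memo.body)))
    if memo.author:
        g.add((node, ns.memoAuthor, Literal(memo.author)))
    g.add((node, ns.memoCreatedAt, Literal(memo.created_at.isoformat())))
    if memo.attached_decision:
        g.add((node, ns.attachedDecision, ns[memo.attached_decision]))
    return memo.id
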