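"""Interactive interview sessions over a decision module.

The session keeps an agenda of indicated, unanswered questions.  The
agenda policy is workflow-reachability first: the ask nodes currently
reachable from a workflow's start via true-guard edges form the front, in
flow declaration order; after them come the module's declared init
questions (for rule-only modules, all declared questions in declaration
order).  Questions already answered — including values reused from other
modules — are never asked again.  "Unknown" is an admissible answer to any
question: it is recorded and leaves every condition on it undefined, which
is how screening practice skips unavailable data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timezone
from enum import Enum
from numbers import Number

from .engine import Fact, Source, as_fact_map, evaluate
from .errors import NotFoundError, ValidationError
from .kb import DecisionModule, NodeKind, Question, TRUE, UNKNOWN, ValueType, evaluate_condition
from .parser import Registry


class SessionStatus(str, Enum):
    running = "running"
    finished = "finished"


@dataclass
class InterviewSession:
    substance: str
    module: str
    registry: Registry
    agenda: list[str] = field(default_factory=list)
    answered: list[Fact] = field(default_factory=list)
    transcript: list[tuple[str, object]] = field(default_factory=list)

    @property
    def status(self) -> SessionStatus:
        return SessionStatus.finished if not self.agenda else SessionStatus.running

    def facts(self) -> list[Fact]:
        return list(self.answered)

    def decisions(self):
        return evaluate(self.registry, self.answered)


def _flow_front(module: DecisionModule, fact_map: dict) -> list[str]:
    """Ask-node questions reachable via true-guard edges, in flow order."""
    front: list[str] = []
    for wf in module.workflows:
        seen = {wf.start.id}
        queue = [wf.start.id]
        while queue:
            node_id = queue.pop(0)
            node = wf.node(node_id)
            if node.kind is NodeKind.ask and node.question not in front:
                front.append(node.question)
            for edge in wf.outgoing(node_id):
                if edge.target in seen:
                    continue
                if edge.guard is None or (
                    evaluate_condition(edge.guard, fact_map) is TRUE
                ):
                    seen.add(edge.target)
                    queue.append(edge.target)
    return front


def _compute_agenda(module: DecisionModule, facts) -> list[str]:
    fact_map = as_fact_map(facts)
    candidates = _flow_front(module, fact_map)
    init = module.init_questions
    if not init and not module.workflows:
        init = [q.id for q in module.questions]
    for qid in init:
        if qid not in candidates:
            candidates.append(qid)
    return [q for q in candidates if q not in fact_map]


def start_interview(
    registry: Registry, module_name: str, existing_facts=None, substance: str = ""
) -> InterviewSession:
    """Open a session for one module, skipping already-answered questions."""
    module = registry.module(module_name)
    existing = list(existing_facts or [])
    session = InterviewSession(
        substance=substance,
        module=module.name,
        registry=registry,
        answered=existing,
    )
    session.agenda = _compute_agenda(module, session.answered)
    return session


def _validate_answer(question: Question | None, value):
    if value is UNKNOWN or question is None:
        return
    vt = question.value_type
    if vt is ValueType.numeric:
        if not isinstance(value, Number) or isinstance(value, bool):
            raise ValidationError(
                f"question {question.id!r} expects a number, got {value!r}"
            )
    elif vt is ValueType.one_choice:
        if value not in question.choices:
            raise ValidationError(
                f"{value!r} is not a choice of {question.id!r} "
                f"(choices: {', '.join(question.choices)})"
            )
    elif vt is ValueType.multi_choice:
        values = value if isinstance(value, (list, tuple, set)) else (value,)
        bad = [v for v in values if v not in question.choices]
        if bad:
            raise ValidationError(
                f"{bad[0]!r} is not a choice of {question.id!r}"
            )


def answer(
    session: InterviewSession, question_id: str, value, author: str = "user"
) -> InterviewSession:
    """Record an answer, re-run inference and recompute the agenda.

    Answering a question that is not on the agenda is allowed (the fact is
    recorded) but warned about.  Returns the updated session.
    """
    registry = session.registry
    question = registry.all_questions().get(question_id)
    if question is None:
        raise NotFoundError(f"no question with id {question_id!r}")
    _validate_answer(question, value)
    if question_id not in session.agenda:
        import warnings

        warnings.warn(
            f"question {question_id!r} is not on the agenda", stacklevel=2
        )
    seq = len(session.answered)
    session.answered = [
        f for f in session.answered if f.question != question_id
    ]
    session.answered.append(
        Fact(
            substance=session.substance,
            question=question_id,
            value=value,
            timestamp=datetime.now(timezone.utc),
            author=author,
            source=Source.user,
            seq=seq,
        )
    )
    session.transcript.append((question_id, value))
    module = registry.module(session.module)
    session.agenda = _compute_agenda(module, session.answered)
    return session


def next_question(session: InterviewSession) -> str | None:
    """The agenda head, or None when the interview is finished."""
    return session.agenda[0] if session.agenda else None


def run_scripted(
    registry: Registry,
    module_name: str,
    answers: dict[str, object],
    existing_facts=None,
    substance: str = "",
) -> InterviewSession:
    """Drive a session from a question->answer script until finished.

    Questions the script cannot answer are answered "Unknown"; the
    transcript records the order actually asked.
    """
    session = start_interview(registry, module_name, existing_facts, substance)
    while (qid := next_question(session)) is not None:
        answer(session, qid, answers.get(qid, UNKNOWN))
    return session
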