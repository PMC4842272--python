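"""Decision derivation with truth maintenance.

The engine derives decision states from a substance's facts by stateless
full re-evaluation: every call recomputes all decisions from the current
fact set, so the result is independent of the order in which facts were
entered, and retracting a fact behaves exactly like a fresh session that
never saw it.  An incremental truth-maintenance system would save work at
the scale of hundreds of thousands of rules; at desk scale (hundreds of
rules per registry) the stateless pass is cheap and its correctness is
immediate.

Modules are evaluated once in dependency order.  Within a module, every
scoring rule whose condition is true fires and the category scores sum per
target decision; the summed score maps to a state through the registry's
:class:`~knowsub.kb.ScoreThresholds`.  Workflows then traverse from their
start node, taking the first edge (declaration order) whose guard is true
and executing decide nodes.  A workflow-decided state overrides a
rule-derived one, except that a rule-derived ``excluded`` is never
overridden upward (safety first; a warning is logged).
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from datetime import datetime, timezone
from enum import Enum

from .errors import NotFoundError
from .kb import (
    FlowNode,
    NodeKind,
    State,
    TRUE,
    Workflow,
    evaluate_condition,
)
from .parser import Registry
from .store import SubstanceStore

log = logging.getLogger(__name__)


class Source(str, Enum):
    user = "user"
    import_ = "import"
    derived = "derived"


@dataclass(frozen=True)
class Fact:
    """One timestamped, attributed answer to a question about a substance."""

    substance: str
    question: str
    value: object
    timestamp: datetime = field(
        default_factory=lambda: datetime.now(timezone.utc)
    )
    author: str = ""
    source: Source = Source.user
    reliability: int | None = None  # Klimisch score 1 (reliable) .. 4 (not assignable)
    seq: int = 0

    def __post_init__(self):
        if self.timestamp is None:
            raise ValueError("fact timestamp must be set")
        if self.reliability is not None and self.reliability not in (1, 2, 3, 4):
            raise ValueError("Klimisch reliability must be 1-4")


@dataclass(frozen=True)
class DecisionState:
    """Current rating of one decision, with its supporting evidence.

    ``support`` lists fired rule ids and/or active flow node ids.
    """

    decision: str
    state: State = State.undefined
    score: int = 0
    support: tuple[str, ...] = ()


@dataclass(frozen=True)
class Explanation:
    """Why a decision holds: the responsible facts with their entry dates."""

    decision: str
    state: State
    responsible_facts: tuple[tuple[str, object, datetime | None], ...]
    fired: tuple[str, ...]


@dataclass(frozen=True)
class Trace:
    """The reasoning path a workflow took for one fact set."""

    workflow: str
    visited_nodes: tuple[str, ...]
    taken_edges: tuple[str, ...]


def as_fact_map(facts) -> dict[str, object]:
    """Normalize a fact collection to {question id: value}.

    Accepts a mapping, an iterable of :class:`Fact` (latest by
    (timestamp, seq) wins per question), or None.
    """
    if facts is None:
        return {}
    if isinstance(facts, dict):
        return {q: getattr(v, "value", v) for q, v in facts.items()}
    latest: dict[str, Fact] = {}
    for f in facts:
        prev = latest.get(f.question)
        if prev is None or (f.timestamp, f.seq) >= (prev.timestamp, prev.seq):
            latest[f.question] = f
    return {q: f.value for q, f in latest.items()}


def _fact_objects(facts) -> dict[str, Fact]:
    """Latest Fact object per question, where available (for timestamps)."""
    if facts is None or isinstance(facts, dict):
        out = {}
        for q, v in (facts or {}).items():
            if isinstance(v, Fact):
                out[q] = v
        return out
    latest: dict[str, Fact] = {}
    for f in facts:
        prev = latest.get(f.question)
        if prev is None or (f.timestamp, f.seq) >= (prev.timestamp, prev.seq):
            latest[f.question] = f
    return latest


def evaluate(registry: Registry, facts) -> dict[str, DecisionState]:
    """Derive the state of every decision in the registry from ``facts``.

    Stateless: calling twice with equal fact sets gives identical output,
    and the result does not depend on fact insertion order.
    """
    fact_map = as_fact_map(facts)
    states: dict[str, DecisionState] = {
        did: DecisionState(did) for did in registry.all_decisions()
    }
    for module in registry.dependency_order():
        _evaluate_module(module, fact_map, states, registry)
    return states


def _evaluate_module(module, fact_map, states, registry):
    scores: dict[str, int] = defaultdict(int)
    support: dict[str, list[str]] = defaultdict(list)
    for rule in module.rules:
        if evaluate_condition(rule.condition, fact_map, states) is TRUE:
            scores[rule.target] += rule.score_category.score
            support[rule.target].append(rule.id)
    for target in scores:
        state = registry.thresholds.state_of(scores[target])
        states[target] = DecisionState(
            target, state, scores[target], tuple(support[target])
        )
    for workflow in module.workflows:
        trace = trace_workflow(workflow, fact_map, states)
        for node_id in trace.visited_nodes:
            node = workflow.node(node_id)
            if node.kind is NodeKind.decide:
                _apply_decide(states, node, registry)


def _apply_decide(states, node: FlowNode, registry):
    current = states.get(node.decision, DecisionState(node.decision))
    if (
        current.state is State.excluded
        and node.state in (State.established, State.suggested)
    ):
        log.warning(
            "decision %s: workflow state %s ignored, rule score %d keeps it excluded",
            node.decision,
            node.state.value,
            current.score,
        )
        new_state = State.excluded
    else:
        new_state = node.state
    support = current.support
    if node.id not in support:
        support = support + (node.id,)
    states[node.decision] = DecisionState(node.decision, new_state, current.score, support)


def trace_workflow(workflow: Workflow, facts, decision_states=None) -> Trace:
    """Deterministically traverse a workflow for a fact set.

    At each node, outgoing edges are tested in declaration order and the
    first true guard is taken (an unguarded edge counts as true); traversal
    stops at an exit node or when every guard is false or undefined.
    """
    fact_map = as_fact_map(facts)
    node = workflow.start
    visited = [node.id]
    taken: list[str] = []
    while node.kind is not NodeKind.exit:
        chosen = None
        n_true = 0
        for edge in workflow.outgoing(node.id):
            guard_true = edge.guard is None or (
                evaluate_condition(edge.guard, fact_map, decision_states) is TRUE
            )
            if guard_true:
                n_true += 1
                if chosen is None:
                    chosen = edge
        if chosen is None:
            break
        if n_true > 1:
            log.warning(
                "workflow %s: %d guards true at node %s, taking %s",
                workflow.name,
                n_true,
                node.id,
                chosen.id,
            )
        taken.append(chosen.id)
        node = workflow.node(chosen.target)
        visited.append(node.id)
    return Trace(workflow.name, tuple(visited), tuple(taken))


def retract(facts, question_id: str):
    """Remove a question's answer from a fact collection.

    Returns the reduced collection (same shape as the input); retracting an
    unanswered question is a no-op with a warning.  Re-evaluating the
    result is exactly a fresh session that never saw the fact — this is the
    operational meaning of non-monotonicity here.
    """
    if isinstance(facts, dict):
        if question_id not in facts:
            warnings.warn(f"question {question_id!r} was not answered", stacklevel=2)
            return dict(facts)
        return {q: v for q, v in facts.items() if q != question_id}
    fact_list = list(facts)
    if not any(f.question == question_id for f in fact_list):
        warnings.warn(f"question {question_id!r} was not answered", stacklevel=2)
        return fact_list
    return [f for f in fact_list if f.question != question_id]


def explain(registry: Registry, facts, decision_id: str) -> Explanation:
    """Responsible facts (with entry dates) behind a decision's state.

    Facts are collected from the rules that fired for the decision and the
    guards on the workflow path reaching its decide nodes; references to
    other modules' decisions are followed transitively, so explaining a
    combined decision (e.g. PBT) surfaces the facts behind each
    sub-decision.  Re-evaluating with only the responsible facts reproduces
    the explained state.
    """
    if decision_id not in registry.all_decisions():
        raise NotFoundError(f"no decision with id {decision_id!r}")
    fact_map = as_fact_map(facts)
    fact_objs = _fact_objects(facts)
    states = evaluate(registry, facts)

    questions: set[str] = set()
    fired: list[str] = []
    _collect(registry, fact_map, states, decision_id, questions, fired, set())

    responsible = tuple(
        sorted(
            (
                q,
                fact_map[q],
                fact_objs[q].timestamp if q in fact_objs else None,
            )
            for q in questions
            if q in fact_map
        )
    )
    return Explanation(
        decision=decision_id,
        state=states[decision_id].state,
        responsible_facts=responsible,
        fired=tuple(fired),
    )


def _collect(registry, fact_map, states, decision_id, questions, fired, seen):
    if decision_id in seen:
        return
    seen.add(decision_id)
    module_name = registry.module_of_decision(decision_id)
    if module_name is None:
        return
    module = registry.module(module_name)
    referenced_decisions: set[str] = set()
    for rule in module.rules:
        if rule.target != decision_id:
            continue
        if evaluate_condition(rule.condition, fact_map, states) is TRUE:
            fired.append(rule.id)
            questions |= rule.condition.question_ids()
            referenced_decisions |= rule.condition.decision_ids()
    for workflow in module.workflows:
        trace = trace_workflow(workflow, fact_map, states)
        decided_here = [
            nid
            for nid in trace.visited_nodes
            if workflow.node(nid).kind is NodeKind.decide
            and workflow.node(nid).decision == decision_id
        ]
        if not decided_here:
            continue
        fired.extend(trace.taken_edges)
        for edge_id in trace.taken_edges:
            edge = next(e for e in workflow.edges if e.id == edge_id)
            if edge.guard is not None:
                questions |= edge.guard.question_ids()
                referenced_decisions |= edge.guard.decision_ids()
    for dep in referenced_decisions:
        _collect(registry, fact_map, states, dep, questions, fired, seen)


def restrict_facts(facts, explanation: Explanation):
    """Keep only the facts an explanation names (for soundness checks)."""
    keep = {q for q, _, _ in explanation.responsible_facts}
    if isinstance(facts, dict):
        return {q: v for q, v in facts.items() if q in keep}
    return [f for f in facts if f.question in keep]


def mirror_decisions(
    store: SubstanceStore, substance: str, states: dict[str, DecisionState]
) -> None:
    """Mirror derived decision states into the RDF store (idempotent)."""
    store.mirror_decisions(substance, states)
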