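"""Decision-module knowledge representation.

A decision module bundles a question hierarchy, a decision hierarchy,
non-monotonic scoring rules and acyclic decision workflows.  Modules share
one terminology: a question answered in one module is visible to every
other, and a module may reuse the derived decisions of the modules it
declares in ``depends_on`` (e.g. a PBT module combining the persistence,
bioaccumulation and toxicity sub-decisions).

Conditions are evaluated under Kleene three-valued semantics
(true / false / undefined): a comparison on an unanswered question is
undefined, NOT(undefined) is undefined, AND short-circuits on false, OR on
true.  Rules never fire on undefined conditions — this is what keeps
explanations sound and interviews monotone.  The one deliberately
two-valued atom is ``known(q)``, true iff the question has been answered;
rules guarded by NOT known(q) are the non-monotonic escape hatch that may
unfire when data arrives.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from numbers import Number

from .errors import EvaluationError


class Truth(enum.Enum):
    """Three-valued truth lattice."""

    TRUE = "true"
    FALSE = "false"
    UNDEFINED = "undefined"


TRUE, FALSE, UNDEFINED = Truth.TRUE, Truth.FALSE, Truth.UNDEFINED


class Unknown:
    """Sentinel for an explicit 'Unknown' answer: recorded, but every
    comparison on it stays undefined."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):
        return "Unknown"


UNKNOWN = Unknown()


class ValueType(str, enum.Enum):
    one_choice = "one_choice"
    multi_choice = "multi_choice"
    numeric = "numeric"
    date = "date"
    text = "text"


class State(str, enum.Enum):
    """Rating of a decision for one substance."""

    established = "established"
    suggested = "suggested"
    undefined = "undefined"
    excluded = "excluded"


@dataclass(frozen=True)
class Question:
    id: str
    prompt: str = ""
    value_type: ValueType = ValueType.text
    choices: tuple[str, ...] = ()
    unit: str | None = None
    parent: str | None = None
    explanation: str | None = None

    def __post_init__(self):
        is_choice = self.value_type in (ValueType.one_choice, ValueType.multi_choice)
        if is_choice and not self.choices:
            raise ValueError(f"question {self.id!r}: choice type needs choices")
        if not is_choice and self.choices:
            raise ValueError(f"question {self.id!r}: only choice types take choices")


@dataclass(frozen=True)
class DecisionNode:
    id: str
    label: str = ""
    parent: str | None = None
    module: str = ""


# -- conditions -----------------------------------------------------------


class Condition:
    """Base class; concrete nodes below form the condition tree."""

    def question_ids(self) -> set[str]:
        return set()

    def decision_ids(self) -> set[str]:
        return set()


@dataclass(frozen=True)
class And(Condition):
    children: tuple[Condition, ...]

    def question_ids(self):
        return set().union(*(c.question_ids() for c in self.children))

    def decision_ids(self):
        return set().union(*(c.decision_ids() for c in self.children))


@dataclass(frozen=True)
class Or(Condition):
    children: tuple[Condition, ...]

    def question_ids(self):
        return set().union(*(c.question_ids() for c in self.children))

    def decision_ids(self):
        return set().union(*(c.decision_ids() for c in self.children))


@dataclass(frozen=True)
class Not(Condition):
    child: Condition

    def question_ids(self):
        return self.child.question_ids()

    def decision_ids(self):
        return self.child.decision_ids()


@dataclass(frozen=True)
class Compare(Condition):
    """``question <op> literal`` with op in =, !=, <, <=, >, >=, in."""

    question: str
    op: str
    literal: object

    def question_ids(self):
        return {self.question}


@dataclass(frozen=True)
class Known(Condition):
    question: str

    def question_ids(self):
        return {self.question}


@dataclass(frozen=True)
class DecisionIs(Condition):
    """``decision_state(decision, state)`` — reuse of another module's result."""

    decision: str
    state: State

    def decision_ids(self):
        return {self.decision}


_NUMERIC_OPS = {"<", "<=", ">", ">="}


def _compare(value, op: str, literal) -> Truth:
    if op in _NUMERIC_OPS:
        if not isinstance(value, Number) or isinstance(value, bool):
            raise EvaluationError(
                f"numeric comparison {op!r} on non-numeric answer {value!r}"
            )
        if not isinstance(literal, Number):
            raise EvaluationError(f"numeric comparison against {literal!r}")
        result = {
            "<": value < literal,
            "<=": value <= literal,
            ">": value > literal,
            ">=": value >= literal,
        }[op]
    elif op == "=":
        result = _eq(value, literal)
    elif op == "!=":
        result = not _eq(value, literal)
    elif op == "in":
        options = literal if isinstance(literal, (tuple, list, set)) else (literal,)
        if isinstance(value, (tuple, list, set)):  # multi-choice answer
            result = any(_eq(v, o) for v in value for o in options)
        else:
            result = any(_eq(value, o) for o in options)
    else:
        raise EvaluationError(f"unknown operator {op!r}")
    return TRUE if result else FALSE


def _eq(value, literal) -> bool:
    if isinstance(value, (tuple, list, set)) and not isinstance(
        literal, (tuple, list, set)
    ):
        return literal in value
    return value == literal


def evaluate_condition(
    condition: Condition,
    facts: dict,
    decision_states: dict | None = None,
) -> Truth:
    """Evaluate a condition tree under three-valued semantics.

    ``facts`` maps question id -> answer value (possibly partial); an
    absent or :data:`UNKNOWN` answer makes comparisons undefined.
    ``decision_states`` maps decision id -> :class:`State` for
    ``decision_state`` atoms; an absent entry counts as undefined state.
    """
    if isinstance(condition, And):
        saw_undef = False
        for child in condition.children:
            t = evaluate_condition(child, facts, decision_states)
            if t is FALSE:
                return FALSE
            if t is UNDEFINED:
                saw_undef = True
        return UNDEFINED if saw_undef else TRUE
    if isinstance(condition, Or):
        saw_undef = False
        for child in condition.children:
            t = evaluate_condition(child, facts, decision_states)
            if t is TRUE:
                return TRUE
            if t is UNDEFINED:
                saw_undef = True
        return UNDEFINED if saw_undef else FALSE
    if isinstance(condition, Not):
        t = evaluate_condition(condition.child, facts, decision_states)
        return {TRUE: FALSE, FALSE: TRUE, UNDEFINED: UNDEFINED}[t]
    if isinstance(condition, Known):
        return TRUE if condition.question in facts else FALSE
    if isinstance(condition, Compare):
        value = facts.get(condition.question)
        if value is None or value is UNKNOWN:
            return UNDEFINED
        return _compare(value, condition.op, condition.literal)
    if isinstance(condition, DecisionIs):
        states = decision_states or {}
        current = states.get(condition.decision)
        current = getattr(current, "state", current)  # accept DecisionState
        if current is None or current is State.undefined:
            return UNDEFINED
        return TRUE if current is condition.state else FALSE
    raise EvaluationError(f"unknown condition node {condition!r}")


# -- scoring rules --------------------------------------------------------

#: Heuristic score categories: N7..N1 negative, P1..P7 positive, with
#: magnitudes 1, 2, 5, 10, 20, 40, 80 for index 1..7.
_MAGNITUDES = {1: 1, 2: 2, 3: 5, 4: 10, 5: 20, 6: 40, 7: 80}


class ScoreCategory(str, enum.Enum):
    N7 = "N7"; N6 = "N6"; N5 = "N5"; N4 = "N4"; N3 = "N3"; N2 = "N2"; N1 = "N1"
    P1 = "P1"; P2 = "P2"; P3 = "P3"; P4 = "P4"; P5 = "P5"; P6 = "P6"; P7 = "P7"

    @property
    def score(self) -> int:
        sign = 1 if self.value[0] == "P" else -1
        return sign * _MAGNITUDES[int(self.value[1])]


@dataclass(frozen=True)
class ScoringRule:
    id: str
    condition: Condition
    target: str
    score_category: ScoreCategory


@dataclass(frozen=True)
class ScoreThresholds:
    """Score-to-state mapping for rule-derived decisions.

    A decision is established at score >= 42, suggested at >= 10, excluded
    at <= -42, undefined otherwise; at a conflict the excluded band wins
    (safety first).
    """

    established: int = 42
    suggested: int = 10
    excluded: int = -42

    def state_of(self, score: int) -> State:
        if score <= self.excluded:
            return State.excluded
        if score >= self.established:
            return State.established
        if score >= self.suggested:
            return State.suggested
        return State.undefined


# -- workflows ------------------------------------------------------------


class NodeKind(str, enum.Enum):
    start = "start"
    ask = "ask"
    decide = "decide"
    exit = "exit"


@dataclass(frozen=True)
class FlowNode:
    id: str
    kind: NodeKind
    question: str | None = None          # ask nodes
    decision: str | None = None          # decide nodes
    state: State | None = None           # decide nodes


@dataclass(frozen=True)
class FlowEdge:
    source: str
    target: str
    guard: Condition | None = None

    @property
    def id(self) -> str:
        return f"{self.source}->{self.target}"


@dataclass(frozen=True)
class Workflow:
    """A directed acyclic decision flow with guarded edges.

    Exactly one start node; traversal follows the first edge (in
    declaration order) whose guard is true, executing decide nodes on the
    way, and stops at an exit node or when no guard holds.
    """

    name: str
    nodes: tuple[FlowNode, ...]
    edges: tuple[FlowEdge, ...]

    def node(self, node_id: str) -> FlowNode:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise KeyError(node_id)

    @property
    def start(self) -> FlowNode:
        starts = [n for n in self.nodes if n.kind is NodeKind.start]
        if len(starts) != 1:
            raise ValueError(f"workflow {self.name!r} has {len(starts)} start nodes")
        return starts[0]

    def outgoing(self, node_id: str) -> tuple[FlowEdge, ...]:
        return tuple(e for e in self.edges if e.source == node_id)


@dataclass
class DecisionModule:
    """One criterion's knowledge base (questions, decisions, rules, flows)."""

    name: str
    questions: list[Question] = field(default_factory=list)
    decisions: list[DecisionNode] = field(default_factory=list)
    rules: list[ScoringRule] = field(default_factory=list)
    workflows: list[Workflow] = field(default_factory=list)
    depends_on: list[str] = field(default_factory=list)
    init_questions: list[str] = field(default_factory=list)

    def question(self, qid: str) -> Question | None:
        for q in self.questions:
            if q.id == qid:
                return q
        return None

    def question_ids(self) -> set[str]:
        return {q.id for q in self.questions}

    def decision_ids(self) -> set[str]:
        return {d.id for d in self.decisions}

    def __eq__(self, other):
        if not isinstance(other, DecisionModule):
            return NotImplemented
        return (
            self.name == other.name
            and self.questions == other.questions
            and self.decisions == other.decisions
            and self.rules == other.rules
            and self.workflows == other.workflows
            and self.depends_on == other.depends_on
            and self.init_questions == other.init_questions
        )
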