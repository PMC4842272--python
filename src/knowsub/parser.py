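"""Plain-text dialect for decision modules, plus the module registry.

A ``.kb`` file is line-oriented UTF-8 with ``#`` comments; indentation (two
spaces per level) expresses the question/decision hierarchies::

    MODULE Persistence
    DEPENDS: OtherModule

    QUESTIONS
    ThCO2 (numeric) [%] "Degradation after 28 d as % ThCO2"
      ? Pass level of the ready-biodegradability test series.
    BCF_available (one_choice: yes | no) "Is a measured BCF available?"
      BCF (numeric) [L/kg] "Bioconcentration factor"

    DECISIONS
    ReadyBiodegradability "Ready biodegradability"
      NotReadilyBiodegradable "not readily biodegradable"

    RULES
    r1: IF ThCO2 < 60 OR ThOD < 60 OR DOC < 70 THEN NotReadilyBiodegradable P7

    FLOW BioFlow
    start s0
    ask a1 BCF_available
    decide d_vB vB established
    exit end
    edge s0 -> a1
    edge a1 -> d_vB IF BCF >= 5000

    INIT: ThCO2, ThOD, DOC

Conditions use ``AND`` / ``OR`` / ``NOT`` (OR binds loosest), comparisons
``=  !=  <  <=  >  >=  in`` with ``in {a, b}`` set literals, ``KNOWN[q]``
atoms and ``DECISION[d] = state`` atoms for reusing another module's
derived decision.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import networkx as nx

from .errors import LinkError, ParseError, RegistryError, StructureError
from .kb import (
    And,
    Compare,
    Condition,
    DecisionIs,
    DecisionModule,
    DecisionNode,
    FlowEdge,
    FlowNode,
    Known,
    NodeKind,
    Not,
    Or,
    Question,
    ScoreCategory,
    ScoreThresholds,
    ScoringRule,
    State,
    ValueType,
    Workflow,
)

_SECTION_RE = re.compile(
    r"^(MODULE|DEPENDS|QUESTIONS|DECISIONS|RULES|FLOW|INIT)\b"
)
_QUESTION_RE = re.compile(
    r"^(?P<id>[\w.-]+)\s*\((?P<type>[^)]*)\)\s*(?:\[(?P<unit>[^\]]*)\]\s*)?"
    r'(?:"(?P<prompt>[^"]*)")?\s*$'
)
_DECISION_RE = re.compile(r'^(?P<id>[\w.-]+)\s*(?:"(?P<label>[^"]*)")?\s*$')
_RULE_RE = re.compile(
    r"^(?P<id>[\w.-]+)\s*:\s*IF\s+(?P<cond>.+?)\s+THEN\s+"
    r"(?P<target>[\w.-]+)\s+(?P<cat>[NP][1-7])\s*$",
    re.DOTALL,
)

_WORD_SAFE = re.compile(r"^[\w.-]+$")


# -- condition expression parsing -----------------------------------------

_TOKEN_RE = re.compile(
    r"""\s*(?:
        (?P<string>"[^"]*")
      | (?P<number>-?\d+\.\d+|-?\d+)
      | (?P<op><=|>=|!=|≤|≥|≠|=|<|>)
      | (?P<punct>[()\[\]{},])
      | (?P<word>[\w.-]+)
    )""",
    re.VERBOSE,
)

_OP_CANON = {"≤": "<=", "≥": ">=", "≠": "!="}


def _tokenize(text: str, line: int | None) -> list[tuple[str, object]]:
    tokens, pos = [], 0
    while pos < len(text):
        if text[pos].isspace():
            pos += 1
            continue
        m = _TOKEN_RE.match(text, pos)
        if not m:
            raise ParseError(f"bad condition syntax near {text[pos:pos+15]!r}", line)
        if m.group("string") is not None:
            tokens.append(("string", m.group("string")[1:-1]))
        elif m.group("number") is not None:
            raw = m.group("number")
            tokens.append(("number", float(raw) if "." in raw else int(raw)))
        elif m.group("op") is not None:
            tokens.append(("op", _OP_CANON.get(m.group("op"), m.group("op"))))
        elif m.group("punct") is not None:
            tokens.append(("punct", m.group("punct")))
        else:
            tokens.append(("word", m.group("word")))
        pos = m.end()
    return tokens


class _CondParser:
    """Recursive-descent parser for the condition grammar."""

    def __init__(self, text: str, line: int | None = None):
        self.tokens = _tokenize(text, line)
        self.pos = 0
        self.line = line

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else (None, None)

    def next(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def expect(self, kind, value=None):
        k, v = self.next()
        if k != kind or (value is not None and v != value):
            raise ParseError(
                f"expected {value or kind}, got {v!r} in condition", self.line
            )
        return v

    def parse(self) -> Condition:
        cond = self.parse_or()
        if self.peek() != (None, None):
            raise ParseError(
                f"trailing tokens in condition: {self.peek()[1]!r}", self.line
            )
        return cond

    def parse_or(self) -> Condition:
        parts = [self.parse_and()]
        while self.peek() == ("word", "OR"):
            self.next()
            parts.append(self.parse_and())
        return parts[0] if len(parts) == 1 else Or(tuple(parts))

    def parse_and(self) -> Condition:
        parts = [self.parse_unary()]
        while self.peek() == ("word", "AND"):
            self.next()
            parts.append(self.parse_unary())
        return parts[0] if len(parts) == 1 else And(tuple(parts))

    def parse_unary(self) -> Condition:
        kind, value = self.peek()
        if (kind, value) == ("word", "NOT"):
            self.next()
            return Not(self.parse_unary())
        if (kind, value) == ("punct", "("):
            self.next()
            inner = self.parse_or()
            self.expect("punct", ")")
            return inner
        return self.parse_atom()

    def parse_atom(self) -> Condition:
        kind, value = self.next()
        if kind != "word":
            raise ParseError(f"expected identifier, got {value!r}", self.line)
        if value == "KNOWN":
            self.expect("punct", "[")
            _, qid = self.next()
            self.expect("punct", "]")
            return Known(str(qid))
        if value == "DECISION":
            self.expect("punct", "[")
            _, did = self.next()
            self.expect("punct", "]")
            op = self.expect("op")
            _, state = self.next()
            try:
                atom = DecisionIs(str(did), State(str(state)))
            except ValueError:
                raise ParseError(f"unknown decision state {state!r}", self.line)
            return Not(atom) if op == "!=" else atom
        qid = value
        kind, op = self.next()
        if (kind, op) == ("word", "in"):
            return Compare(qid, "in", self._parse_set())
        if kind != "op":
            raise ParseError(f"expected operator after {qid!r}", self.line)
        _, literal = self.next()
        return Compare(qid, op, literal)

    def _parse_set(self) -> tuple:
        self.expect("punct", "{")
        items = []
        while True:
            kind, value = self.next()
            if (kind, value) == ("punct", "}"):
                break
            if (kind, value) == ("punct", ","):
                continue
            items.append(value)
        return tuple(items)


def parse_condition(text: str, line: int | None = None) -> Condition:
    """Parse a condition expression (see module docstring for the grammar)."""
    return _CondParser(text, line).parse()


def serialize_condition(cond: Condition, parent: str = "or") -> str:
    """Render a condition tree back to the dialect; inverse of parsing."""
    if isinstance(cond, Or):
        text = " OR ".join(serialize_condition(c, "or") for c in cond.children)
        return f"({text})" if parent in ("and", "not") else text
    if isinstance(cond, And):
        text = " AND ".join(serialize_condition(c, "and") for c in cond.children)
        return f"({text})" if parent == "not" else text
    if isinstance(cond, Not):
        return f"NOT {serialize_condition(cond.child, 'not')}"
    if isinstance(cond, Known):
        return f"KNOWN[{cond.question}]"
    if isinstance(cond, DecisionIs):
        return f"DECISION[{cond.decision}] = {cond.state.value}"
    if isinstance(cond, Compare):
        return f"{cond.question} {cond.op} {_literal(cond.literal)}"
    raise ValueError(f"cannot serialize {cond!r}")


def _literal(value) -> str:
    if isinstance(value, tuple):
        return "{" + ", ".join(_literal(v) for v in value) + "}"
    if isinstance(value, str):
        return value if _WORD_SAFE.match(value) else f'"{value}"'
    return repr(value)


# -- module file parsing --------------------------------------------------


def _indent_depth(line: str, lineno: int) -> int:
    stripped = line.lstrip(" ")
    spaces = len(line) - len(stripped)
    if spaces % 2:
        raise ParseError("indentation must be multiples of two spaces", lineno)
    return spaces // 2


def parse_module(
    text: str,
    known_questions: set[str] | None = None,
    known_decisions: set[str] | None = None,
) -> DecisionModule:
    """Parse a ``.kb`` module file into a fully linked :class:`DecisionModule`.

    References in rules and flow guards must resolve against this module's
    declarations or the ``known_*`` context (terminology shared with
    dependency modules); an unresolved id raises :class:`LinkError` with the
    line number.
    """
    known_questions = set(known_questions or ())
    known_decisions = set(known_decisions or ())
    module = DecisionModule(name="")
    section = None
    flow_name = None
    flow_nodes: list[FlowNode] = []
    flow_edges: list[FlowEdge] = []
    parent_stack: list[tuple[int, str]] = []  # (depth, id) for hierarchies
    last_question: str | None = None
    pending_refs: list[tuple[Condition, int]] = []

    def close_flow():
        nonlocal flow_name, flow_nodes, flow_edges
        if flow_name is not None:
            module.workflows.append(
                _build_workflow(flow_name, flow_nodes, flow_edges)
            )
            flow_name, flow_nodes, flow_edges = None, [], []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].rstrip() if not raw.lstrip().startswith("?") else raw.rstrip()
        if not line.strip():
            continue
        head = _SECTION_RE.match(line)
        if head and not line.startswith(" "):
            close_flow()
            section = head.group(1)
            rest = line[head.end():].lstrip(" :")
            if section == "MODULE":
                module.name = rest.strip()
            elif section == "DEPENDS":
                module.depends_on = [d.strip() for d in rest.split(",") if d.strip()]
            elif section == "INIT":
                module.init_questions = [q.strip() for q in rest.split(",") if q.strip()]
            elif section == "FLOW":
                flow_name = rest.strip() or f"flow{len(module.workflows) + 1}"
            parent_stack = []
            last_question = None
            continue
        if section == "QUESTIONS":
            depth = _indent_depth(line, lineno)
            body = line.strip()
            if body.startswith("?"):
                if last_question is None:
                    raise ParseError("explanation with no preceding question", lineno)
                q = module.question(last_question)
                extra = body[1:].strip()
                text_now = f"{q.explanation} {extra}".strip() if q.explanation else extra
                module.questions[module.questions.index(q)] = Question(
                    q.id, q.prompt, q.value_type, q.choices, q.unit, q.parent, text_now
                )
                continue
            m = _QUESTION_RE.match(body)
            if not m:
                raise ParseError(f"bad question declaration: {body!r}", lineno)
            parent_stack = [(d, i) for d, i in parent_stack if d < depth]
            parent = parent_stack[-1][1] if parent_stack else None
            vtype, choices = _parse_value_type(m.group("type"), lineno)
            try:
                q = Question(
                    id=m.group("id"),
                    prompt=m.group("prompt") or "",
                    value_type=vtype,
                    choices=choices,
                    unit=m.group("unit"),
                    parent=parent,
                )
            except ValueError as exc:
                raise ParseError(str(exc), lineno)
            if q.id in module.question_ids():
                raise ParseError(f"duplicate question id {q.id!r}", lineno)
            module.questions.append(q)
            parent_stack.append((depth, q.id))
            last_question = q.id
        elif section == "DECISIONS":
            depth = _indent_depth(line, lineno)
            m = _DECISION_RE.match(line.strip())
            if not m:
                raise ParseError(f"bad decision declaration: {line.strip()!r}", lineno)
            parent_stack = [(d, i) for d, i in parent_stack if d < depth]
            parent = parent_stack[-1][1] if parent_stack else None
            node = DecisionNode(
                id=m.group("id"),
                label=m.group("label") or m.group("id"),
                parent=parent,
                module=module.name,
            )
            if node.id in module.decision_ids():
                raise ParseError(f"duplicate decision id {node.id!r}", lineno)
            module.decisions.append(node)
            parent_stack.append((depth, node.id))
        elif section == "RULES":
            m = _RULE_RE.match(line.strip())
            if not m:
                raise ParseError(f"bad rule declaration: {line.strip()!r}", lineno)
            cond = parse_condition(m.group("cond"), lineno)
            rule = ScoringRule(
                id=m.group("id"),
                condition=cond,
                target=m.group("target"),
                score_category=ScoreCategory(m.group("cat")),
            )
            module.rules.append(rule)
            pending_refs.append((cond, lineno))
            if m.group("target") not in module.decision_ids():
                raise LinkError(
                    f"rule {rule.id!r} targets undeclared decision {rule.target!r}",
                    lineno,
                )
        elif section == "FLOW":
            _parse_flow_line(line.strip(), lineno, flow_nodes, flow_edges, pending_refs)
        elif section in ("MODULE", "DEPENDS", "INIT"):
            raise ParseError(f"unexpected content in {section} section", lineno)
        else:
            raise ParseError(f"content before any section: {line.strip()!r}", lineno)

    close_flow()
    _check_links(module, pending_refs, known_questions, known_decisions)
    _check_hierarchies(module)
    return module


def _parse_value_type(spec: str, lineno: int) -> tuple[ValueType, tuple[str, ...]]:
    spec = spec.strip()
    if ":" in spec:
        name, _, choice_text = spec.partition(":")
        choices = tuple(c.strip() for c in choice_text.split("|") if c.strip())
    else:
        name, choices = spec, ()
    try:
        return ValueType(name.strip()), choices
    except ValueError:
        raise ParseError(f"unknown value type {name.strip()!r}", lineno)


def _parse_flow_line(line, lineno, nodes, edges, pending_refs):
    parts = line.split(None, 1)
    keyword = parts[0]
    rest = parts[1] if len(parts) > 1 else ""
    if keyword in ("start", "exit"):
        nodes.append(FlowNode(id=rest.strip(), kind=NodeKind(keyword)))
    elif keyword == "ask":
        try:
            node_id, question = rest.split()
        except ValueError:
            raise ParseError(f"ask node needs '<id> <question>': {line!r}", lineno)
        nodes.append(FlowNode(id=node_id, kind=NodeKind.ask, question=question))
    elif keyword == "decide":
        try:
            node_id, decision, state = rest.split()
        except ValueError:
            raise ParseError(
                f"decide node needs '<id> <decision> <state>': {line!r}", lineno
            )
        try:
            st = State(state)
        except ValueError:
            raise ParseError(f"unknown decision state {state!r}", lineno)
        nodes.append(
            FlowNode(id=node_id, kind=NodeKind.decide, decision=decision, state=st)
        )
    elif keyword == "edge":
        m = re.match(r"^([\w.-]+)\s*->\s*([\w.-]+)(?:\s+IF\s+(.+))?$", rest)
        if not m:
            raise ParseError(f"bad edge declaration: {line!r}", lineno)
        guard = parse_condition(m.group(3), lineno) if m.group(3) else None
        edges.append(FlowEdge(m.group(1), m.group(2), guard))
        if guard is not None:
            pending_refs.append((guard, lineno))
    else:
        raise ParseError(f"unknown flow statement {keyword!r}", lineno)


def _build_workflow(name, nodes, edges) -> Workflow:
    ids = [n.id for n in nodes]
    if len(ids) != len(set(ids)):
        raise StructureError(f"workflow {name!r} has duplicate node ids")
    id_set = set(ids)
    for e in edges:
        for end in (e.source, e.target):
            if end not in id_set:
                raise StructureError(f"workflow {name!r}: unknown node {end!r} in edge")
    wf = Workflow(name=name, nodes=tuple(nodes), edges=tuple(edges))
    graph = nx.DiGraph()
    graph.add_nodes_from(ids)
    graph.add_edges_from((e.source, e.target) for e in edges)
    if not nx.is_directed_acyclic_graph(graph):
        raise StructureError(f"workflow {name!r} contains a cycle")
    wf.start  # noqa: B018 — raises if start count != 1
    for n in nodes:
        if n.kind is not NodeKind.exit and not wf.outgoing(n.id):
            raise StructureError(
                f"workflow {name!r}: non-exit node {n.id!r} has no outgoing edge"
            )
    return wf


def _check_links(module, pending_refs, known_questions, known_decisions):
    qids = module.question_ids() | known_questions
    dids = module.decision_ids() | known_decisions
    for cond, lineno in pending_refs:
        for q in cond.question_ids():
            if q not in qids:
                raise LinkError(f"reference to undeclared question {q!r}", lineno)
        for d in cond.decision_ids():
            if d not in dids:
                raise LinkError(f"reference to undeclared decision {d!r}", lineno)
    for wf in module.workflows:
        for n in wf.nodes:
            if n.kind is NodeKind.ask and n.question not in qids:
                raise LinkError(
                    f"workflow {wf.name!r} asks undeclared question {n.question!r}"
                )
            if n.kind is NodeKind.decide and n.decision not in dids:
                raise LinkError(
                    f"workflow {wf.name!r} decides undeclared decision {n.decision!r}"
                )
    for q in module.init_questions:
        if q not in qids:
            raise LinkError(f"INIT references undeclared question {q!r}")


def _check_hierarchies(module):
    for items, kind in ((module.questions, "question"), (module.decisions, "decision")):
        ids = {i.id for i in items}
        for item in items:
            if item.parent is not None and item.parent not in ids:
                raise StructureError(
                    f"{kind} {item.id!r} has unknown parent {item.parent!r}"
                )


# -- serialization --------------------------------------------------------


def serialize_module(module: DecisionModule) -> str:
    """Render a module back to the ``.kb`` dialect (parse∘serialize = id)."""
    out = [f"MODULE {module.name}"]
    if module.depends_on:
        out.append("DEPENDS: " + ", ".join(module.depends_on))
    if module.questions:
        out.append("")
        out.append("QUESTIONS")
        depth_of = {q.id: 0 for q in module.questions}
        for q in module.questions:
            depth = 0 if q.parent is None else depth_of[q.parent] + 1
            depth_of[q.id] = depth
            type_spec = q.value_type.value
            if q.choices:
                type_spec += ": " + " | ".join(q.choices)
            parts = [f"{q.id} ({type_spec})"]
            if q.unit:
                parts.append(f"[{q.unit}]")
            if q.prompt:
                parts.append(f'"{q.prompt}"')
            out.append("  " * depth + " ".join(parts))
            if q.explanation:
                out.append("  " * (depth + 1) + f"? {q.explanation}")
    if module.decisions:
        out.append("")
        out.append("DECISIONS")
        depth_of = {}
        for d in module.decisions:
            depth = 0 if d.parent is None else depth_of[d.parent] + 1
            depth_of[d.id] = depth
            out.append("  " * depth + f'{d.id} "{d.label}"')
    if module.rules:
        out.append("")
        out.append("RULES")
        for r in module.rules:
            out.append(
                f"{r.id}: IF {serialize_condition(r.condition)} "
                f"THEN {r.target} {r.score_category.value}"
            )
    for wf in module.workflows:
        out.append("")
        out.append(f"FLOW {wf.name}")
        for n in wf.nodes:
            if n.kind is NodeKind.ask:
                out.append(f"ask {n.id} {n.question}")
            elif n.kind is NodeKind.decide:
                out.append(f"decide {n.id} {n.decision} {n.state.value}")
            else:
                out.append(f"{n.kind.value} {n.id}")
        for e in wf.edges:
            suffix = f" IF {serialize_condition(e.guard)}" if e.guard else ""
            out.append(f"edge {e.source} -> {e.target}{suffix}")
    if module.init_questions:
        out.append("")
        out.append("INIT: " + ", ".join(module.init_questions))
    return "\n".join(out) + "\n"


# -- registry -------------------------------------------------------------


@dataclass(frozen=True)
class Issue:
    kind: str
    detail: str


@dataclass
class Registry:
    """All loaded decision modules plus the shared scoring configuration."""

    modules: dict[str, DecisionModule]
    thresholds: ScoreThresholds = ScoreThresholds()

    def module(self, name: str) -> DecisionModule:
        if name not in self.modules:
            from .errors import NotFoundError

            raise NotFoundError(f"no module named {name!r}")
        return self.modules[name]

    def dependency_order(self) -> list[DecisionModule]:
        graph = nx.DiGraph()
        graph.add_nodes_from(self.modules)
        for mod in self.modules.values():
            for dep in mod.depends_on:
                if dep in self.modules:
                    graph.add_edge(dep, mod.name)
        try:
            order = list(nx.lexicographical_topological_sort(graph))
        except nx.NetworkXUnfeasible:
            raise RegistryError("module dependency cycle")
        return [self.modules[name] for name in order]

    def all_questions(self) -> dict[str, Question]:
        out = {}
        for mod in self.modules.values():
            for q in mod.questions:
                out.setdefault(q.id, q)
        return out

    def all_decisions(self) -> dict[str, DecisionNode]:
        out = {}
        for mod in self.modules.values():
            for d in mod.decisions:
                out.setdefault(d.id, d)
        return out

    def module_of_decision(self, decision_id: str) -> str | None:
        for mod in self.modules.values():
            if decision_id in mod.decision_ids():
                return mod.name
        return None


def load_registry(paths_or_texts, thresholds: ScoreThresholds | None = None) -> Registry:
    """Load modules in order, sharing terminology across files.

    ``paths_or_texts`` is a sequence of file paths or raw module texts;
    later modules may reference questions/decisions of earlier ones.
    """
    modules: dict[str, DecisionModule] = {}
    known_q: set[str] = set()
    known_d: set[str] = set()
    for item in paths_or_texts:
        text = item
        if "\n" not in str(item):
            with open(item, encoding="utf-8") as fh:
                text = fh.read()
        mod = parse_module(text, known_questions=known_q, known_decisions=known_d)
        if mod.name in modules:
            raise RegistryError(f"module {mod.name!r} loaded twice")
        modules[mod.name] = mod
        known_q |= mod.question_ids()
        known_d |= mod.decision_ids()
    return Registry(modules=modules, thresholds=thresholds or ScoreThresholds())


def validate_registry(registry: Registry | dict) -> list[Issue]:
    """Well-formedness report for a module registry; empty iff clean."""
    modules = registry.modules if isinstance(registry, Registry) else dict(registry)
    issues: list[Issue] = []
    seen_q: dict[str, str] = {}
    seen_d: dict[str, str] = {}
    for mod in modules.values():
        for q in mod.questions:
            if q.id in seen_q:
                issues.append(
                    Issue(
                        "duplicate-id",
                        f"question {q.id!r} declared in both "
                        f"{seen_q[q.id]!r} and {mod.name!r}",
                    )
                )
            else:
                seen_q[q.id] = mod.name
        for d in mod.decisions:
            if d.id in seen_d:
                issues.append(
                    Issue(
                        "duplicate-id",
                        f"decision {d.id!r} declared in both "
                        f"{seen_d[d.id]!r} and {mod.name!r}",
                    )
                )
            else:
                seen_d[d.id] = mod.name

    graph = nx.DiGraph()
    graph.add_nodes_from(modules)
    for mod in modules.values():
        for dep in mod.depends_on:
            if dep not in modules:
                issues.append(
                    Issue(
                        "dangling-dependency",
                        f"module {mod.name!r} depends on missing {dep!r}",
                    )
                )
            else:
                graph.add_edge(dep, mod.name)
    if not nx.is_directed_acyclic_graph(graph):
        issues.append(Issue("dependency-cycle", "module dependencies form a cycle"))

    for mod in modules.values():
        reachable_deps = _transitive_deps(mod.name, modules)
        for rule in mod.rules:
            if rule.target not in mod.decision_ids():
                issues.append(
                    Issue(
                        "foreign-target",
                        f"rule {rule.id!r} in {mod.name!r} targets "
                        f"{rule.target!r} outside the module",
                    )
                )
            for did in rule.condition.decision_ids():
                owner = seen_d.get(did)
                if owner == mod.name:
                    issues.append(
                        Issue(
                            "self-reference",
                            f"rule {rule.id!r} in {mod.name!r} tests decision "
                            f"{did!r} of its own module",
                        )
                    )
                elif owner is not None and owner not in reachable_deps:
                    issues.append(
                        Issue(
                            "undeclared-dependency",
                            f"module {mod.name!r} uses decision {did!r} of "
                            f"{owner!r} without depending on it",
                        )
                    )
        for wf in mod.workflows:
            reached = _reachable(wf)
            for node in wf.nodes:
                if node.id not in reached:
                    issues.append(
                        Issue(
                            "unreachable-node",
                            f"workflow {wf.name!r} node {node.id!r} is "
                            "unreachable from start",
                        )
                    )
    issues.sort(key=lambda i: (i.kind, i.detail))
    return issues


def _transitive_deps(name: str, modules: dict) -> set[str]:
    seen: set[str] = set()
    stack = list(modules[name].depends_on)
    while stack:
        dep = stack.pop()
        if dep in seen or dep not in modules:
            continue
        seen.add(dep)
        stack.extend(modules[dep].depends_on)
    return seen


def _reachable(workflow: Workflow) -> set[str]:
    try:
        start = workflow.start.id
    except ValueError:
        return set()
    seen = {start}
    stack = [start]
    while stack:
        node = stack.pop()
        for edge in workflow.outgoing(node):
            if edge.target not in seen:
                seen.add(edge.target)
                stack.append(edge.target)
    return seen
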