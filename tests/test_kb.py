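"""Module dialect parsing, three-valued conditions, registry validation."""

import pytest
from hypothesis import given, settings, strategies as st

from knowsub import UNKNOWN, Truth, evaluate_condition, parse_module, validate_registry
from knowsub.errors import EvaluationError, LinkError, ParseError, StructureError
from knowsub.kb import And, Compare, Known, Not, Or
from knowsub.parser import load_registry, parse_condition, serialize_condition, serialize_module

from conftest import oracle_condition

T, F, U = Truth.TRUE, Truth.FALSE, Truth.UNDEFINED

MINI_MODULE = """
MODULE Mini
QUESTIONS
x (numeric) "x value"
mode (one_choice: fast | slow) "mode"
DECISIONS
D "the decision"
RULES
r1: IF x < 60 OR mode = fast THEN D P7
"""


class TestParseModule:
    def test_persistence_fixture(self, registry):
        mod = registry.module("Persistence")
        assert {q.id for q in mod.questions} >= {"ThCO2", "ThOD", "DOC"}
        biodeg = next(r for r in mod.rules if r.target == "NotReadilyBiodegradable")
        assert isinstance(biodeg.condition, Or)
        assert len(biodeg.condition.children) == 3
        thco2 = next(q for q in mod.questions if q.id == "ThCO2")
        assert "pass level" in thco2.explanation

    def test_empty_text_is_empty_module(self):
        mod = parse_module("")
        assert mod.questions == [] and mod.rules == [] and mod.workflows == []

    def test_undeclared_question_is_link_error(self):
        text = MINI_MODULE.replace("x < 60", "y < 60")
        with pytest.raises(LinkError, match="'y'"):
            parse_module(text)

    def test_link_error_carries_line_number(self):
        text = MINI_MODULE.replace("x < 60", "y < 60")
        with pytest.raises(LinkError, match=r"line \d+"):
            parse_module(text)

    def test_duplicate_question_id_rejected(self):
        text = MINI_MODULE.replace('mode (one_choice: fast | slow) "mode"',
                                   'x (numeric) "again"')
        with pytest.raises(ParseError):
            parse_module(text)

    def test_flow_cycle_rejected(self):
        text = """
MODULE Loop
QUESTIONS
x (numeric) "x"
DECISIONS
D "d"
FLOW f
start s
ask a x
exit e
edge s -> a
edge a -> a IF x > 0
edge a -> e
"""
        with pytest.raises(StructureError, match="cycle"):
            parse_module(text)

    def test_question_hierarchy_from_indentation(self):
        text = """
MODULE H
QUESTIONS
parent (one_choice: yes | no) "p"
  child (numeric) "c"
"""
        mod = parse_module(text)
        assert mod.question("child").parent == "parent"


class TestRoundTrip:
    def test_bundled_modules_survive_serialize_parse(self, registry):
        known_q, known_d = set(), set()
        for mod in registry.dependency_order():
            text = serialize_module(mod)
            again = parse_module(text, known_questions=known_q, known_decisions=known_d)
            assert again == mod
            known_q |= mod.question_ids()
            known_d |= mod.decision_ids()

    def test_condition_round_trip(self):
        texts = [
            "ThCO2 < 60 OR ThOD < 60 OR DOC < 70",
            "NOT (a = 1 AND b = 2)",
            "KNOWN[q] AND x in {low, high}",
            "DECISION[P] = established AND DECISION[B] != excluded",
        ]
        for text in texts:
            cond = parse_condition(text)
            assert parse_condition(serialize_condition(cond)) == cond


class TestEvaluateCondition:
    def test_threshold_reached(self):
        assert evaluate_condition(Compare("ThCO2", "<", 60), {"ThCO2": 45}) is T

    def test_unanswered_is_undefined(self):
        assert evaluate_condition(Compare("ThCO2", "<", 60), {}) is U

    def test_unknown_answer_is_undefined(self):
        assert evaluate_condition(Compare("ThCO2", "<", 60), {"ThCO2": UNKNOWN}) is U

    @pytest.mark.parametrize(
        "cond, facts, expected",
        [
            (Or((Compare("a", "=", 1), Compare("b", "=", 1))), {"a": 1}, T),
            (And((Compare("a", "=", 1), Compare("b", "=", 1))), {"a": 1}, U),
            (And((Compare("a", "=", 2), Compare("b", "=", 1))), {"a": 1}, F),
            (Not(Compare("a", "=", 1)), {}, U),
            (Not(Compare("a", "=", 1)), {"a": 2}, T),
            (Known("a"), {"a": 5}, T),
            (Known("a"), {}, F),
        ],
    )
    def test_three_valued_lattice(self, cond, facts, expected):
        assert evaluate_condition(cond, facts) is expected

    def test_numeric_compare_on_text_raises(self):
        with pytest.raises(EvaluationError):
            evaluate_condition(Compare("a", "<", 60), {"a": "tall"})


# -- property tests: random knownness-free conditions ----------------------

questions = st.sampled_from(["q0", "q1", "q2", "q3"])
compares = st.builds(
    Compare,
    questions,
    st.sampled_from(["<", "<=", ">", ">=", "=", "!="]),
    st.integers(0, 10),
)
conditions = st.recursive(
    compares,
    lambda inner: st.one_of(
        st.builds(lambda cs: And(tuple(cs)), st.lists(inner, min_size=2, max_size=3)),
        st.builds(lambda cs: Or(tuple(cs)), st.lists(inner, min_size=2, max_size=3)),
        st.builds(Not, inner),
    ),
    max_leaves=12,
)
fact_sets = st.dictionaries(questions, st.integers(0, 10), max_size=4)


@settings(max_examples=300, derandomize=True)
@given(conditions, fact_sets)
def test_condition_agrees_with_independent_interpreter(cond, facts):
    """Engine evaluation matches the min/max truth-ordering oracle."""
    mapping = {0: F, 1: U, 2: T}
    assert evaluate_condition(cond, facts) is mapping[oracle_condition(cond, facts)]


@settings(max_examples=300, derandomize=True)
@given(conditions, fact_sets, fact_sets)
def test_condition_monotone_under_fact_extension(cond, base, extra):
    """Adding facts only resolves undefined, never flips true/false."""
    extended = {**extra, **base}  # base answers win; extra adds new ones
    before = evaluate_condition(cond, base)
    after = evaluate_condition(cond, extended)
    if before is not U:
        assert after is before


class TestValidateRegistry:
    def test_bundled_registry_is_clean(self, registry):
        assert validate_registry(registry) == []

    def test_duplicate_decision_id_across_modules(self):
        a = parse_module("MODULE A\nDECISIONS\nB \"b\"\n")
        b = parse_module("MODULE B\nDECISIONS\nB \"b again\"\n")
        issues = validate_registry({"A": a, "B": b})
        assert any(i.kind == "duplicate-id" for i in issues)

    def test_dangling_dependency(self):
        mod = parse_module("MODULE A\nDEPENDS: Exposure\n")
        issues = validate_registry({"A": mod})
        assert any(i.kind == "dangling-dependency" for i in issues)

    def test_unreachable_workflow_node(self):
        text = """
MODULE A
QUESTIONS
x (numeric) "x"
DECISIONS
D "d"
FLOW f
start s
ask orphan x
exit e
edge s -> e
edge orphan -> e
"""
        issues = validate_registry({"A": parse_module(text)})
        assert any(i.kind == "unreachable-node" for i in issues)

    def test_own_module_decision_reference_flagged(self):
        text = """
MODULE A
QUESTIONS
x (numeric) "x"
DECISIONS
D "d"
E "e"
RULES
r1: IF x > 1 THEN D P7
r2: IF DECISION[D] = established THEN E P7
"""
        issues = validate_registry({"A": parse_module(text)})
        assert any(i.kind == "self-reference" for i in issues)

    def test_registry_loading_shares_terminology(self):
        reg = load_registry(
            [
                "MODULE A\nQUESTIONS\nx (numeric) \"x\"\nDECISIONS\nDA \"da\"\nRULES\nr: IF x > 1 THEN DA P7\n",
                "MODULE B\nDEPENDS: A\nDECISIONS\nDB \"db\"\nRULES\nr2: IF DECISION[DA] = established AND x > 2 THEN DB P7\n",
            ]
        )
        assert validate_registry(reg) == []
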