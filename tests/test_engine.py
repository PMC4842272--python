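"""Inference: scoring, truth maintenance, explanations, traces, mirroring."""

import random

import pytest

from knowsub import (
    evaluate,
    explain,
    generate_random_registry,
    load_bundled_views,
    mirror_decisions,
    render_view,
    restrict_facts,
    retract,
    trace_workflow,
)
from knowsub.errors import NotFoundError
from knowsub.fixtures import random_facts
from knowsub.kb import State
from knowsub.parser import load_registry

from conftest import KRYPTONITE, oracle_decisions

TWO_RULE_MODULE = """
MODULE Two
QUESTIONS
x (numeric) "x"
DECISIONS
D "d"
RULES
pro: IF x > 0 THEN D P7
con: IF x > 0 THEN D N5
"""


class TestScoring:
    def test_p7_plus_n5_gives_60_established(self):
        registry = load_registry([TWO_RULE_MODULE])
        states = evaluate(registry, {"x": 1})
        assert states["D"].score == 80 - 20 == 60
        assert states["D"].state is State.established
        assert set(states["D"].support) == {"pro", "con"}

    @pytest.mark.parametrize(
        "category, expected_score",
        [("P1", 1), ("P3", 5), ("P5", 20), ("N2", -2), ("N7", -80)],
    )
    def test_category_magnitudes(self, category, expected_score):
        text = TWO_RULE_MODULE.replace("pro: IF x > 0 THEN D P7\ncon: IF x > 0 THEN D N5",
                                       f"only: IF x > 0 THEN D {category}")
        states = evaluate(load_registry([text]), {"x": 1})
        assert states["D"].score == expected_score

    @pytest.mark.parametrize(
        "score, state",
        [(42, State.established), (41, State.suggested), (10, State.suggested),
         (9, State.undefined), (-41, State.undefined), (-42, State.excluded)],
    )
    def test_state_thresholds(self, registry, score, state):
        assert registry.thresholds.state_of(score) is state

    def test_no_facts_leaves_everything_undefined(self, registry):
        states = evaluate(registry, {})
        assert all(s.state is State.undefined for s in states.values())


class TestKryptoniteDerivation:
    def test_pbt_established_from_sub_decisions(self, registry, answers):
        states = evaluate(registry, answers)
        for decision in ("P", "vP", "B", "vB", "T", "PBT", "vPvB"):
            assert states[decision].state is State.established, decision

    def test_without_toxicity_answers_pbt_stays_undefined(self, registry, answers):
        partial = {q: v for q, v in answers.items()
                   if q not in ("chronic_NOEC", "cmr_category")}
        states = evaluate(registry, partial)
        assert states["T"].state is State.undefined
        assert states["PBT"].state is State.undefined

    def test_order_invariance_over_fact_permutations(self, registry, facts):
        rng = random.Random(1)
        reference = evaluate(registry, facts)
        for _ in range(20):
            shuffled = facts[:]
            rng.shuffle(shuffled)
            assert evaluate(registry, shuffled) == reference

    def test_stateless_reevaluation_is_identical(self, registry, answers):
        assert evaluate(registry, answers) == evaluate(registry, answers)


class TestRetraction:
    def test_retract_bcf_leaves_b_undefined(self, registry, answers):
        assert evaluate(registry, answers)["B"].state is State.established
        reduced = retract(answers, "BCF")
        states = evaluate(registry, reduced)
        assert states["B"].state is State.undefined
        # the flow decide-nodes that depended on BCF no longer support anything
        supports = {sid for st in states.values() for sid in st.support}
        assert {"d_b", "d_vb", "d_notb"}.isdisjoint(supports)

    def test_retract_unreferenced_fact_changes_nothing(self, registry, answers):
        answers = {**answers, "unrelated": 1}
        before = evaluate(registry, {q: v for q, v in answers.items() if q != "unrelated"})
        assert evaluate(registry, retract(answers, "unrelated")) == before

    def test_retract_then_reassert_restores_original(self, registry, answers):
        original = evaluate(registry, answers)
        reduced = retract(answers, "BCF")
        restored = {**reduced, "BCF": answers["BCF"]}
        assert evaluate(registry, restored) == original

    def test_retracting_unanswered_question_warns(self, registry, answers):
        with pytest.warns(UserWarning):
            same = retract(answers, "never_asked")
        assert same == answers

    def test_retraction_equals_fresh_session(self, registry, answers):
        """Non-monotonic consistency: evaluate(facts - f) == fresh run without f."""
        reduced = retract(answers, "halflife_water")
        fresh = {q: v for q, v in answers.items() if q != "halflife_water"}
        assert evaluate(registry, reduced) == evaluate(registry, fresh)


class TestExplain:
    def test_pbt_explanation_is_transitive(self, registry, facts):
        exp = explain(registry, facts, "PBT")
        assert exp.state is State.established
        named = {q for q, _, _ in exp.responsible_facts}
        # facts behind P, B and T surface through the module dependencies
        assert {"halflife_water", "BCF", "chronic_NOEC"} <= named
        timestamps = [t for _, _, t in exp.responsible_facts]
        assert all(t is not None for t in timestamps)

    def test_undefined_decision_has_empty_explanation(self, registry):
        exp = explain(registry, {}, "PBT")
        assert exp.responsible_facts == () and exp.fired == ()

    def test_restricted_reevaluation_reproduces_state(self, registry, answers):
        exp = explain(registry, answers, "NotReadilyBiodegradable")
        restricted = restrict_facts(answers, exp)
        assert evaluate(registry, restricted)["NotReadilyBiodegradable"].state is exp.state

    def test_unknown_decision(self, registry):
        with pytest.raises(NotFoundError):
            explain(registry, {}, "Unobtainium")


class TestTraceWorkflow:
    def _flow(self, registry):
        return registry.module("Bioaccumulation").workflows[0]

    def test_high_bcf_routes_through_vb(self, registry):
        trace = trace_workflow(self._flow(registry), {"BCF_available": "yes", "BCF": 5300})
        assert "d_vb" in trace.visited_nodes and "d_b" in trace.visited_nodes
        assert trace.visited_nodes[-1] == "done"

    def test_low_bcf_ends_at_not_b(self, registry):
        trace = trace_workflow(self._flow(registry), {"BCF_available": "yes", "BCF": 100})
        assert "d_notb" in trace.visited_nodes
        assert "d_b" not in trace.visited_nodes

    def test_empty_facts_stop_before_any_decision(self, registry):
        trace = trace_workflow(self._flow(registry), {})
        assert trace.visited_nodes[0] == "s0"
        assert not any(n.startswith("d_") for n in trace.visited_nodes)

    def test_every_taken_edge_guard_was_true(self, registry):
        facts = {"BCF_available": "yes", "BCF": 2500}
        trace = trace_workflow(self._flow(registry), facts)
        flow = self._flow(registry)
        from knowsub.kb import TRUE, evaluate_condition

        for edge_id in trace.taken_edges:
            edge = next(e for e in flow.edges if e.id == edge_id)
            assert edge.guard is None or evaluate_condition(edge.guard, facts) is TRUE


class TestMirroring:
    def test_established_pbt_appears_in_screening_view(self, store, registry, answers):
        mirror_decisions(store, KRYPTONITE, evaluate(registry, answers))
        view = load_bundled_views()["pbt_screening"]
        assert [r[0] for r in render_view(store, view).rows] == ["Kryptonite"]

    def test_all_undefined_mirrors_nothing(self, store, registry):
        mirror_decisions(store, KRYPTONITE, evaluate(registry, {}))
        assert store.mirrored_decisions(KRYPTONITE) == {}

    def test_mirroring_twice_is_idempotent(self, store, registry, answers):
        states = evaluate(registry, answers)
        mirror_decisions(store, KRYPTONITE, states)
        size = len(store.graph)
        mirror_decisions(store, KRYPTONITE, states)
        assert len(store.graph) == size


class TestRuleEngineOracle:
    def test_agrees_with_brute_force_interpreter(self):
        for seed in range(5):
            registry = generate_random_registry(seed, n_rules=15)
            rng = random.Random(seed + 100)
            for _ in range(50):
                facts = random_facts(registry, rng)
                states = evaluate(registry, facts)
                expected = oracle_decisions(registry, facts)
                for decision, (state, score) in expected.items():
                    assert states[decision].score == score
                    assert states[decision].state.value == state

    def test_dependency_pass_is_a_fixpoint(self, registry, answers):
        """Re-running evaluation with the previous states folded in changes nothing."""
        first = evaluate(registry, answers)
        again = dict(first)
        for module in registry.dependency_order():
            from knowsub.engine import _evaluate_module, as_fact_map

            _evaluate_module(module, as_fact_map(answers), again, registry)
        assert again == first
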