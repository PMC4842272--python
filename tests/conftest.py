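import pytest

from knowsub import (
    bundled_registry,
    kryptonite_example,
    kryptonite_facts,
    kryptonite_store,
)

KRYPTONITE = "https://knowsub.dev/ks/Kryptonite"


@pytest.fixture()
def store():
    return kryptonite_store()


@pytest.fixture(scope="session")
def registry():
    return bundled_registry()


@pytest.fixture()
def answers():
    return kryptonite_example()[2]


@pytest.fixture()
def facts():
    return kryptonite_facts()


# -- independent oracles ---------------------------------------------------
# These re-implement condition evaluation and rule scoring with a different
# mechanism (numeric truth ordering F=0 < U=1 < T=2) so the engine can be
# cross-checked against them.


def oracle_condition(cond, facts, decisions=None):
    """Three-valued evaluation via min/max over the truth ordering."""
    from knowsub.kb import And, Compare, DecisionIs, Known, Not, Or, UNKNOWN

    F, U, T = 0, 1, 2
    if isinstance(cond, And):
        return min(oracle_condition(c, facts, decisions) for c in cond.children)
    if isinstance(cond, Or):
        return max(oracle_condition(c, facts, decisions) for c in cond.children)
    if isinstance(cond, Not):
        return 2 - oracle_condition(cond.child, facts, decisions)
    if isinstance(cond, Known):
        return T if cond.question in facts else F
    if isinstance(cond, DecisionIs):
        state = (decisions or {}).get(cond.decision)
        state = getattr(state, "state", state)
        if state is None or getattr(state, "value", state) == "undefined":
            return U
        return T if state is cond.state else F
    if isinstance(cond, Compare):
        if cond.question not in facts or facts[cond.question] is UNKNOWN:
            return U
        v, lit = facts[cond.question], cond.literal
        table = {
            "<": lambda: v < lit,
            "<=": lambda: v <= lit,
            ">": lambda: v > lit,
            ">=": lambda: v >= lit,
            "=": lambda: v == lit,
            "!=": lambda: v != lit,
            "in": lambda: v in (lit if isinstance(lit, tuple) else (lit,)),
        }
        return T if table[cond.op]() else F
    raise AssertionError(cond)


def oracle_decisions(registry, facts):
    """Brute-force rule interpreter: enumerate rules, sum fired categories."""
    magnitudes = {"1": 1, "2": 2, "3": 5, "4": 10, "5": 20, "6": 40, "7": 80}
    out = {}
    for module in registry.modules.values():
        scores = {}
        for rule in module.rules:
            if oracle_condition(rule.condition, facts) == 2:
                cat = rule.score_category.value
                delta = magnitudes[cat[1]] * (1 if cat[0] == "P" else -1)
                scores[rule.target] = scores.get(rule.target, 0) + delta
        for target, score in scores.items():
            if score <= -42:
                state = "excluded"
            elif score >= 42:
                state = "established"
            elif score >= 10:
                state = "suggested"
            else:
                state = "undefined"
            out[target] = (state, score)
    return out
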