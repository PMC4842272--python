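"""Deterministic generators and the bundled worked example.

Everything here is a pure function of its spec: the same seed always
yields byte-identical output, so property-based tests and the worked
example run without any external data.  Generated identifiers are drawn
from the all-nines / 9xx high ranges and carry a SYNTHETIC marker so they
cannot be mistaken for real registry entries.
"""

from __future__ import annotations

import csv
import random
from dataclasses import dataclass
from datetime import datetime, timedelta, timezone
from importlib import resources

from .engine import Fact, Source
from .errors import ValidationError
from .identifiers import cas_check_digit, ec_check_digit
from .kb import (
    And,
    Compare,
    DecisionModule,
    DecisionNode,
    Not,
    Or,
    Question,
    ScoreCategory,
    ScoringRule,
    ValueType,
)
from .parser import Registry, load_registry
from .provenance import FactHistory
from .store import SubstanceRecord, SubstanceStore


@dataclass(frozen=True)
class FixtureSpec:
    n_substances: int = 20
    invalid_id_rate: float = 0.0
    n_facts_per_substance: int = 4
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.invalid_id_rate <= 1.0:
            raise ValidationError("invalid_id_rate must lie in [0, 1]")
        if self.n_substances < 0:
            raise ValidationError("n_substances must be >= 0")


def _synthetic_cas(rng: random.Random, valid: bool, used: set[str]) -> str:
    while True:
        body = f"{rng.randint(9000000, 9999999)}{rng.randint(0, 99):02d}"
        if body in used:
            continue  # identifiers are unique unless duplicates are injected
        used.add(body)
        check = cas_check_digit(body)
        if not valid:
            check = (check + 1) % 10
        return f"{body[:7]}-{body[7:]}-{check}"


def _synthetic_ec(rng: random.Random, valid: bool, used: set[str]) -> str:
    while True:
        body = f"9{rng.randint(0, 99):02d}{rng.randint(0, 999):03d}"
        check = ec_check_digit(body)
        if check is None or body in used:
            continue  # remainder-10 bodies have no valid check digit
        used.add(body)
        if not valid:
            check = (check + 1) % 10
            if check == ec_check_digit(body):
                check = (check + 1) % 10
        return f"{body[:3]}-{body[3:]}-{check}"


def generate_substances(
    spec: FixtureSpec, csv_path=None
) -> list[SubstanceRecord]:
    """Generate synthetic substance records with unique labels.

    Exactly ``round(n * invalid_id_rate)`` records carry a checksum-failing
    CAS number (their EC numbers stay valid), so the identifier quality
    dashboard flags precisely that many findings.  Optionally also writes
    the records as an import-ready CSV with a SYNTHETIC comment column.
    """
    rng = random.Random(spec.seed)
    n_invalid = round(spec.n_substances * spec.invalid_id_rate)
    invalid_rows = set(rng.sample(range(spec.n_substances), n_invalid))
    used_cas: set[str] = set()
    used_ec: set[str] = set()
    records = []
    for i in range(spec.n_substances):
        records.append(
            SubstanceRecord(
                label=f"SYN-{spec.seed:03d}-{i:04d}",
                cas_number=_synthetic_cas(rng, i not in invalid_rows, used_cas),
                ec_number=_synthetic_ec(rng, True, used_ec),
                internal_names=[f"synthetic compound {i}"],
            )
        )
    if csv_path is not None:
        with open(csv_path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["label", "ec", "cas", "iupac", "smiles", "internal_names", "comment"])
            for rec in records:
                writer.writerow(
                    [
                        rec.label,
                        rec.ec_number,
                        rec.cas_number,
                        "",
                        "",
                        ";".join(rec.internal_names),
                        "SYNTHETIC",
                    ]
                )
    return records


def bundled_registry() -> Registry:
    """The four example modules (Persistence, Bioaccumulation, Toxicity, PBT)."""
    root = resources.files("knowsub.data")
    import yaml

    manifest = yaml.safe_load(root.joinpath("registry.yaml").read_text("utf-8"))
    texts = [root.joinpath(name).read_text("utf-8") for name in manifest["modules"]]
    return load_registry(texts)


#: Answer script that drives Kryptonite's PBT assessment to "established".
KRYPTONITE_ANSWERS: dict[str, object] = {
    "ThCO2": 45,
    "ThOD": 40,
    "DOC": 50,
    "halflife_water": 70,
    "BCF_available": "yes",
    "BCF": 5300,
    "chronic_NOEC": 0.005,
    "cmr_category": "none",
}


def kryptonite_store() -> SubstanceStore:
    """A store holding the bundled Kryptonite ontology."""
    with resources.as_file(
        resources.files("knowsub.data").joinpath("kryptonite.ttl")
    ) as path:
        return SubstanceStore.load_turtle(path)


def kryptonite_example() -> tuple[SubstanceStore, Registry, dict[str, object]]:
    """The full worked example: store, module registry and answer script."""
    return kryptonite_store(), bundled_registry(), dict(KRYPTONITE_ANSWERS)


def kryptonite_facts(
    start: datetime | None = None, answers: dict | None = None
) -> list[Fact]:
    """The answer script as timestamped facts (one hour apart)."""
    start = start or datetime(2015, 6, 1, 9, 0, tzinfo=timezone.utc)
    answers = KRYPTONITE_ANSWERS if answers is None else answers
    facts = []
    for i, (question, value) in enumerate(answers.items()):
        facts.append(
            Fact(
                substance="https://knowsub.dev/ks/Kryptonite",
                question=question,
                value=value,
                timestamp=start + timedelta(hours=i),
                author="assessor",
                source=Source.user,
                seq=i,
            )
        )
    return facts


# -- random registries for oracle-equivalence testing ---------------------


def generate_random_registry(seed: int, n_rules: int = 10) -> Registry:
    """A random single-module registry for property-based tests.

    Conditions are built from comparison atoms over numeric and one-choice
    questions combined with AND/OR/NOT (depth <= 3, no knownness atoms so
    rule firing is monotone in the facts).  Validates cleanly.
    """
    if n_rules > 50:
        raise ValidationError("n_rules must be <= 50")
    rng = random.Random(seed)
    n_questions = max(3, min(8, 2 + n_rules // 2))
    questions = []
    for i in range(n_questions):
        if rng.random() < 0.7:
            questions.append(
                Question(id=f"q{i}", prompt=f"numeric input {i}", value_type=ValueType.numeric)
            )
        else:
            questions.append(
                Question(
                    id=f"q{i}",
                    prompt=f"choice input {i}",
                    value_type=ValueType.one_choice,
                    choices=("low", "mid", "high"),
                )
            )
    n_decisions = max(1, n_rules // 3 + 1)
    decisions = [
        DecisionNode(id=f"d{i}", label=f"decision {i}", module="Random")
        for i in range(n_decisions)
    ]
    rules = [
        ScoringRule(
            id=f"r{i}",
            condition=_random_condition(rng, questions, depth=0),
            target=rng.choice(decisions).id,
            score_category=rng.choice(list(ScoreCategory)),
        )
        for i in range(n_rules)
    ]
    module = DecisionModule(
        name="Random",
        questions=questions,
        decisions=decisions,
        rules=rules,
        init_questions=[q.id for q in questions],
    )
    return Registry(modules={module.name: module})


def _random_condition(rng: random.Random, questions, depth: int):
    if depth >= 3 or rng.random() < 0.45:
        q = rng.choice(questions)
        if q.value_type is ValueType.numeric:
            op = rng.choice(["<", "<=", ">", ">=", "=", "!="])
            return Compare(q.id, op, rng.randint(0, 10))
        op = rng.choice(["=", "!=", "in"])
        if op == "in":
            k = rng.randint(1, 2)
            return Compare(q.id, "in", tuple(rng.sample(q.choices, k)))
        return Compare(q.id, op, rng.choice(q.choices))
    kind = rng.random()
    if kind < 0.4:
        children = tuple(
            _random_condition(rng, questions, depth + 1)
            for _ in range(rng.randint(2, 3))
        )
        return And(children)
    if kind < 0.8:
        children = tuple(
            _random_condition(rng, questions, depth + 1)
            for _ in range(rng.randint(2, 3))
        )
        return Or(children)
    return Not(_random_condition(rng, questions, depth + 1))


def random_facts(registry: Registry, rng: random.Random, answer_rate: float = 0.7):
    """A random partial answer set over a registry's questions."""
    facts = {}
    for qid, q in registry.all_questions().items():
        if rng.random() > answer_rate:
            continue
        if q.value_type is ValueType.numeric:
            facts[qid] = rng.randint(0, 10)
        elif q.value_type is ValueType.one_choice:
            facts[qid] = rng.choice(q.choices)
        else:
            facts[qid] = f"text-{rng.randint(0, 5)}"
    return facts


def generate_fact_log(
    registry: Registry, spec: FixtureSpec, substance: str = "urn:synthetic:s1"
) -> FactHistory:
    """A deterministic fact history with revisions, for time-machine tests."""
    rng = random.Random(spec.seed)
    history = FactHistory()
    start = datetime(2015, 1, 1, tzinfo=timezone.utc)
    questions = list(registry.all_questions().values())
    for i in range(spec.n_facts_per_substance):
        q = rng.choice(questions)
        if q.value_type is ValueType.numeric:
            value: object = rng.randint(0, 10)
        elif q.value_type is ValueType.one_choice:
            value = rng.choice(q.choices)
        else:
            value = f"note-{i}"
        history.record_fact(
            Fact(
                substance=substance,
                question=q.id,
                value=value,
                timestamp=start + timedelta(days=i),
                author="generator",
                source=Source.import_,
            )
        )
    return history
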