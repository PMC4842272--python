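"""RDF graph model for substances, chemical properties, decisions and memos.

The store is a thin, opinionated layer over an :class:`rdflib.Graph`.  All
terms live in a single configurable namespace (default prefix ``ks:``):
substances are instances of ``ks:Substance`` with one datatype property per
known identifier (EC number, CAS number, IUPAC name, SMILES, internal
names, label), chemical properties are instances of ``ks:ChemProperty``
linked via ``ks:hasChemProperty``, and derived decisions are mirrored as
``ks:hasDecision`` triples so that dynamic SPARQL views can reach them.

Class membership (e.g. "PBT substance" = has the persistent,
bioaccumulative and toxic property) is computed by scanning/querying the
intersection-of-property-values pattern rather than by a full OWL reasoner:
the screening use case exercises only this pattern and a scan is
deterministic and cheap at desk scale.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field

from rdflib import Graph, Literal, Namespace, RDF, RDFS, URIRef
from rdflib.plugins.sparql import prepareQuery

from .errors import (
    ConflictError,
    NotFoundError,
    ParseError,
    QuerySyntaxError,
    ValidationError,
)

#: Default namespace for all minted terms (prefix ``ks:`` in serializations).
DEFAULT_NAMESPACE = "https://knowsub.dev/ks/"

#: Labels of the chemical-property terms bundled with every fresh store.
BUNDLED_PROPERTIES = ("persistent", "bioaccumulative", "toxic")

_IDENTIFIER_PREDICATES = {
    "ec_number": "hasEcNumber",
    "cas_number": "hasCasNumber",
    "iupac_name": "hasIupacName",
    "smiles": "hasSmiles",
}


def slugify(text: str) -> str:
    """Turn an arbitrary label into a URI-safe slug (``Kryptonite`` stays)."""
    text = unicodedata.normalize("NFKD", text).encode("ascii", "ignore").decode()
    text = re.sub(r"[^A-Za-z0-9]+", "_", text).strip("_")
    return text or "substance"


@dataclass
class SubstanceRecord:
    """A chemical substance with its known identifier set.

    At least one identifier field must be non-empty; ``uri`` is minted from
    the label when not given explicitly.
    """

    label: str = ""
    ec_number: str | None = None
    cas_number: str | None = None
    iupac_name: str | None = None
    smiles: str | None = None
    internal_names: list[str] = field(default_factory=list)
    memo_text: str | None = None
    uri: str | None = None

    def is_empty(self) -> bool:
        return not (
            self.label
            or self.ec_number
            or self.cas_number
            or self.iupac_name
            or self.smiles
            or self.internal_names
        )


@dataclass(frozen=True)
class ChemPropertyTerm:
    """A chemical hazard property term (e.g. ``persistent``)."""

    uri: str
    label: str


@dataclass(frozen=True)
class ClassDefinition:
    """A substance class defined as an intersection of required property values.

    ``required_property_values`` holds (predicate local name, object label)
    pairs, e.g. ``("hasChemProperty", "persistent")``.  A substance is a
    member iff every pair is asserted for it; an empty set admits all
    substances.
    """

    name: str
    required_property_values: frozenset[tuple[str, str]] = frozenset()


#: The PBT class of the worked example: persistent AND bioaccumulative AND toxic.
PBT_CLASS = ClassDefinition(
    "PBTSubstance",
    frozenset(("hasChemProperty", p) for p in BUNDLED_PROPERTIES),
)


@dataclass
class ResultTable:
    """Carrier for SPARQL solutions and dynamic views.

    Rows are deterministically ordered (lexicographically over the stringified
    cells) so repeated renders of an unchanged store are byte-identical.
    """

    columns: list[str]
    rows: list[tuple]

    def __post_init__(self):
        for row in self.rows:
            if len(row) != len(self.columns):
                raise ValidationError(
                    f"row {row!r} has {len(row)} cells, expected {len(self.columns)}"
                )

    def sort(self) -> "ResultTable":
        self.rows.sort(key=lambda r: tuple((c is None, str(c)) for c in r))
        return self


def _cell(value) -> object:
    """Convert an rdflib term to a plain Python value for a ResultTable."""
    if value is None:
        return None
    if isinstance(value, Literal):
        py = value.toPython()
        return py if not isinstance(py, bytes) else str(value)
    return str(value)


class SubstanceStore:
    """A substance ontology held in an in-memory triple store."""

    def __init__(self, namespace: str = DEFAULT_NAMESPACE, graph: Graph | None = None):
        self.ns = Namespace(namespace)
        self.graph = graph if graph is not None else Graph()
        self.graph.bind("ks", self.ns)
        self._seed_vocabulary()

    # -- vocabulary -------------------------------------------------------

    def _seed_vocabulary(self) -> None:
        g = self.graph
        g.add((self.ns.Substance, RDF.type, RDFS.Class))
        g.add((self.ns.ChemProperty, RDF.type, RDFS.Class))
        for label in BUNDLED_PROPERTIES:
            term = self.ns[label]
            g.add((term, RDF.type, self.ns.ChemProperty))
            g.add((term, self.ns.hasLabel, Literal(label)))

    def add_property_term(self, label: str) -> str:
        """Register a chemical-property term; idempotent per label."""
        existing = self._property_uri(label)
        if existing is not None:
            return str(existing)
        term = self.ns[slugify(label)]
        self.graph.add((term, RDF.type, self.ns.ChemProperty))
        self.graph.add((term, self.ns.hasLabel, Literal(label)))
        return str(term)

    def property_terms(self) -> list[ChemPropertyTerm]:
        out = []
        for term in self.graph.subjects(RDF.type, self.ns.ChemProperty):
            label = self.graph.value(term, self.ns.hasLabel)
            out.append(ChemPropertyTerm(str(term), str(label) if label else ""))
        return sorted(out, key=lambda t: t.label)

    def _property_uri(self, label: str) -> URIRef | None:
        for term in self.graph.subjects(self.ns.hasLabel, Literal(label)):
            if (term, RDF.type, self.ns.ChemProperty) in self.graph:
                return term
        return None

    # -- substances -------------------------------------------------------

    def substance_uri(self, label_or_uri: str) -> URIRef:
        """Resolve a label or full URI to the substance resource."""
        if label_or_uri.startswith(("http://", "https://", "urn:")):
            uri = URIRef(label_or_uri)
            if (uri, RDF.type, self.ns.Substance) in self.graph:
                return uri
            raise NotFoundError(f"no substance with uri {label_or_uri!r}")
        for s in self.graph.subjects(self.ns.hasLabel, Literal(label_or_uri)):
            if (s, RDF.type, self.ns.Substance) in self.graph:
                return s
        uri = self.ns[slugify(label_or_uri)]
        if (uri, RDF.type, self.ns.Substance) in self.graph:
            return uri
        raise NotFoundError(f"no substance labelled {label_or_uri!r}")

    def add_substance(self, record: SubstanceRecord) -> str:
        """Add a substance; one triple per non-empty identifier field.

        Raises :class:`ConflictError` on a duplicate URI and
        :class:`ValidationError` on an all-empty record.
        """
        if record.is_empty():
            raise ValidationError("substance record has no identifier at all")
        uri = URIRef(record.uri) if record.uri else self.ns[slugify(record.label)]
        if (uri, RDF.type, self.ns.Substance) in self.graph:
            raise ConflictError(f"substance {uri} already exists")
        g = self.graph
        g.add((uri, RDF.type, self.ns.Substance))
        if record.label:
            g.add((uri, self.ns.hasLabel, Literal(record.label)))
        for attr, pred in _IDENTIFIER_PREDICATES.items():
            value = getattr(record, attr)
            if value:
                g.add((uri, self.ns[pred], Literal(value)))
        for name in record.internal_names:
            g.add((uri, self.ns.hasInternalName, Literal(name)))
        if record.memo_text:
            g.add((uri, self.ns.hasMemoText, Literal(record.memo_text)))
        return str(uri)

    def get_substance(self, uri: str) -> SubstanceRecord:
        ref = self.substance_uri(uri)
        g = self.graph

        def one(pred):
            v = g.value(ref, self.ns[pred])
            return str(v) if v is not None else None

        return SubstanceRecord(
            uri=str(ref),
            label=one("hasLabel") or "",
            ec_number=one("hasEcNumber"),
            cas_number=one("hasCasNumber"),
            iupac_name=one("hasIupacName"),
            smiles=one("hasSmiles"),
            internal_names=sorted(
                str(v) for v in g.objects(ref, self.ns.hasInternalName)
            ),
            memo_text=one("hasMemoText"),
        )

    def substances(self) -> list[str]:
        """All substance URIs, sorted."""
        return sorted(
            str(s) for s in self.graph.subjects(RDF.type, self.ns.Substance)
        )

    def assert_property(self, substance: str, property_label: str) -> None:
        """Assert ``hasChemProperty`` between a substance and a term; idempotent."""
        subject = self.substance_uri(substance)
        term = self._property_uri(property_label)
        if term is None:
            raise NotFoundError(f"no chemical property labelled {property_label!r}")
        self.graph.add((subject, self.ns.hasChemProperty, term))

    def properties_of(self, substance: str) -> set[str]:
        subject = self.substance_uri(substance)
        out = set()
        for term in self.graph.objects(subject, self.ns.hasChemProperty):
            label = self.graph.value(term, self.ns.hasLabel)
            out.add(str(label) if label else str(term))
        return out

    # -- querying ---------------------------------------------------------

    def query(self, sparql_text: str) -> ResultTable:
        """Execute a SPARQL SELECT or ASK query; rows deterministically ordered.

        The store's ``ks:`` prefix is available without an explicit PREFIX
        declaration.
        """
        try:
            prepared = prepareQuery(sparql_text, initNs={"ks": self.ns})
        except Exception as exc:  # rdflib raises pyparsing exceptions
            raise QuerySyntaxError(f"SPARQL parse error: {exc}") from exc
        result = self.graph.query(prepared)
        if result.type == "ASK":
            return ResultTable(columns=["ask"], rows=[(bool(result.askAnswer),)])
        columns = [str(v) for v in result.vars]
        rows = [tuple(_cell(row[v]) for v in result.vars) for row in result]
        return ResultTable(columns=columns, rows=rows).sort()

    def members_of(self, classdef: ClassDefinition) -> set[str]:
        """Substances satisfying every required (property, value) pair.

        Equals the result set of :meth:`class_query` by construction; the
        scan is kept independent of the SPARQL path so the two can be
        cross-checked.
        """
        members = set()
        for uri in self.substances():
            subject = URIRef(uri)
            ok = True
            for pred, value in classdef.required_property_values:
                objects = set(self.graph.objects(subject, self.ns[pred]))
                term = self._property_uri(value)
                hit = (term is not None and term in objects) or Literal(
                    value
                ) in objects
                if not hit:
                    ok = False
                    break
            if ok:
                members.add(uri)
        return members

    def class_query(self, classdef: ClassDefinition) -> str:
        """Mechanically generate the SPARQL SELECT equivalent of a class."""
        patterns = ["?s a ks:Substance ."]
        for pred, value in sorted(classdef.required_property_values):
            term = self._property_uri(value)
            obj = f"<{term}>" if term is not None else f'"{value}"'
            patterns.append(f"?s ks:{pred} {obj} .")
        body = "\n  ".join(patterns)
        return f"SELECT ?s WHERE {{\n  {body}\n}}"

    # -- decision mirror ---------------------------------------------------

    def mirror_decisions(self, substance: str, states: dict) -> None:
        """Mirror derived decision states into the graph.

        For each decision whose state is not ``undefined`` a resource
        ``<substance>--decision--<id>`` is (re)created carrying
        ``ks:aboutDecision`` and ``ks:hasState``.  Previously mirrored states
        for the substance are replaced, never duplicated.
        """
        subject = self.substance_uri(substance)
        g = self.graph
        for node in list(g.objects(subject, self.ns.hasDecision)):
            g.remove((node, None, None))
            g.remove((subject, self.ns.hasDecision, node))
        for decision_id, state in sorted(states.items()):
            state_name = getattr(state, "state", state)
            state_name = getattr(state_name, "value", state_name)
            if state_name == "undefined":
                continue
            node = URIRef(f"{subject}--decision--{slugify(decision_id)}")
            g.add((subject, self.ns.hasDecision, node))
            g.add((node, self.ns.aboutDecision, self.ns[slugify(decision_id)]))
            g.add((node, self.ns.hasState, Literal(str(state_name))))

    def mirrored_decisions(self, substance: str) -> dict[str, str]:
        subject = self.substance_uri(substance)
        out = {}
        for node in self.graph.objects(subject, self.ns.hasDecision):
            about = self.graph.value(node, self.ns.aboutDecision)
            state = self.graph.value(node, self.ns.hasState)
            if about is not None and state is not None:
                out[str(about).rsplit("/", 1)[-1]] = str(state)
        return out

    # -- IO ----------------------------------------------------------------

    def save_turtle(self, path) -> None:
        self.graph.serialize(destination=str(path), format="turtle")

    @classmethod
    def load_turtle(cls, path, namespace: str = DEFAULT_NAMESPACE) -> "SubstanceStore":
        graph = Graph()
        try:
            graph.parse(str(path), format="turtle")
        except Exception as exc:
            line = getattr(exc, "lines", None)
            raise ParseError(f"malformed Turtle in {path}: {exc}", line=line) from exc
        return cls(namespace=namespace, graph=graph)
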