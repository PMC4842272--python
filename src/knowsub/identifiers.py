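"""Substance identifier validation and quality dashboard.

CAS registry numbers carry a mod-10 check digit: with the digits of the
body numbered 1, 2, 3, ... from the rightmost non-check digit leftward, the
check digit is the weighted sum ``Σ digit_i * i (mod 10)``.  EC inventory
numbers carry a mod-11 check digit over the six body digits weighted 1..6
left to right; a remainder of 10 has no valid check digit, so such bodies
cannot occur in the inventory.  SMILES strings are checked syntactically
only (token alphabet, balanced brackets, paired ring-closure digits) —
within this system SMILES is an identifier, not a structure to interpret.

The quality dashboard scans a substance store for three kinds of findings:
checksum-invalid identifiers, identifier values shared by several
substances (duplicate registrations), and substances carrying several
distinct values for a scheme that should be single-valued
(contraindicative identifier sets).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import datetime, timezone
from enum import Enum

from .store import SubstanceStore

CAS_RE = re.compile(r"^(\d{2,7})-(\d{2})-(\d)$")
EC_RE = re.compile(r"^(\d{3})-(\d{3})-(\d)$")

_SMILES_TOKEN = re.compile(
    r"Cl|Br|\[[^\]]+\]|[BCNOPSFIbcnops]|[0-9]|%\d\d|[=#$:/\\+\-()@.]"
)


class Scheme(str, Enum):
    CAS = "CAS"
    EC = "EC"
    IUPAC = "IUPAC"
    SMILES = "SMILES"


@dataclass(frozen=True)
class ValidationResult:
    identifier: str
    scheme: Scheme
    well_formed: bool
    checksum_ok: bool
    message: str = ""

    def __post_init__(self):
        if self.checksum_ok and not self.well_formed:
            raise ValueError("checksum_ok requires well_formed")


def cas_check_digit(body: str) -> int:
    """Check digit for a CAS body given as digits without hyphens."""
    digits = [int(c) for c in body]
    return sum(i * d for i, d in enumerate(reversed(digits), start=1)) % 10


def validate_cas(text: str) -> ValidationResult:
    """Validate a CAS registry number (format ``2-7 digits - 2 digits - 1``)."""
    m = CAS_RE.match(text.strip())
    if not m:
        return ValidationResult(text, Scheme.CAS, False, False, "not in CAS format")
    body = m.group(1) + m.group(2)
    expected = cas_check_digit(body)
    ok = int(m.group(3)) == expected
    msg = "" if ok else f"check digit should be {expected}"
    return ValidationResult(text, Scheme.CAS, True, ok, msg)


def ec_check_digit(body: str) -> int | None:
    """Check digit for an EC body (6 digits), or None when remainder is 10."""
    total = sum(i * int(d) for i, d in enumerate(body, start=1))
    rem = total % 11
    return None if rem == 10 else rem


def validate_ec(text: str) -> ValidationResult:
    """Validate an EC inventory number (format ``3 digits - 3 digits - 1``)."""
    m = EC_RE.match(text.strip())
    if not m:
        return ValidationResult(text, Scheme.EC, False, False, "not in EC format")
    expected = ec_check_digit(m.group(1) + m.group(2))
    if expected is None:
        return ValidationResult(
            text, Scheme.EC, True, False, "body has no valid check digit (mod 11 = 10)"
        )
    ok = int(m.group(3)) == expected
    msg = "" if ok else f"check digit should be {expected}"
    return ValidationResult(text, Scheme.EC, True, ok, msg)


def validate_smiles(text: str) -> ValidationResult:
    """Syntactic SMILES check: legal tokens, balanced (), paired ring digits."""
    text = text.strip()
    if not text:
        return ValidationResult(text, Scheme.SMILES, False, False, "empty")
    pos, depth, rings = 0, 0, {}
    while pos < len(text):
        m = _SMILES_TOKEN.match(text, pos)
        if not m:
            return ValidationResult(
                text, Scheme.SMILES, False, False, f"illegal token at position {pos}"
            )
        tok = m.group(0)
        if tok == "(":
            depth += 1
        elif tok == ")":
            depth -= 1
            if depth < 0:
                return ValidationResult(
                    text, Scheme.SMILES, False, False, "unbalanced parentheses"
                )
        elif tok.isdigit() or tok.startswith("%"):
            rings[tok] = not rings.get(tok, False)
        pos = m.end()
    if depth != 0:
        return ValidationResult(text, Scheme.SMILES, False, False, "unbalanced parentheses")
    if any(rings.values()):
        return ValidationResult(text, Scheme.SMILES, False, False, "unclosed ring bond")
    # no checksum exists for SMILES; well-formedness is the whole check
    return ValidationResult(text, Scheme.SMILES, True, True, "")


class FindingKind(str, Enum):
    bad_checksum = "bad_checksum"
    duplicate_identifier = "duplicate_identifier"
    contraindicative_identifiers = "contraindicative_identifiers"


@dataclass(frozen=True)
class QualityFinding:
    kind: FindingKind
    substances: tuple[str, ...]
    detail: str

    def __post_init__(self):
        n = len(self.substances)
        if self.kind is FindingKind.duplicate_identifier and n < 2:
            raise ValueError("duplicate finding needs >= 2 substances")
        if self.kind is not FindingKind.duplicate_identifier and n != 1:
            raise ValueError(f"{self.kind.value} finding references exactly 1 substance")


@dataclass
class QualityReport:
    findings: list[QualityFinding] = field(default_factory=list)
    generated_at: datetime = field(
        default_factory=lambda: datetime.now(timezone.utc)
    )

    def of_kind(self, kind: FindingKind) -> list[QualityFinding]:
        return [f for f in self.findings if f.kind is kind]


# duplicate and contraindication detection run as SPARQL against the store;
# checksum logic stays in code (no arithmetic in the query layer)
_IDENTIFIER_QUERY = """
SELECT ?s ?value WHERE {{ ?s a ks:Substance ; ks:{pred} ?value . }}
"""

_SINGLE_VALUED = {
    Scheme.CAS: "hasCasNumber",
    Scheme.EC: "hasEcNumber",
    Scheme.IUPAC: "hasIupacName",
    Scheme.SMILES: "hasSmiles",
}

_CHECKED = {
    Scheme.CAS: validate_cas,
    Scheme.EC: validate_ec,
}


def run_quality_checks(store: SubstanceStore) -> QualityReport:
    """Assemble the quality dashboard report for a substance store."""
    findings: list[QualityFinding] = []
    per_scheme: dict[Scheme, list[tuple[str, str]]] = {}
    for scheme, pred in _SINGLE_VALUED.items():
        table = store.query(_IDENTIFIER_QUERY.format(pred=pred))
        per_scheme[scheme] = [(str(s), str(v)) for s, v in table.rows]

    for scheme, validator in _CHECKED.items():
        for uri, value in per_scheme[scheme]:
            result = validator(value)
            if not result.checksum_ok:
                findings.append(
                    QualityFinding(
                        FindingKind.bad_checksum,
                        (uri,),
                        f"{scheme.value} {value!r}: {result.message}",
                    )
                )

    for scheme, pairs in per_scheme.items():
        by_value: dict[str, set[str]] = {}
        for uri, value in pairs:
            by_value.setdefault(value, set()).add(uri)
        for value, uris in sorted(by_value.items()):
            if len(uris) >= 2:
                findings.append(
                    QualityFinding(
                        FindingKind.duplicate_identifier,
                        tuple(sorted(uris)),
                        f"{scheme.value} {value!r} shared by {len(uris)} substances",
                    )
                )
        by_substance: dict[str, set[str]] = {}
        for uri, value in pairs:
            by_substance.setdefault(uri, set()).add(value)
        for uri, values in sorted(by_substance.items()):
            if len(values) >= 2:
                findings.append(
                    QualityFinding(
                        FindingKind.contraindicative_identifiers,
                        (uri,),
                        f"{len(values)} distinct {scheme.value} values: "
                        + ", ".join(sorted(values)),
                    )
                )

    findings.sort(key=lambda f: (f.kind.value, f.substances[0], f.detail))
    return QualityReport(findings=findings)
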