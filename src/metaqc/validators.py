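"""Per-attribute value validation: is each value well-specified under its spec?

Five attribute groups carry machine-checkable contracts:

boolean
    The value is ``true`` or ``false`` regardless of capitalization.
    Near-misses like ``yes``, ``Y``, ``0`` or ``never smoker`` are invalid.
integer
    The value parses as a plain decimal integer: optional sign, ASCII
    digits only.  Floats, thousands separators and free text are invalid.
timestamp
    The value matches one of ``D-Mmm-YYYY``, ``Mmm-YYYY``, ``YYYY`` (e.g.
    ``20-Nov-2000``, ``Nov-2000``, ``2000``) or the ISO 8601 forms
    ``YYYY-mm-dd``, ``YYYY-mm``, ``YYYY-mm-ddThh:mm:ss``.  Matching is at
    the pattern level: month abbreviations are case-insensitive, day 31 is
    accepted for every month (no calendar check) and no timezone
    designators are accepted.
value set
    The trimmed value equals a member of the attribute's closed value set,
    ignoring letter case; interior characters must match exactly, so
    ``mal e`` is not ``male``.
ontology term
    The trimmed value exact-matches a term in the designated ontology
    (preferred name, synonym, or term identifier; case-insensitive),
    through a pluggable :class:`TermResolver`.

Attributes with no spec, or whose spec carries no value contract, get the
``untested`` status: the pipeline reports on what it cannot check rather
than guessing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Protocol

from .attribute_specs import ANY_ONTOLOGY, AttributeSpec, SpecRegistry, ValueClass
from .records_io import Attribute, SampleRecord

__all__ = [
    "Status",
    "ValidationResult",
    "TermResolver",
    "LocalTermIndex",
    "validate_boolean",
    "validate_integer",
    "validate_timestamp",
    "validate_value_set",
    "resolve_and_validate_term",
    "validate_attribute",
    "validate_record",
    "validate_corpus",
    "bundled_term_index",
]


class Status(str, Enum):
    WELL_SPECIFIED = "well_specified"
    INVALID = "invalid"
    UNTESTED = "untested"


#: Reason codes attached to non-well-specified verdicts.
REASONS = {
    "not_boolean",
    "not_integer",
    "bad_date_format",
    "not_in_value_set",
    "no_ontology_match",
    "no_spec",
    "unchecked_class",
    "resolver_error",
}


@dataclass(frozen=True)
class ValidationResult:
    """Verdict for one attribute occurrence on one record."""

    accession: str
    attribute_name: str
    value: str
    value_class: ValueClass | None
    status: Status
    reason: str | None = None


# ---------------------------------------------------------------------------
# Class validators
# ---------------------------------------------------------------------------

def validate_boolean(value: str) -> Status:
    """``true``/``false`` in any capitalization; everything else is invalid."""
    return Status.WELL_SPECIFIED if value.strip().lower() in ("true", "false") else Status.INVALID


_INTEGER_RE = re.compile(r"[+-]?[0-9]+", re.ASCII)


def validate_integer(value: str) -> Status:
    """Optional sign followed by ASCII decimal digits only."""
    return Status.WELL_SPECIFIED if _INTEGER_RE.fullmatch(value.strip()) else Status.INVALID


_MMM = r"(?:Jan|Feb|Mar|Apr|May|Jun|Jul|Aug|Sep|Oct|Nov|Dec)"
_TIMESTAMP_RE = re.compile(
    r"(?:"
    r"(?:0?[1-9]|[12][0-9]|3[01])-" + _MMM + r"-[0-9]{4}"   # D-Mmm-YYYY / DD-Mmm-YYYY
    r"|" + _MMM + r"-[0-9]{4}"                               # Mmm-YYYY
    r"|[0-9]{4}"                                             # YYYY
    r"|[0-9]{4}-(?:0[1-9]|1[0-2])"                           # YYYY-mm
    r"|[0-9]{4}-(?:0[1-9]|1[0-2])-(?:0[1-9]|[12][0-9]|3[01])"
    r"(?:T(?:[01][0-9]|2[0-3]):[0-5][0-9]:[0-5][0-9])?"      # YYYY-mm-dd[Thh:mm:ss]
    r")",
    re.ASCII | re.IGNORECASE,
)


def validate_timestamp(value: str) -> Status:
    """Pattern-level date/timestamp check (see module docstring for the grammar)."""
    return Status.WELL_SPECIFIED if _TIMESTAMP_RE.fullmatch(value.strip()) else Status.INVALID


def validate_value_set(value: str, value_set: Iterable[str]) -> Status:
    """Case-insensitive membership of the trimmed value in a closed value set."""
    members = {m.casefold() for m in value_set}
    if not members:
        raise ValueError("value_set must be non-empty")
    return Status.WELL_SPECIFIED if value.strip().casefold() in members else Status.INVALID


# ---------------------------------------------------------------------------
# Ontology-term resolution
# ---------------------------------------------------------------------------

class TermResolver(Protocol):
    """Exact-match term lookup: value -> set of matching term identifiers.

    Matching is over preferred names, synonyms and term identifiers,
    case-insensitively; resolving the empty string yields the empty set.
    Implementations may be backed by a local index (the default) or by a
    remote terminology service exposing the same exact-search contract.
    """

    def resolve(self, value: str, ontology: str = ANY_ONTOLOGY) -> set[str]:
        ...


class ResolverError(RuntimeError):
    """The resolver backend is unavailable (e.g. remote service down)."""


class LocalTermIndex:
    """In-memory exact-match index over a tab-delimited term table.

    File format: ``ontology_acronym <TAB> term_id <TAB> preferred_label
    [<TAB> pipe-separated synonyms]``; ``#`` lines are comments.
    """

    def __init__(self) -> None:
        self._index: dict[str, dict[str, set[str]]] = {}
        #: per ontology, every resolvable key (term ids, labels, synonyms) verbatim
        self.keys_by_ontology: dict[str, list[str]] = {}

    @classmethod
    def from_tsv(cls, source: str | Path | IO[str]) -> "LocalTermIndex":
        idx = cls()
        if hasattr(source, "read"):
            idx._load(source)  # type: ignore[arg-type]
        else:
            with open(source, "r", encoding="utf-8") as fh:
                idx._load(fh)
        return idx

    def _load(self, fh: Iterable[str]) -> None:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"term index row needs >=3 columns: {line!r}")
            ontology, term_id, label = parts[0], parts[1], parts[2]
            synonyms = parts[3].split("|") if len(parts) > 3 and parts[3] else []
            for key in (term_id, label, *synonyms):
                self.add(ontology, term_id, key)

    def add(self, ontology: str, term_id: str, key: str) -> None:
        if key:
            self._index.setdefault(ontology, {}).setdefault(key.casefold(), set()).add(term_id)
            self.keys_by_ontology.setdefault(ontology, []).append(key)

    @property
    def ontologies(self) -> set[str]:
        return set(self._index)

    def resolve(self, value: str, ontology: str = ANY_ONTOLOGY) -> set[str]:
        key = value.strip().casefold()
        if not key:
            return set()
        if ontology == ANY_ONTOLOGY:
            hits: set[str] = set()
            for table in self._index.values():
                hits |= table.get(key, set())
            return hits
        return self._index.get(ontology, {}).get(key, set())


def bundled_term_index() -> LocalTermIndex:
    """The small ontology excerpt shipped with the package."""
    path = resources.files("metaqc").joinpath("data/term_index.tsv")
    return LocalTermIndex.from_tsv(str(path))


def resolve_and_validate_term(value: str, ontology: str, resolver: TermResolver) -> Status:
    """Well-specified iff the resolver finds >=1 exact match in the ontology.

    A resolver failure yields ``untested`` (never silently invalid).
    """
    if not value.strip():
        return Status.INVALID
    try:
        hits = resolver.resolve(value, ontology)
    except ResolverError:
        return Status.UNTESTED
    return Status.WELL_SPECIFIED if hits else Status.INVALID


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------

def validate_attribute(
    attr: Attribute,
    registry: SpecRegistry,
    resolver: TermResolver | None = None,
    accession: str = "",
) -> ValidationResult:
    """Look up the attribute's spec and apply the matching class validator."""
    spec: AttributeSpec | None = registry.lookup(attr.name)
    if spec is None:
        return ValidationResult(accession, attr.name, attr.value, None, Status.UNTESTED, "no_spec")
    vc = spec.value_class
    if vc is ValueClass.UNCHECKED:
        return ValidationResult(accession, attr.name, attr.value, vc, Status.UNTESTED, "unchecked_class")
    if vc is ValueClass.BOOLEAN:
        status, reason = validate_boolean(attr.value), "not_boolean"
    elif vc is ValueClass.INTEGER:
        status, reason = validate_integer(attr.value), "not_integer"
    elif vc is ValueClass.TIMESTAMP:
        status, reason = validate_timestamp(attr.value), "bad_date_format"
    elif vc is ValueClass.VALUE_SET:
        assert spec.value_set is not None
        status, reason = validate_value_set(attr.value, spec.value_set), "not_in_value_set"
    else:  # ontology_term
        if resolver is None:
            return ValidationResult(accession, attr.name, attr.value, vc, Status.UNTESTED, "resolver_error")
        assert spec.ontology is not None
        status = resolve_and_validate_term(attr.value, spec.ontology, resolver)
        reason = "resolver_error" if status is Status.UNTESTED else "no_ontology_match"
    if status is Status.WELL_SPECIFIED:
        return ValidationResult(accession, attr.name, attr.value, vc, status)
    return ValidationResult(accession, attr.name, attr.value, vc, status, reason)


def validate_record(
    record: SampleRecord,
    registry: SpecRegistry,
    resolver: TermResolver | None = None,
) -> list[ValidationResult]:
    """One result per attribute occurrence, in input order (duplicates kept)."""
    return [validate_attribute(a, registry, resolver, accession=record.accession) for a in record.attributes]


def validate_corpus(
    records: Iterable[SampleRecord],
    registry: SpecRegistry,
    resolver: TermResolver | None = None,
) -> Iterable[ValidationResult]:
    """Lazily validate every attribute of every record in a corpus."""
    for record in records:
        yield from validate_record(record, registry, resolver)
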