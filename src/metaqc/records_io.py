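"""Readers and writers for sample-metadata records in two repository dialects.

Biosample repositories distribute sample metadata either as large XML dumps
(NCBI BioSample: a ``BioSampleSet`` document with one ``BioSample`` element
per record) or as tab-delimited SampleTab files (EBI BioSamples: an ``[MSI]``
submission section followed by an ``[SCD]`` sample-characteristics table).
Both dialects are mapped onto a single record model, :class:`SampleRecord`,
which carries the identifying fields of a sample plus an *ordered* list of
name--value attributes.

Parsing is streaming for the XML dialect (memory use is bounded per record,
so multi-gigabyte dumps can be processed) and line-by-line for SampleTab.
Attribute names and values are preserved verbatim -- no trimming or case
normalization happens at parse time, because downstream censuses count
syntactically distinct names.

The SampleTab writer emits a small set of reserved columns (``Sample
Accession``, ``Sample Title``, ``Owner`` and the three date columns) so that
record-level fields survive a round trip through the tab-delimited dialect;
files without those columns parse exactly as plain SampleTab.
"""

from __future__ import annotations

import csv
import io
import re
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import IO, Iterable, Iterator, Sequence

from lxml import etree

__all__ = [
    "Repository",
    "Attribute",
    "SampleRecord",
    "ParseLog",
    "ParseError",
    "parse_ncbi_xml",
    "parse_sampletab",
    "serialize_records",
    "write_records",
    "find_duplicate_accessions",
]


class Repository(str, Enum):
    """Origin repository of a record (also selects the serialization dialect)."""

    NCBI = "NCBI"
    EBI = "EBI"


class ParseError(ValueError):
    """Unrecoverable parse failure (malformed document)."""


@dataclass
class Attribute:
    """One name--value pair on a sample record.

    ``term_source_ref``/``term_source_id`` hold the SampleTab ontology
    reference for the value, when present (e.g. an Organism value pointing
    at an NCBI Taxonomy identifier).
    """

    name: str
    value: str
    term_source_ref: str | None = None
    term_source_id: str | None = None


@dataclass
class SampleRecord:
    """A single sample metadata record in the common model.

    Dates are kept as raw text: submission and publication dates in the
    wild are frequently malformed, and interpreting them (e.g. extracting
    a year) is a reporting concern, not a parsing one.  ``package`` is
    ``None`` when the record does not state one; reports map unset packages
    to ``Generic`` (NCBI) or ``Unpackaged`` (EBI).
    """

    accession: str
    repository: Repository
    record_id: str = ""
    title: str | None = None
    publication_date: str = ""
    last_update_date: str = ""
    submission_date: str = ""
    organism_name: str | None = None
    organism_taxon_id: str | None = None
    owner: str | None = None
    package: str | None = None
    attributes: list[Attribute] = field(default_factory=list)


@dataclass
class ParseLog:
    """Collector for recoverable per-record problems met while parsing."""

    warnings: list[str] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# NCBI BioSample XML dialect
# ---------------------------------------------------------------------------

def parse_ncbi_xml(stream: IO[bytes] | str, log: ParseLog | None = None) -> Iterator[SampleRecord]:
    """Stream ``SampleRecord`` objects out of a BioSampleSet XML document.

    Parameters
    ----------
    stream
        A binary file-like object (or a path) containing a ``BioSampleSet``
        document with zero or more ``BioSample`` elements.
    log
        Optional :class:`ParseLog`; records lacking an accession are
        reported there and skipped, parsing continues.

    Yields one record per ``BioSample`` element, lazily; each element is
    cleared after use so peak memory is independent of corpus size.

    Raises :class:`ParseError` on malformed XML, naming the position at
    which parsing failed.
    """
    context = etree.iterparse(stream, events=("end",), tag="BioSample")
    try:
        for _, elem in context:
            rec = _biosample_element_to_record(elem)
            # free the subtree and preceding siblings kept by iterparse
            elem.clear()
            parent = elem.getparent()
            if parent is not None:
                while elem.getprevious() is not None:
                    del parent[0]
            if rec.accession:
                yield rec
            elif log is not None:
                log.errors.append(
                    f"BioSample element without accession (record_id={rec.record_id!r}) skipped"
                )
    except etree.XMLSyntaxError as exc:  # pragma: no cover - message formatting
        line, col = exc.position
        raise ParseError(f"malformed XML at line {line}, column {col}: {exc.msg}") from exc


def _biosample_element_to_record(elem: etree._Element) -> SampleRecord:
    rec = SampleRecord(
        accession=elem.get("accession", ""),
        repository=Repository.NCBI,
        record_id=elem.get("id", ""),
        publication_date=elem.get("publication_date", ""),
        last_update_date=elem.get("last_update", ""),
        submission_date=elem.get("submission_date", ""),
    )
    title = elem.findtext("Description/Title")
    rec.title = title if title is not None else None
    organism = elem.find("Description/Organism")
    if organism is not None:
        rec.organism_name = organism.get("taxonomy_name") or organism.findtext("OrganismName")
        rec.organism_taxon_id = organism.get("taxonomy_id")
    owner = elem.findtext("Owner/Name")
    rec.owner = owner if owner is not None else None
    package = elem.find("Package")
    if package is not None and package.text:
        rec.package = package.text
    for attr in elem.iterfind("Attributes/Attribute"):
        rec.attributes.append(
            Attribute(
                name=attr.get("attribute_name", ""),
                value=attr.text or "",
                term_source_ref=attr.get("term_source_ref"),
                term_source_id=attr.get("term_source_id"),
            )
        )
    return rec


def _record_to_biosample_element(rec: SampleRecord) -> etree._Element:
    elem = etree.Element("BioSample", accession=rec.accession)
    if rec.record_id:
        elem.set("id", rec.record_id)
    if rec.publication_date:
        elem.set("publication_date", rec.publication_date)
    if rec.last_update_date:
        elem.set("last_update", rec.last_update_date)
    if rec.submission_date:
        elem.set("submission_date", rec.submission_date)
    ids = etree.SubElement(elem, "Ids")
    idel = etree.SubElement(ids, "Id", db="BioSample", is_primary="1")
    idel.text = rec.accession
    if rec.title is not None or rec.organism_name is not None or rec.organism_taxon_id is not None:
        desc = etree.SubElement(elem, "Description")
        if rec.title is not None:
            etree.SubElement(desc, "Title").text = rec.title
        if rec.organism_name is not None or rec.organism_taxon_id is not None:
            org = etree.SubElement(desc, "Organism")
            if rec.organism_taxon_id is not None:
                org.set("taxonomy_id", rec.organism_taxon_id)
            if rec.organism_name is not None:
                org.set("taxonomy_name", rec.organism_name)
                etree.SubElement(org, "OrganismName").text = rec.organism_name
    if rec.owner is not None:
        owner = etree.SubElement(elem, "Owner")
        etree.SubElement(owner, "Name").text = rec.owner
    if rec.package is not None:
        etree.SubElement(elem, "Package").text = rec.package
    attrs = etree.SubElement(elem, "Attributes")
    for a in rec.attributes:
        ael = etree.SubElement(attrs, "Attribute", attribute_name=a.name)
        if a.term_source_ref is not None:
            ael.set("term_source_ref", a.term_source_ref)
        if a.term_source_id is not None:
            ael.set("term_source_id", a.term_source_id)
        ael.text = a.value
    return elem


# ---------------------------------------------------------------------------
# EBI SampleTab dialect
# ---------------------------------------------------------------------------

#: SCD columns mapped to record-level fields rather than attributes.
_RESERVED_COLUMNS = {
    "Sample Name": "record_id",
    "Sample Accession": "accession",
    "Sample Title": "title",
    "Owner": "owner",
    "Submission Date": "submission_date",
    "Publication Date": "publication_date",
    "Last Update Date": "last_update_date",
}
_TERM_SOURCE_REF = "Term Source REF"
_TERM_SOURCE_ID = "Term Source ID"
_NAMED_ATTRIBUTES = ("Organism", "Material", "Sex")
_CHARACTERISTIC_RE = re.compile(r"^Characteristic\[(.*)\]$")


def parse_sampletab(stream: IO[str] | Iterable[str], log: ParseLog | None = None) -> Iterator[SampleRecord]:
    """Stream ``SampleRecord`` objects out of a SampleTab file.

    Only the SCD section is consumed; the MSI section is skipped with a log
    line.  ``Characteristic[x]`` columns and the named-attribute columns
    (Organism, Material, Sex) become attributes; a ``Term Source REF`` /
    ``Term Source ID`` column pair attaches to the immediately preceding
    attribute column.  A missing SCD section yields an empty sequence and a
    warning; ragged rows are reported row-by-row and skipped.
    """
    reader = csv.reader(stream, delimiter="\t", quoting=csv.QUOTE_NONE)
    in_scd = False
    header: list[str] | None = None
    saw_msi = False
    for lineno, row in enumerate(reader, start=1):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        marker = row[0].strip()
        if marker == "[MSI]":
            saw_msi = True
            in_scd = False
            continue
        if marker == "[SCD]":
            in_scd = True
            continue
        if not in_scd:
            continue
        if header is None:
            header = row
            continue
        if len(row) > len(header):
            if log is not None:
                log.errors.append(f"line {lineno}: row has {len(row)} fields, header has {len(header)}; skipped")
            continue
        row = row + [""] * (len(header) - len(row))
        yield _scd_row_to_record(header, row)
    if header is None and log is not None:
        if saw_msi:
            log.warnings.append("no SCD section found (MSI only); produced no records")
        else:
            log.warnings.append("no SCD section found; produced no records")
    elif saw_msi and log is not None:
        log.warnings.append("MSI section skipped")


def _scd_row_to_record(header: Sequence[str], row: Sequence[str]) -> SampleRecord:
    rec = SampleRecord(accession="", repository=Repository.EBI)
    sample_name = ""
    i = 0
    while i < len(header):
        col, cell = header[i], row[i]
        if col in _RESERVED_COLUMNS:
            if col == "Sample Name":
                sample_name = cell
                rec.record_id = cell
            elif cell:
                setattr(rec, _RESERVED_COLUMNS[col], cell)
            i += 1
            continue
        if col in (_TERM_SOURCE_REF, _TERM_SOURCE_ID):
            # orphan term-source column (no preceding attribute cell); ignore
            i += 1
            continue
        m = _CHARACTERISTIC_RE.match(col)
        name = m.group(1) if m else col
        if cell:
            attr = Attribute(name=name, value=cell)
            # attach adjacent Term Source REF / Term Source ID columns
            j = i + 1
            while j < len(header) and header[j] in (_TERM_SOURCE_REF, _TERM_SOURCE_ID):
                if row[j]:
                    if header[j] == _TERM_SOURCE_REF:
                        attr.term_source_ref = row[j]
                    else:
                        attr.term_source_id = row[j]
                j += 1
            rec.attributes.append(attr)
        i += 1
    if not rec.accession:
        rec.accession = sample_name
    for a in rec.attributes:
        if a.name == "Organism":
            rec.organism_name = a.value
            if a.term_source_id is not None:
                rec.organism_taxon_id = a.term_source_id
            break
    return rec


def _sampletab_layout(records: Sequence[SampleRecord]) -> tuple[list[str], list[tuple[str, bool]]]:
    """Compute the deterministic SCD column layout for a corpus.

    Returns the reserved columns in use plus, for each attribute name in
    order of first appearance, one column per maximum within-record
    multiplicity, flagged for whether a term-source pair follows it.
    """
    reserved = ["Sample Name"]
    for col, fld in _RESERVED_COLUMNS.items():
        if col == "Sample Name":
            continue
        if any(getattr(r, fld) for r in records):
            reserved.append(col)
    multiplicity: Counter[str] = Counter()
    has_term_source: dict[str, bool] = {}
    for rec in records:
        per_rec: Counter[str] = Counter()
        for a in rec.attributes:
            has_term_source.setdefault(a.name, False)
            per_rec[a.name] += 1
            if a.term_source_ref is not None or a.term_source_id is not None:
                has_term_source[a.name] = True
        for name, k in per_rec.items():
            multiplicity[name] = max(multiplicity[name], k)
    # columns sorted by attribute name: the columnar format canonicalizes
    # cross-name order anyway, and a sorted layout makes parse(serialize(R))
    # order-preserving exactly when each record's attributes are name-sorted
    attr_cols = [(name, has_term_source[name]) for name in sorted(multiplicity) for _ in range(multiplicity[name])]
    return reserved, attr_cols


def _attr_column_header(name: str) -> str:
    if name in _NAMED_ATTRIBUTES or name in _RESERVED_COLUMNS or name in (_TERM_SOURCE_REF, _TERM_SOURCE_ID):
        # named attributes serialize as bare columns; collisions with the
        # reserved vocabulary are rejected earlier
        return name
    return f"Characteristic[{name}]"


def _check_ebi_serializable(rec: SampleRecord) -> None:
    for a in rec.attributes:
        for text, what in ((a.name, "name"), (a.value, "value"), (a.term_source_ref, "term source ref"), (a.term_source_id, "term source id")):
            if text is not None and ("\t" in text or "\n" in text or "\r" in text):
                raise ValueError(
                    f"record {rec.accession!r}: attribute {what} {text!r} contains a tab/newline; "
                    "cannot be represented in the tab-delimited dialect"
                )
        if a.name in _RESERVED_COLUMNS or a.name in (_TERM_SOURCE_REF, _TERM_SOURCE_ID):
            raise ValueError(f"record {rec.accession!r}: attribute name {a.name!r} collides with a reserved SCD column")
        if not a.value:
            raise ValueError(
                f"record {rec.accession!r}: attribute {a.name!r} has an empty value; an empty SCD "
                "cell means 'absent', so the EBI dialect cannot represent it"
            )
    for fld in ("record_id", "accession", "title", "owner", "submission_date", "publication_date", "last_update_date"):
        text = getattr(rec, fld)
        if text and ("\t" in text or "\n" in text or "\r" in text):
            raise ValueError(f"record {rec.accession!r}: field {fld} contains a tab/newline")


# ---------------------------------------------------------------------------
# Serialization (both dialects)
# ---------------------------------------------------------------------------

def write_records(records: Iterable[SampleRecord], dialect: Repository, out: IO[str]) -> int:
    """Write records in the given dialect to a text stream; returns the count.

    Every record must carry an accession.  The NCBI writer is incremental
    (one element at a time); the EBI writer needs two passes over the corpus
    to lay out columns and therefore materializes the record list.
    """
    n = 0
    if dialect is Repository.NCBI:
        out.write('<?xml version="1.0" encoding="UTF-8"?>\n<BioSampleSet>\n')
        for rec in records:
            if not rec.accession:
                raise ValueError("cannot serialize a record without an accession")
            payload = etree.tostring(_record_to_biosample_element(rec), encoding="unicode", pretty_print=True)
            out.write(payload)
            n += 1
        out.write("</BioSampleSet>\n")
        return n

    recs = list(records)
    for rec in recs:
        if not rec.accession:
            raise ValueError("cannot serialize a record without an accession")
        _check_ebi_serializable(rec)
    reserved, attr_cols = _sampletab_layout(recs)
    header: list[str] = list(reserved)
    for name, with_ts in attr_cols:
        header.append(_attr_column_header(name))
        if with_ts:
            header.extend((_TERM_SOURCE_REF, _TERM_SOURCE_ID))
    out.write("[SCD]\n")
    out.write("\t".join(header) + "\n")
    for rec in recs:
        row: list[str] = []
        for col in reserved:
            if col == "Sample Name":
                row.append(rec.record_id)
            else:
                row.append(getattr(rec, _RESERVED_COLUMNS[col]) or "")
        remaining: dict[str, list[Attribute]] = {}
        for a in rec.attributes:
            remaining.setdefault(a.name, []).append(a)
        for name, with_ts in attr_cols:
            queue = remaining.get(name)
            a = queue.pop(0) if queue else None
            row.append(a.value if a is not None else "")
            if with_ts:
                row.append(a.term_source_ref or "" if a is not None else "")
                row.append(a.term_source_id or "" if a is not None else "")
        out.write("\t".join(row) + "\n")
        n += 1
    return n


def serialize_records(records: Iterable[SampleRecord], dialect: Repository) -> str:
    """Serialize records to a string in the given dialect (see :func:`write_records`)."""
    buf = io.StringIO()
    write_records(records, dialect, buf)
    return buf.getvalue()


def find_duplicate_accessions(records: Iterable[SampleRecord]) -> dict[str, int]:
    """Audit a parsed corpus for accessions used by more than one record.

    Repositories intend accessions to be unique within a snapshot; the
    parsers deliberately surface duplicates instead of silently dropping
    records, leaving de-duplication policy to the caller.
    """
    counts = Counter(r.accession for r in records)
    return {acc: n for acc, n in counts.items() if n > 1}
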