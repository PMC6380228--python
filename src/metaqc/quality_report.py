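"""Aggregate per-attribute verdicts and record metadata into summary reports.

The reports mirror the standard questions asked of a biosample metadata
snapshot: how well-specified is each attribute group (per-attribute and
per-record counts); how are records distributed over packages and
submission years; how many syntactically unique attribute names are in use
and how many of them are dictionary versus custom; which records exist in
both repositories; how many syntactically distinct term-source URIs appear
and whether they are well-formed; and how many records touch each curated
concept group of redundant attribute names.

Percentages are carried as floats and rounded to the nearest integer for
display; raw counts are always available alongside.
"""

from __future__ import annotations

import json
import re
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Callable, Collection, Iterable, Mapping

from .attribute_specs import SpecRegistry, ValueClass
from .records_io import Repository, SampleRecord
from .validators import Status, ValidationResult

__all__ = [
    "QualitySummary",
    "CensusReport",
    "IntersectionReport",
    "summarize_by_type",
    "package_distribution",
    "submissions_per_year",
    "attribute_name_census",
    "intersect_repositories",
    "term_source_uri_census",
    "concept_record_counts",
    "categorize_top_names",
    "load_concept_groups",
    "load_name_categories",
    "bundled_concept_groups",
    "bundled_name_categories",
]


@dataclass
class QualitySummary:
    """Validity counts for one attribute group (value class)."""

    value_class: ValueClass
    attributes_total: int = 0
    attributes_well_specified: int = 0
    records_with_class: int = 0
    records_all_valid: int = 0

    @property
    def attributes_invalid(self) -> int:
        return self.attributes_total - self.attributes_well_specified

    @property
    def percent_well_specified(self) -> float | None:
        """Percentage on 0--100, or None when the group is empty."""
        if self.attributes_total == 0:
            return None
        return 100.0 * self.attributes_well_specified / self.attributes_total

    @property
    def percent_display(self) -> int | None:
        p = self.percent_well_specified
        return None if p is None else round(p)


@dataclass
class CensusReport:
    """Census of attribute names across a corpus.

    Unique names are exact strings after surrounding-whitespace trim
    (case-sensitive); a name is *custom* when it is absent from the
    repository's attribute dictionary.
    """

    total_records: int
    total_attributes: int
    unique_names: int
    dictionary_names_used: int
    custom_names: int
    attributes_using_custom_names: int
    records_touched_by_custom_names: int
    mean_attributes_per_record: float


@dataclass
class IntersectionReport:
    ncbi_records: int
    ebi_records: int
    shared_accessions: set[str] = field(default_factory=set)
    shared_attribute_names: set[str] = field(default_factory=set)
    ncbi_attribute_names: int = 0
    ebi_attribute_names: int = 0


_CHECKED_CLASSES = (
    ValueClass.BOOLEAN,
    ValueClass.INTEGER,
    ValueClass.TIMESTAMP,
    ValueClass.VALUE_SET,
    ValueClass.ONTOLOGY_TERM,
)


def _as_predicate(subset: Collection[str] | Callable[[str], bool] | None) -> Callable[[str], bool]:
    if subset is None:
        return lambda acc: True
    if callable(subset):
        return subset
    members = set(subset)
    return lambda acc: acc in members


def summarize_by_type(
    results: Iterable[ValidationResult],
    subset_filter: Collection[str] | Callable[[str], bool] | None = None,
) -> dict[ValueClass, QualitySummary]:
    """Partition verdicts by value class and count validity per attribute and record.

    ``subset_filter`` restricts the summary to records whose accession
    satisfies the predicate (or belongs to the given collection) -- e.g.
    the packaged subset, or the accessions shared with the other
    repository.  Untested verdicts never enter the counts.
    """
    keep = _as_predicate(subset_filter)
    summaries = {vc: QualitySummary(vc) for vc in _CHECKED_CLASSES}
    record_class_valid: dict[ValueClass, dict[str, bool]] = {vc: {} for vc in _CHECKED_CLASSES}
    for res in results:
        if res.status is Status.UNTESTED or res.value_class is None:
            continue
        if res.value_class not in summaries or not keep(res.accession):
            continue
        s = summaries[res.value_class]
        s.attributes_total += 1
        ok = res.status is Status.WELL_SPECIFIED
        if ok:
            s.attributes_well_specified += 1
        per_rec = record_class_valid[res.value_class]
        per_rec[res.accession] = per_rec.get(res.accession, True) and ok
    for vc, per_rec in record_class_valid.items():
        summaries[vc].records_with_class = len(per_rec)
        summaries[vc].records_all_valid = sum(per_rec.values())
    return summaries


def record_package_label(record: SampleRecord) -> str:
    """Report-time package label for a record.

    NCBI records without a package element belong to the undocumented
    ``Generic`` package; EBI records are ``Unpackaged`` unless they carry a
    ``package`` attribute whose value mirrors an NCBI package definition.
    """
    if record.package:
        return record.package
    if record.repository is Repository.EBI:
        for a in record.attributes:
            if a.name == "package" and a.value:
                return a.value
        return "Unpackaged"
    return "Generic"


def package_distribution(records: Iterable[SampleRecord]) -> dict[str, tuple[int, float]]:
    """Mapping package label -> (record count, percentage of corpus)."""
    counts: Counter[str] = Counter(record_package_label(r) for r in records)
    total = sum(counts.values())
    return {pkg: (n, 100.0 * n / total) for pkg, n in counts.items()} if total else {}


_YEAR_RE = re.compile(r"\s*([0-9]{4})(?:[^0-9].*)?$", re.DOTALL)


def submission_year(record: SampleRecord) -> str:
    """Leading 4-digit year of the submission date, or ``"unknown"``."""
    m = _YEAR_RE.fullmatch(record.submission_date or "")
    return m.group(1) if m else "unknown"


def submissions_per_year(
    records: Iterable[SampleRecord],
    split_generic: bool = False,
) -> dict[str, int] | dict[str, dict[str, int]]:
    """Histogram of records per submission year.

    With ``split_generic=True`` each year maps to separate counts for
    records on the Generic package versus any other package.
    """
    if not split_generic:
        return dict(Counter(submission_year(r) for r in records))
    out: dict[str, dict[str, int]] = defaultdict(lambda: {"Generic": 0, "non-Generic": 0})
    for r in records:
        key = "Generic" if record_package_label(r) == "Generic" else "non-Generic"
        out[submission_year(r)][key] += 1
    return dict(out)


def attribute_name_census(records: Iterable[SampleRecord], registry: SpecRegistry) -> CensusReport:
    """Count attribute use and syntactically unique names, split dictionary/custom."""
    total_records = 0
    total_attributes = 0
    attrs_custom = 0
    records_custom = 0
    names: set[str] = set()
    for rec in records:
        total_records += 1
        touched = False
        for a in rec.attributes:
            total_attributes += 1
            name = a.name.strip()
            names.add(name)
            if registry.lookup(name) is None:
                attrs_custom += 1
                touched = True
        if touched:
            records_custom += 1
    custom_names = sum(1 for n in names if registry.lookup(n) is None)
    return CensusReport(
        total_records=total_records,
        total_attributes=total_attributes,
        unique_names=len(names),
        dictionary_names_used=len(names) - custom_names,
        custom_names=custom_names,
        attributes_using_custom_names=attrs_custom,
        records_touched_by_custom_names=records_custom,
        mean_attributes_per_record=(total_attributes / total_records) if total_records else 0.0,
    )


def intersect_repositories(
    ncbi_records: Iterable[SampleRecord],
    ebi_records: Iterable[SampleRecord],
) -> IntersectionReport:
    """Accession intersection and shared unique attribute names of two corpora."""
    ncbi_acc: set[str] = set()
    ncbi_names: set[str] = set()
    n_ncbi = 0
    for r in ncbi_records:
        n_ncbi += 1
        ncbi_acc.add(r.accession)
        ncbi_names.update(a.name.strip() for a in r.attributes)
    ebi_acc: set[str] = set()
    ebi_names: set[str] = set()
    n_ebi = 0
    for r in ebi_records:
        n_ebi += 1
        ebi_acc.add(r.accession)
        ebi_names.update(a.name.strip() for a in r.attributes)
    return IntersectionReport(
        ncbi_records=n_ncbi,
        ebi_records=n_ebi,
        shared_accessions=ncbi_acc & ebi_acc,
        shared_attribute_names=ncbi_names & ebi_names,
        ncbi_attribute_names=len(ncbi_names),
        ebi_attribute_names=len(ebi_names),
    )


_URI_SCHEME_RE = re.compile(r"^[A-Za-z][A-Za-z0-9+.\-]*://\S+$")


def term_source_uri_census(records: Iterable[SampleRecord]) -> dict[str, tuple[int, str]]:
    """Distinct term-source URIs with use counts and a syntactic verdict.

    A URI is ``well_formed`` when it has a scheme followed by ``://`` and a
    non-empty remainder; e.g. ``http//example.org`` (no colon after the
    scheme) is ``malformed``.  URIs differing only by a trailing slash are
    distinct entries: the census is deliberately syntactic.
    """
    counts: Counter[str] = Counter()
    for rec in records:
        for a in rec.attributes:
            if a.term_source_ref:
                counts[a.term_source_ref] += 1
    return {
        uri: (n, "well_formed" if _URI_SCHEME_RE.match(uri) else "malformed")
        for uri, n in counts.items()
    }


def concept_record_counts(
    records: Iterable[SampleRecord],
    concept_groups: Mapping[str, Collection[str]],
) -> dict[str, int]:
    """Per concept, the number of records using *any* member attribute name.

    A record counts once per concept no matter how many member names it
    uses.  Groups are expected to be disjoint; overlaps trigger a warning.
    """
    member_of: dict[str, str] = {}
    for concept, members in concept_groups.items():
        for name in members:
            if name in member_of and member_of[name] != concept:
                warnings.warn(
                    f"attribute name {name!r} appears in concept groups "
                    f"{member_of[name]!r} and {concept!r}",
                    stacklevel=2,
                )
            member_of[name] = concept
    out: dict[str, int] = {concept: 0 for concept in concept_groups}
    for rec in records:
        hit: set[str] = set()
        for a in rec.attributes:
            concept = member_of.get(a.name.strip())
            if concept is not None:
                hit.add(concept)
        for concept in hit:
            out[concept] += 1
    return out


def categorize_top_names(
    records: Iterable[SampleRecord],
    categories: Mapping[str, Collection[str]],
    top_n: int = 50,
) -> list[tuple[str, int, str]]:
    """Rank names by occurrence count and tag the top ``top_n`` with a category.

    Returns ``(name, occurrences, category)`` triples; names missing from
    the category fixture are tagged ``"unmapped"``.
    """
    from .name_clustering import rank_names_by_use  # local import: avoid cycle

    category_of: dict[str, str] = {}
    for cat, members in categories.items():
        for name in members:
            category_of[name] = cat
    ranked = rank_names_by_use(records)[:top_n]
    return [(u.name, u.n_occurrences, category_of.get(u.name, "unmapped")) for u in ranked]


# ---------------------------------------------------------------------------
# Fixtures and output helpers
# ---------------------------------------------------------------------------

def _load_two_column_tsv(source: str | Path | IO[str]) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {}
    if hasattr(source, "read"):
        lines = list(source)  # type: ignore[arg-type]
    else:
        with open(source, "r", encoding="utf-8") as fh:
            lines = list(fh)
    for line in lines:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        key, _, member = line.partition("\t")
        if not member:
            raise ValueError(f"expected two tab-separated columns: {line!r}")
        groups.setdefault(key, []).append(member)
    return groups


def load_concept_groups(source: str | Path | IO[str]) -> dict[str, list[str]]:
    """Load a concept -> member-names fixture (TSV, one pair per row)."""
    return _load_two_column_tsv(source)


def load_name_categories(source: str | Path | IO[str]) -> dict[str, list[str]]:
    """Load a category -> attribute-names fixture (TSV, one pair per row)."""
    return _load_two_column_tsv(source)


def bundled_concept_groups() -> dict[str, list[str]]:
    return load_concept_groups(str(resources.files("metaqc").joinpath("data/concept_groups.tsv")))


def bundled_name_categories() -> dict[str, list[str]]:
    return load_name_categories(str(resources.files("metaqc").joinpath("data/name_categories.tsv")))


def summaries_to_json(summaries: Mapping[ValueClass, QualitySummary]) -> str:
    """Serialize per-class summaries (counts plus display percentages) to JSON."""
    doc = {}
    for vc, s in summaries.items():
        doc[vc.value] = {
            "attributes_total": s.attributes_total,
            "attributes_well_specified": s.attributes_well_specified,
            "attributes_invalid": s.attributes_invalid,
            "records_with_class": s.records_with_class,
            "records_all_valid": s.records_all_valid,
            "percent_well_specified": s.percent_well_specified,
            "percent_display": s.percent_display,
        }
    return json.dumps(doc, indent=2, sort_keys=True)


def results_to_tsv(results: Iterable[ValidationResult], out: IO[str]) -> int:
    """Write verdicts as TSV; returns the row count."""
    out.write("accession\tattribute_name\tvalue\tvalue_class\tstatus\treason\n")
    n = 0
    for r in results:
        vc = r.value_class.value if r.value_class is not None else ""
        out.write(f"{r.accession}\t{r.attribute_name}\t{r.value}\t{vc}\t{r.status.value}\t{r.reason or ''}\n")
        n += 1
    return n
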