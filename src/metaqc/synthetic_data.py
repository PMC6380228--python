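"""Synthetic metadata corpora with exact, known ground truth.

The generator emulates the statistical structure of a repository snapshot
-- a package mix, a submission-year histogram, a controlled fraction of
well-specified values per attribute group, and a controlled rate of custom
(typo/decoration-variant) attribute names -- while recording, for every
generated attribute, what was intended: its value class, whether the value
is valid, and for custom names which dictionary name it was derived from.

Composition is *exact*, not sampled: fractions are converted to integer
counts by largest-remainder apportionment and deterministic rounding, so
every downstream report can be checked for equality against the
:class:`GroundTruthLedger` instead of statistically.  Everything is
reproducible from a single seed, and generated corpora serialize cleanly
in the repository dialects (invalid-value pools contain no empty strings
or tab characters).

Invalid values are drawn from class-aware pools seeded with the kinds of
entries observed in the wild -- ``Yes``/``N``/``--``/``never smoker`` for
booleans, ``Fluoxetine`` or ``Mus musculus`` for integers, ``1800/2014``
or ``no description`` for timestamps, ``mal e``/``makle``/``femLE`` for
value sets, underscore-mangled labels for ontology terms -- and every draw
is re-checked against the real validators at generation time, so the
ledger is correct by construction.
"""

from __future__ import annotations

import json
import math
import random
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .attribute_specs import (
    ANY_ONTOLOGY,
    SpecRegistry,
    ValueClass,
    load_bundled_registry,
)
from .records_io import Attribute, Repository, SampleRecord
from .validators import (
    LocalTermIndex,
    Status,
    bundled_term_index,
    validate_boolean,
    validate_integer,
    validate_timestamp,
    validate_value_set,
)

__all__ = [
    "TypoModel",
    "CorpusConfig",
    "ConfigError",
    "AttributeTruth",
    "GroundTruthLedger",
    "generate_corpus",
    "generate_paired_corpora",
    "perturb_name",
]


class ConfigError(ValueError):
    """The corpus configuration is inconsistent or infeasible."""


@dataclass(frozen=True)
class TypoModel:
    """How custom attribute-name variants are fabricated from dictionary names.

    ``edit_rate`` single-character edits (insert/delete/substitute) are
    applied, and/or one decoration affix is appended -- emulating names
    like ``weight (kg)``, ``weight_kg`` or ``Weight..kg.`` derived from a
    canonical name.
    """

    edit_rate: int = 1
    decorations: tuple[str, ...] = (" (kg)", "_kg", " (m)", "..kg.", "_years", " (cm)")


_CHECKED = (
    ValueClass.BOOLEAN,
    ValueClass.INTEGER,
    ValueClass.TIMESTAMP,
    ValueClass.VALUE_SET,
    ValueClass.ONTOLOGY_TERM,
)

_NCBI_PACKAGE_MIX = {
    "Generic": 0.85,
    "Pathogen.cl.1.0": 0.032,
    "Microbe.1.0": 0.04,
    "Human.1.0": 0.03,
    "Plant.1.0": 0.028,
    "Metagenome.environmental.1.0": 0.02,
}
_EBI_PACKAGE_MIX = {
    "Unpackaged": 0.60,
    "Generic": 0.16,
    "Metagenome.environmental.1.0": 0.04,
    "Pathogen.cl.1.0": 0.08,
    "Microbe.1.0": 0.12,
}
_YEAR_HISTOGRAM = {
    2009: 0.005, 2010: 0.01, 2011: 0.02, 2012: 0.045, 2013: 0.07,
    2014: 0.12, 2015: 0.17, 2016: 0.25, 2017: 0.31,
}
_NCBI_VALIDITY = {
    ValueClass.BOOLEAN: 0.27,
    ValueClass.INTEGER: 0.74,
    ValueClass.TIMESTAMP: 0.74,
    ValueClass.VALUE_SET: 0.92,
    ValueClass.ONTOLOGY_TERM: 0.32,
}
_EBI_VALIDITY = {
    ValueClass.ONTOLOGY_TERM: 0.87,
    ValueClass.VALUE_SET: 0.90,
}

#: plain (non-variant) submitter-invented names used when the profile has
#: no unchecked dictionary names to draw filler from (the EBI profile).
_PLAIN_CUSTOM_POOL = (
    "source name", "Sample_title", "project name", "study name", "common name",
    "secondary description", "time point", "developmental stage", "cell line name",
    "growth condition", "sample id", "label",
)

_INVALID_BOOLEAN = (
    "Yes", "No", "Y", "N", "0", "--", "never", "never smoker", "Non-smoker",
    "nonsmoker", "non smoker", "ex-smoker", "Ex smoker", "former-smoker",
    "Former", "current smoker", "f", "yes",
)
_INVALID_INTEGER = (
    "e;N/A", "Mus musculus", "NO", "3.5", "Fluoxetine",
    "Insulin glargine injectable solution", "Simvastatin", "N/A", "12,345",
    "seven", "4e6", "- 7",
)
_INVALID_TIMESTAMP = (
    "1800/2014", "Jan-Feb 2009", "no description", "unspecified", "2014-13-01",
    "32-Jan-2000", "2000/11/20", "20 Nov 2000", "Nov 20, 2000", "2000-1-5",
    "not collected", "0-Jan-2000",
)
_INVALID_VALUE_SET = (
    "m", "f", "mal e", "makle", "femLE", "juvenile", "Sexual equality",
    "unknown", "N/A", "--", "castrated horse", "uncertainty",
)
_INVALID_ONTOLOGY = (
    "lung_squamous_carcinoma", "gastrointestinal stromal tumor_4", "HIV_Positive",
    "infected with Tomato spotted wilt virus isolate p105RBMar", "784523",
    "n/a", "Homo_sapiens", "mixed_sex", "unknown_sex",
)
_MONTHS = ("Jan", "Feb", "Mar", "Apr", "May", "Jun", "Jul", "Aug", "Sep", "Oct", "Nov", "Dec")
_ORGANISMS = (("9606", "Homo sapiens"), ("10090", "Mus musculus"),
              ("562", "Escherichia coli"), ("3702", "Arabidopsis thaliana"))
_OWNERS = ("Lab A", "Lab B", "EBI", "Institute C")


@dataclass
class CorpusConfig:
    """Parameters of a synthetic corpus; defaults emulate a repository snapshot.

    The default package mix, year histogram and per-class validity
    fractions mirror the reported composition of the 2017 snapshots
    (85% Generic packages, rising submissions 2009--2017, and 27% / 74% /
    74% / 92% / 32% well-specified boolean / integer / timestamp /
    value-set / ontology-term attributes for the NCBI profile).
    """

    n_records: int = 10_000
    repository: Repository = Repository.NCBI
    package_mix: Mapping[str, float] = field(default_factory=lambda: dict(_NCBI_PACKAGE_MIX))
    year_histogram: Mapping[int, float] = field(default_factory=lambda: dict(_YEAR_HISTOGRAM))
    per_class_validity: Mapping[ValueClass, float] = field(default_factory=lambda: dict(_NCBI_VALIDITY))
    class_attrs_per_record: Mapping[ValueClass, int] | None = None  # default: 1 each
    attributes_per_record: int = 12
    #: fraction of all attribute occurrences that should carry custom
    #: (non-dictionary) names; capped by the number of filler slots
    custom_name_rate: float = 0.15
    typo_model: TypoModel = field(default_factory=TypoModel)
    #: URIs planted as Term Source REF on ontology-term attributes
    #: (fraction of those attributes per URI; empty = no term sources).
    uri_pool: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def for_repository(cls, repository: Repository, **overrides) -> "CorpusConfig":
        """Defaults adapted to a repository profile (EBI has only 2 checked classes)."""
        repository = Repository(repository)
        base: dict = {"repository": repository}
        if repository is Repository.EBI:
            base.update(
                package_mix=dict(_EBI_PACKAGE_MIX),
                per_class_validity=dict(_EBI_VALIDITY),
                attributes_per_record=10,
                uri_pool={"http://purl.obolibrary.org/obo/ncbitaxon": 1.0},
            )
        base.update(overrides)
        return cls(**base)

    def normalized_class_counts(self) -> dict[ValueClass, int]:
        if self.class_attrs_per_record is None:
            return {ValueClass(c): 1 for c in self.per_class_validity}
        return {ValueClass(c): int(n) for c, n in self.class_attrs_per_record.items()}

    def validate(self, registry: SpecRegistry) -> None:
        for what, fractions in (("package_mix", self.package_mix), ("year_histogram", self.year_histogram)):
            if fractions:
                total = sum(fractions.values())
                if not math.isclose(total, 1.0, abs_tol=1e-9):
                    raise ConfigError(f"{what} fractions must sum to 1, got {total}")
                if any(f < 0 for f in fractions.values()):
                    raise ConfigError(f"{what} fractions must be non-negative")
        if not 0.0 <= self.custom_name_rate <= 1.0:
            raise ConfigError(f"custom_name_rate must be in [0,1], got {self.custom_name_rate}")
        counts = self.normalized_class_counts()
        for c, frac in self.per_class_validity.items():
            vc = ValueClass(c)
            if vc not in _CHECKED:
                raise ConfigError(f"per_class_validity: {vc.value} is not a checkable class")
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(f"per_class_validity[{vc.value}] must be in [0,1], got {frac}")
            if counts.get(vc, 0) <= 0:
                raise ConfigError(f"validity fraction given for class {vc.value} with zero attributes per record")
            if not registry.names_by_class(vc):
                raise ConfigError(f"profile {registry.repository_profile.value} has no {vc.value} attributes")
        n_checked = sum(counts.get(vc, 0) for vc in self.per_class_validity)
        if self.attributes_per_record < n_checked:
            raise ConfigError(
                f"attributes_per_record={self.attributes_per_record} is fewer than the "
                f"{n_checked} checked attributes per record"
            )


@dataclass(frozen=True)
class AttributeTruth:
    """Intended truth for one generated attribute occurrence."""

    accession: str
    name: str
    value: str
    value_class: ValueClass | None
    intended_valid: bool | None          # None for unchecked/custom attributes
    is_custom: bool
    source_name: str | None = None       # dictionary name a custom variant derives from


@dataclass
class GroundTruthLedger:
    """Everything the generator intended, queryable as expected report values."""

    repository: Repository
    attributes: list[AttributeTruth] = field(default_factory=list)
    record_packages: dict[str, str] = field(default_factory=dict)
    record_years: dict[str, int] = field(default_factory=dict)
    planted_uris: Counter = field(default_factory=Counter)
    shared_accessions: set[str] = field(default_factory=set)

    # -- expected report values -------------------------------------------
    def expected_class_summary(self) -> dict[ValueClass, dict[str, int]]:
        out: dict[ValueClass, dict[str, int]] = {}
        per_rec: dict[ValueClass, dict[str, bool]] = {}
        for t in self.attributes:
            if t.value_class is None or t.intended_valid is None:
                continue
            s = out.setdefault(t.value_class, {"attributes_total": 0, "attributes_well_specified": 0})
            s["attributes_total"] += 1
            s["attributes_well_specified"] += int(t.intended_valid)
            d = per_rec.setdefault(t.value_class, {})
            d[t.accession] = d.get(t.accession, True) and t.intended_valid
        for vc, d in per_rec.items():
            out[vc]["records_with_class"] = len(d)
            out[vc]["records_all_valid"] = sum(d.values())
        return out

    def expected_package_distribution(self) -> dict[str, int]:
        return dict(Counter(self.record_packages.values()))

    def expected_year_histogram(self) -> dict[str, int]:
        return {str(y): n for y, n in sorted(Counter(self.record_years.values()).items())}

    def expected_census(self) -> dict[str, int | float]:
        names_custom: set[str] = set()
        names_dict: set[str] = set()
        attrs_custom = 0
        touched: set[str] = set()
        for t in self.attributes:
            (names_custom if t.is_custom else names_dict).add(t.name.strip())
            if t.is_custom:
                attrs_custom += 1
                touched.add(t.accession)
        n_records = len(self.record_packages)
        return {
            "total_records": n_records,
            "total_attributes": len(self.attributes),
            "unique_names": len(names_custom | names_dict),
            "dictionary_names_used": len(names_dict),
            "custom_names": len(names_custom),
            "attributes_using_custom_names": attrs_custom,
            "records_touched_by_custom_names": len(touched),
            "mean_attributes_per_record": len(self.attributes) / n_records if n_records else 0.0,
        }

    def expected_concept_counts(self, concept_groups: Mapping[str, Sequence[str]]) -> dict[str, int]:
        member_of = {name: c for c, members in concept_groups.items() for name in members}
        per_concept: dict[str, set[str]] = {c: set() for c in concept_groups}
        for t in self.attributes:
            c = member_of.get(t.name.strip())
            if c is not None:
                per_concept[c].add(t.accession)
        return {c: len(accs) for c, accs in per_concept.items()}

    def expected_uri_census(self) -> dict[str, int]:
        return dict(self.planted_uris)

    def to_json(self) -> str:
        doc = {
            "repository": self.repository.value,
            "record_packages": self.record_packages,
            "record_years": self.record_years,
            "planted_uris": dict(self.planted_uris),
            "shared_accessions": sorted(self.shared_accessions),
            "attributes": [
                {
                    "accession": t.accession,
                    "name": t.name,
                    "value": t.value,
                    "value_class": t.value_class.value if t.value_class else None,
                    "intended_valid": t.intended_valid,
                    "is_custom": t.is_custom,
                    "source_name": t.source_name,
                }
                for t in self.attributes
            ],
        }
        return json.dumps(doc, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Name perturbation
# ---------------------------------------------------------------------------

_EDIT_ALPHABET = "abcdefghijklmnopqrstuvwxyz_ "


def _perturb(rng: random.Random, name: str, model: TypoModel) -> str:
    out = name
    for _ in range(max(0, model.edit_rate)):
        op = rng.choice(("insert", "delete", "substitute")) if out else "insert"
        ch = rng.choice(_EDIT_ALPHABET)
        pos = rng.randrange(len(out) + 1) if op == "insert" else (rng.randrange(len(out)) if out else 0)
        if op == "insert":
            out = out[:pos] + ch + out[pos:]
        elif op == "delete":
            out = out[:pos] + out[pos + 1:]
        else:
            out = out[:pos] + ch + out[pos + 1:]
    if model.decorations and (model.edit_rate == 0 or rng.random() < 0.5):
        out = out + rng.choice(model.decorations)
    return out if out else name + rng.choice(model.decorations or ("_x",))


def perturb_name(name: str, typo_model: TypoModel, seed: int = 0) -> str:
    """One typo/decoration variant of ``name``; reproducible from ``seed``.

    The edit distance between input and variant is bounded by
    ``edit_rate`` plus the longest decoration length.
    """
    if not name:
        raise ValueError("name must be non-empty")
    return _perturb(random.Random(seed), name, typo_model)


# ---------------------------------------------------------------------------
# Exact apportionment helpers
# ---------------------------------------------------------------------------

def _apportion(fractions: Mapping, n: int) -> dict:
    """Largest-remainder conversion of fractions to integer counts summing to n."""
    keys = list(fractions)
    base = {k: int(math.floor(fractions[k] * n)) for k in keys}
    leftover = n - sum(base.values())
    remainders = sorted(keys, key=lambda k: (-(fractions[k] * n - base[k]), keys.index(k)))
    for k in remainders[:leftover]:
        base[k] += 1
    return base


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _composition_flags(n_true: int, n_total: int, rng: random.Random) -> list[bool]:
    flags = [True] * n_true + [False] * (n_total - n_true)
    rng.shuffle(flags)
    return flags


def _labels_from_counts(counts: Mapping, rng: random.Random) -> list:
    labels = [k for k, n in counts.items() for _ in range(n)]
    rng.shuffle(labels)
    return labels


# ---------------------------------------------------------------------------
# Value draws (each draw re-checked against the real validators)
# ---------------------------------------------------------------------------

def _draw_boolean(rng: random.Random, valid: bool) -> str:
    v = rng.choice(("true", "false", "TRUE", "FALSE", "True", "False")) if valid else rng.choice(_INVALID_BOOLEAN)
    assert (validate_boolean(v) is Status.WELL_SPECIFIED) == valid
    return v


def _draw_integer(rng: random.Random, valid: bool) -> str:
    if valid:
        v = str(rng.randint(-10_000, 10_000_000))
    else:
        v = rng.choice(_INVALID_INTEGER)
    assert (validate_integer(v) is Status.WELL_SPECIFIED) == valid
    return v


def _draw_timestamp(rng: random.Random, valid: bool) -> str:
    if valid:
        y, m, d = rng.randint(1990, 2017), rng.randint(1, 12), rng.randint(1, 28)
        v = rng.choice((
            f"{d}-{_MONTHS[m - 1]}-{y}",
            f"{_MONTHS[m - 1]}-{y}",
            f"{y}",
            f"{y}-{m:02d}",
            f"{y}-{m:02d}-{d:02d}",
            f"{y}-{m:02d}-{d:02d}T{rng.randint(0, 23):02d}:{rng.randint(0, 59):02d}:{rng.randint(0, 59):02d}",
        ))
    else:
        v = rng.choice(_INVALID_TIMESTAMP)
    assert (validate_timestamp(v) is Status.WELL_SPECIFIED) == valid
    return v


def _case_variant(rng: random.Random, s: str) -> str:
    return rng.choice((s, s.upper(), s.capitalize(), s.lower()))


def _draw_value_set(rng: random.Random, valid: bool, members: frozenset[str]) -> str:
    ordered = sorted(members)
    folded = {m.casefold() for m in members}
    if valid:
        v = _case_variant(rng, rng.choice(ordered))
    else:
        candidates = [c for c in _INVALID_VALUE_SET if c.casefold() not in folded]
        corrupt = rng.choice(ordered)
        corrupt = corrupt[: max(1, len(corrupt) // 2)] + " " + corrupt[max(1, len(corrupt) // 2):]
        if corrupt.casefold() not in folded:
            candidates.append(corrupt)
        v = rng.choice(candidates)
    assert (validate_value_set(v, members) is Status.WELL_SPECIFIED) == valid
    return v


def _draw_ontology_term(rng: random.Random, valid: bool, ontology: str, index: LocalTermIndex) -> str:
    if valid:
        if ontology == ANY_ONTOLOGY:
            onto = rng.choice(sorted(index.ontologies))
        else:
            onto = ontology
        keys = index.keys_by_ontology[onto]
        v = _case_variant(rng, rng.choice(keys))
        assert index.resolve(v, ontology)
    else:
        candidates = [c for c in _INVALID_ONTOLOGY if not index.resolve(c, ontology)]
        v = rng.choice(candidates) if candidates else "zzz_no_such_term_zzz"
        assert not index.resolve(v, ontology)
    return v


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------

def generate_corpus(
    config: CorpusConfig,
    registry: SpecRegistry | None = None,
    resolver: LocalTermIndex | None = None,
    accession_overrides: Mapping[int, str] | None = None,
) -> tuple[list[SampleRecord], GroundTruthLedger]:
    """Generate a corpus and its ground-truth ledger.

    ``registry`` defaults to the bundled profile matching
    ``config.repository``; ``resolver`` defaults to the bundled term index
    when ontology-term attributes are requested.  ``accession_overrides``
    (record index -> accession) supports planting cross-repository
    overlap.  Identical config + seed yields byte-identical serialized
    corpora.
    """
    if registry is None:
        registry = load_bundled_registry(config.repository)
    ledger = GroundTruthLedger(repository=config.repository)
    if config.n_records == 0:
        return [], ledger
    config.validate(registry)
    rng = random.Random(config.seed)

    class_counts = config.normalized_class_counts()
    checked_classes = [vc for vc in _CHECKED if vc in config.per_class_validity]
    if ValueClass.ONTOLOGY_TERM in checked_classes and resolver is None:
        resolver = bundled_term_index()

    n = config.n_records
    package_labels = _labels_from_counts(_apportion(config.package_mix, n), rng) if config.package_mix else ["Generic"] * n
    year_labels = _labels_from_counts(_apportion(config.year_histogram, n), rng) if config.year_histogram else [2015] * n

    validity_flags: dict[ValueClass, list[bool]] = {}
    for vc in checked_classes:
        total = n * class_counts[vc]
        n_valid = _round_half_up(config.per_class_validity[vc] * total)
        validity_flags[vc] = _composition_flags(n_valid, total, rng)

    n_checked_per_rec = sum(class_counts[vc] for vc in checked_classes)
    n_filler_per_rec = config.attributes_per_record - n_checked_per_rec
    n_filler_total = n * n_filler_per_rec
    n_custom = min(_round_half_up(config.custom_name_rate * n * config.attributes_per_record), n_filler_total)
    custom_flags = _composition_flags(n_custom, n_filler_total, rng)

    # URI planting over ontology-term attribute occurrences
    uri_labels: list[str | None] = []
    if config.uri_pool and ValueClass.ONTOLOGY_TERM in class_counts:
        n_onto = n * class_counts[ValueClass.ONTOLOGY_TERM]
        counts = _apportion(config.uri_pool, n_onto)
        uri_labels = _labels_from_counts(counts, rng)

    class_names = {vc: registry.names_by_class(vc) for vc in checked_classes}
    unchecked_names = registry.names_by_class(ValueClass.UNCHECKED)
    value_draws = 0  # running index into per-class validity flags
    class_cursor = {vc: 0 for vc in checked_classes}
    onto_cursor = 0
    filler_cursor = 0

    prefix = "SAMN" if config.repository is Repository.NCBI else "SAMEA"
    records: list[SampleRecord] = []
    for i in range(n):
        accession = (accession_overrides or {}).get(i, f"{prefix}{i + 1:08d}")
        year = year_labels[i]
        pkg_label = package_labels[i]
        month, day = rng.randint(1, 12), rng.randint(1, 28)
        sub_date = f"{year}-{month:02d}-{day:02d}"
        taxid, orgname = rng.choice(_ORGANISMS)
        rec = SampleRecord(
            accession=accession,
            repository=config.repository,
            record_id=str(i + 1),
            title=f"Sample {i + 1}",
            submission_date=sub_date,
            publication_date=sub_date,
            last_update_date=sub_date,
            owner=_OWNERS[i % len(_OWNERS)],
        )
        ledger.record_packages[accession] = pkg_label
        ledger.record_years[accession] = int(year)

        attrs: list[tuple[Attribute, AttributeTruth]] = []

        if config.repository is Repository.NCBI:
            rec.organism_name, rec.organism_taxon_id = orgname, taxid
            if pkg_label != "Generic":
                rec.package = pkg_label
        elif pkg_label != "Unpackaged":
            a = Attribute("package", pkg_label)
            attrs.append((a, AttributeTruth(accession, a.name, a.value, None, None, is_custom=registry.lookup(a.name) is None)))

        for vc in checked_classes:
            for _ in range(class_counts[vc]):
                names = class_names[vc]
                name = names[class_cursor[vc] % len(names)]
                class_cursor[vc] += 1
                valid = validity_flags[vc].pop()
                spec = registry.lookup(name)
                assert spec is not None
                if vc is ValueClass.BOOLEAN:
                    value = _draw_boolean(rng, valid)
                elif vc is ValueClass.INTEGER:
                    value = _draw_integer(rng, valid)
                elif vc is ValueClass.TIMESTAMP:
                    value = _draw_timestamp(rng, valid)
                elif vc is ValueClass.VALUE_SET:
                    assert spec.value_set is not None
                    value = _draw_value_set(rng, valid, spec.value_set)
                else:
                    assert resolver is not None and spec.ontology is not None
                    value = _draw_ontology_term(rng, valid, spec.ontology, resolver)
                a = Attribute(name, value)
                if vc is ValueClass.ONTOLOGY_TERM and uri_labels:
                    uri = uri_labels[onto_cursor]
                    onto_cursor += 1
                    if uri is not None:
                        a.term_source_ref = uri
                        ledger.planted_uris[uri] += 1
                        if spec.ontology == "NCBITAXON":
                            hits = resolver.resolve(value, "NCBITAXON") if resolver else set()
                            if hits:
                                a.term_source_id = sorted(hits)[0]
                attrs.append((a, AttributeTruth(accession, name, value, vc, valid, is_custom=False)))

        for _ in range(n_filler_per_rec):
            custom = custom_flags[filler_cursor]
            filler_cursor += 1
            value = f"free text {rng.randrange(100000)}"
            if custom:
                source = rng.choice(unchecked_names) if unchecked_names else rng.choice(_PLAIN_CUSTOM_POOL)
                variant = _perturb(rng, source, config.typo_model)
                tries = 0
                while registry.lookup(variant) is not None and tries < 10:
                    variant = _perturb(rng, source, config.typo_model)
                    tries += 1
                if registry.lookup(variant) is not None:
                    variant = source + "_custom_variant"
                a = Attribute(variant, value)
                attrs.append((a, AttributeTruth(accession, variant, value, None, None, is_custom=True, source_name=source)))
            elif unchecked_names:
                name = rng.choice(unchecked_names)
                a = Attribute(name, value)
                attrs.append((a, AttributeTruth(accession, name, value, ValueClass.UNCHECKED, None, is_custom=False)))
            else:
                name = rng.choice(_PLAIN_CUSTOM_POOL)
                a = Attribute(name, value)
                attrs.append((a, AttributeTruth(accession, name, value, None, None, is_custom=True)))

        rng.shuffle(attrs)
        if config.repository is Repository.EBI:
            # the tab-delimited dialect is columnar and canonicalizes
            # cross-name attribute order; store name-sorted so that
            # serialization round trips field-identically
            attrs.sort(key=lambda pair: pair[0].name)
        rec.attributes = [a for a, _ in attrs]
        ledger.attributes.extend(t for _, t in attrs)
        if config.repository is Repository.EBI:
            for a in rec.attributes:
                if a.name == "Organism":
                    rec.organism_name = a.value
                    if a.term_source_id is not None:
                        rec.organism_taxon_id = a.term_source_id
                    break
        records.append(rec)
    return records, ledger


def generate_paired_corpora(
    ncbi_config: CorpusConfig,
    ebi_config: CorpusConfig,
    overlap_fraction: float = 0.3,
    seed: int = 0,
) -> tuple[list[SampleRecord], GroundTruthLedger, list[SampleRecord], GroundTruthLedger]:
    """Generate an NCBI/EBI corpus pair with a planted accession overlap.

    Exactly ``round(overlap_fraction * min(n_ncbi, n_ebi))`` EBI records
    reuse NCBI accessions; both ledgers record the shared set.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ConfigError(f"overlap_fraction must be in [0,1], got {overlap_fraction}")
    ncbi_records, ncbi_ledger = generate_corpus(replace(ncbi_config, repository=Repository.NCBI))
    rng = random.Random(seed)
    m = _round_half_up(overlap_fraction * min(ncbi_config.n_records, ebi_config.n_records))
    shared_sources = rng.sample([r.accession for r in ncbi_records], m) if m else []
    target_idx = rng.sample(range(ebi_config.n_records), m) if m else []
    overrides = dict(zip(target_idx, shared_sources))
    ebi_records, ebi_ledger = generate_corpus(
        replace(ebi_config, repository=Repository.EBI), accession_overrides=overrides
    )
    ncbi_ledger.shared_accessions = set(shared_sources)
    ebi_ledger.shared_accessions = set(shared_sources)
    return ncbi_records, ncbi_ledger, ebi_records, ebi_ledger
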