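"""Registry of attribute specifications: the dictionary of attribute names.

Each repository documents, for some attribute names, what a valid value
looks like.  This module loads those expectations from a declarative YAML
profile into a :class:`SpecRegistry`: a mapping from canonical attribute
name to a typed :class:`AttributeSpec` (boolean, integer, timestamp,
value-set, ontology-term, or unchecked), plus the package definitions that
group attributes into sample types.

Two profiles ship with the package:

* ``ncbi_profile.yaml`` -- the NCBI BioSample dictionary shape: 452 names,
  of which 4 are boolean, 4 integer, 11 timestamp, 32 value-set and 9
  ontology-term; the remainder carry no machine-checkable value contract.
  The documented members (e.g. *smoker*, *medication code*, *host taxonomy
  ID*, *collection_date*, *sex*, *dominant hand*, *disease* -> DOID,
  *phenotype* -> PATO) are encoded directly; the rest of the membership is
  a synthetic reconstruction (see the file header).
* ``ebi_profile.yaml`` -- the three EBI named attributes: Organism
  (ontology-term, NCBI Taxonomy), Material (ontology-term, any indexed
  ontology) and Sex (value-set, the NCBI sex value set).

Name lookup trims surrounding whitespace and is case-sensitive: the name
censuses treat case variants as syntactically distinct, so ``Sex`` is a
custom name even though ``sex`` is in the dictionary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import IO, Mapping

import yaml

from .records_io import Repository

__all__ = [
    "ValueClass",
    "AttributeSpec",
    "PackageSpec",
    "SpecRegistry",
    "SchemaError",
    "ANY_ONTOLOGY",
    "load_registry",
    "bundled_profile_path",
    "lookup_spec",
    "classify_name",
]

#: Sentinel ontology binding meaning "a term in any indexed ontology".
ANY_ONTOLOGY = "ANY"


class ValueClass(str, Enum):
    """The machine-checkable value contract of an attribute."""

    BOOLEAN = "boolean"
    INTEGER = "integer"
    TIMESTAMP = "timestamp"
    VALUE_SET = "value_set"
    ONTOLOGY_TERM = "ontology_term"
    UNCHECKED = "unchecked"


class SchemaError(ValueError):
    """A profile file violates the spec-file schema; message names the field path."""


@dataclass(frozen=True)
class AttributeSpec:
    canonical_name: str
    value_class: ValueClass
    harmonized_name: str | None = None
    value_set: frozenset[str] | None = None
    ontology: str | None = None

    def __post_init__(self) -> None:
        if self.value_class is ValueClass.VALUE_SET and not self.value_set:
            raise SchemaError(f"attribute {self.canonical_name!r}: value_set class requires a non-empty value set")
        if self.value_class is ValueClass.ONTOLOGY_TERM and not self.ontology:
            raise SchemaError(f"attribute {self.canonical_name!r}: ontology_term class requires an ontology binding")


@dataclass(frozen=True)
class PackageSpec:
    name: str
    required_attributes: frozenset[str] = frozenset()
    optional_attributes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        overlap = self.required_attributes & self.optional_attributes
        if overlap:
            raise SchemaError(f"package {self.name!r}: attributes both required and optional: {sorted(overlap)}")


@dataclass
class SpecRegistry:
    """All attribute and package specifications for one repository profile."""

    specs: dict[str, AttributeSpec]
    packages: dict[str, PackageSpec]
    repository_profile: Repository
    _index: dict[str, AttributeSpec] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self._index = {}
        for spec in self.specs.values():
            self._index[spec.canonical_name] = spec
            if spec.harmonized_name:
                self._index.setdefault(spec.harmonized_name, spec)

    def lookup(self, name: str) -> AttributeSpec | None:
        """Exact (case-sensitive) lookup after surrounding-whitespace trim."""
        return self._index.get(name.strip())

    def classify(self, name: str) -> str:
        """``"dictionary"`` iff the name resolves to a spec, else ``"custom"``."""
        return "dictionary" if self.lookup(name) is not None else "custom"

    def names_by_class(self, value_class: ValueClass) -> list[str]:
        return [s.canonical_name for s in self.specs.values() if s.value_class is value_class]


def _schema_error(path: str, msg: str) -> SchemaError:
    return SchemaError(f"{path}: {msg}")


def load_registry(source: str | Path | IO[str]) -> SpecRegistry:
    """Load a :class:`SpecRegistry` from a YAML profile file.

    The profile has sections ``profile`` (NCBI or EBI), ``value_sets``
    (name -> list of members), ``attributes`` (list of entries; a plain
    string is shorthand for an unchecked attribute) and ``packages``.
    Loading is deterministic and idempotent; schema violations raise
    :class:`SchemaError` naming the offending field.
    """
    if hasattr(source, "read"):
        doc = yaml.safe_load(source)  # type: ignore[arg-type]
    else:
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise _schema_error("<root>", "profile document must be a mapping")
    try:
        profile = Repository(doc.get("profile"))
    except ValueError:
        raise _schema_error("profile", f"must be NCBI or EBI, got {doc.get('profile')!r}") from None

    value_sets_raw = doc.get("value_sets") or {}
    if not isinstance(value_sets_raw, Mapping):
        raise _schema_error("value_sets", "must be a mapping")
    value_sets: dict[str, frozenset[str]] = {}
    for vs_name, members in value_sets_raw.items():
        if not isinstance(members, list) or not members:
            raise _schema_error(f"value_sets.{vs_name}", "must be a non-empty list")
        value_sets[vs_name] = frozenset(str(m) for m in members)

    entries = doc.get("attributes")
    if not isinstance(entries, list) or not entries:
        raise _schema_error("attributes", "must be a non-empty list")
    specs: dict[str, AttributeSpec] = {}
    for i, entry in enumerate(entries):
        path = f"attributes[{i}]"
        if isinstance(entry, str):
            entry = {"name": entry}
        if not isinstance(entry, Mapping):
            raise _schema_error(path, "must be a mapping or a name string")
        name = entry.get("name")
        if not isinstance(name, str) or not name.strip():
            raise _schema_error(f"{path}.name", "must be a non-empty string")
        if name in specs:
            raise _schema_error(f"{path}.name", f"duplicate canonical name {name!r}")
        cls_raw = entry.get("class", "unchecked")
        try:
            value_class = ValueClass(cls_raw)
        except ValueError:
            raise _schema_error(f"{path}.class", f"unknown value class {cls_raw!r}") from None
        value_set = None
        if value_class is ValueClass.VALUE_SET:
            vs_key = entry.get("value_set")
            if vs_key not in value_sets:
                raise _schema_error(f"{path}.value_set", f"references undefined value set {vs_key!r}")
            value_set = value_sets[vs_key]
        ontology = None
        if value_class is ValueClass.ONTOLOGY_TERM:
            ontology = entry.get("ontology")
            if not isinstance(ontology, str) or not ontology:
                raise _schema_error(f"{path}.ontology", "ontology_term class requires an ontology acronym")
        specs[name] = AttributeSpec(
            canonical_name=name,
            value_class=value_class,
            harmonized_name=entry.get("harmonized_name"),
            value_set=value_set,
            ontology=ontology,
        )

    packages: dict[str, PackageSpec] = {}
    for i, entry in enumerate(doc.get("packages") or []):
        path = f"packages[{i}]"
        if not isinstance(entry, Mapping) or "name" not in entry:
            raise _schema_error(path, "must be a mapping with a name")
        pname = str(entry["name"])
        if pname in packages:
            raise _schema_error(f"{path}.name", f"duplicate package name {pname!r}")
        packages[pname] = PackageSpec(
            name=pname,
            required_attributes=frozenset(entry.get("required") or []),
            optional_attributes=frozenset(entry.get("optional") or []),
        )
    return SpecRegistry(specs=specs, packages=packages, repository_profile=profile)


def bundled_profile_path(profile: Repository | str) -> Path:
    """Path of a profile shipped with the package (``NCBI`` or ``EBI``)."""
    name = Repository(profile).value.lower()
    return Path(str(resources.files("metaqc").joinpath(f"data/{name}_profile.yaml")))


def load_bundled_registry(profile: Repository | str) -> SpecRegistry:
    return load_registry(bundled_profile_path(profile))


def lookup_spec(registry: SpecRegistry, name: str) -> AttributeSpec | None:
    """Functional form of :meth:`SpecRegistry.lookup`."""
    return registry.lookup(name)


def classify_name(registry: SpecRegistry, name: str) -> str:
    """Functional form of :meth:`SpecRegistry.classify`."""
    return registry.classify(name)
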