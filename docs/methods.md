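# Methods

## Record model and dialects

Both repositories are mapped onto one record model: accession, repository,
raw date strings (publication, last-update, submission), organism name and
taxon id, owner, package, and an ordered list of attributes (name, value,
optional term-source REF/ID). Two deliberate choices:

* **Verbatim names and values.** Nothing is trimmed or case-normalized at
  parse time, because the name census counts *syntactically* unique names;
  normalization is applied where each report defines it (surrounding-
  whitespace trim for name lookup, casefold for value-set and term
  matching).
* **Raw dates.** Submission dates in the wild are frequently malformed, so
  dates stay text; year extraction happens at report time, with a
  `"unknown"` bucket for unparseable values.

The NCBI XML parser is streaming (`lxml.iterparse`, elements cleared after
use), so peak memory is per-record, not per-corpus; the test suite parses
a 100,000-record file under a 50 MB ceiling. Records lacking an accession
are collected in a parse log and skipped; parsing continues. Duplicate
accessions are surfaced (`find_duplicate_accessions`) rather than
deduplicated — the repositories intend accessions to be unique, and policy
is left to the caller.

The SampleTab dialect models only the SCD section; MSI is skipped with a
log line. `Characteristic[x]` columns and the three named-attribute
columns become attributes; a `Term Source REF`/`Term Source ID` column
pair attaches to the attribute column immediately preceding it. Because
SCD is columnar, three representational limits are made explicit instead
of silently corrupting data:

* record-level fields (accession, title, owner, dates) are carried in
  reserved columns (`Sample Accession`, `Owner`, `Submission Date`, …)
  emitted only when non-empty; plain SampleTab files parse unchanged;
* an empty SCD cell means "attribute absent", so an attribute with an
  empty value cannot be represented — the writer raises; likewise for
  tabs/newlines in names or values and for attribute names that collide
  with the reserved column vocabulary;
* a shared column layout cannot preserve arbitrary *cross-name* attribute
  order per record. The writer lays attribute columns out name-sorted;
  per-name occurrence order and the attribute multiset are always
  preserved, and `parse(serialize(R)) == R` holds field-identically
  whenever each record's attributes are name-sorted (the synthetic
  generator stores EBI-profile records that way).

## Specification registry

Attribute specifications load from declarative YAML profiles into a
registry: canonical name → value class (boolean / integer / timestamp /
value-set / ontology-term / unchecked), with shared value sets and
ontology bindings, plus package definitions (required/optional attribute
sets; the Generic package has none). Name lookup trims surrounding
whitespace and is **case-sensitive** — `Sex` is a custom name even though
`sex` is in the dictionary — matching how the census treats case variants
as distinct; a case-insensitive policy would belong in the registry, not
the census.

The NCBI profile has 452 names: 4 boolean, 4 integer, 11 timestamp, 32
value-set, 9 ontology-term, 392 with no machine-checkable contract. The
published documentation enumerates only some members of the typed groups
(smoker; medication code; host taxonomy ID; collection_date; sex; dominant
hand; disease → DOID; phenotype → PATO; the Human.1.0 required set), and
those are encoded directly; the rest of the membership is a plausible
reconstruction, clearly labelled as such in the file header. The profile
is data, not code — correcting a group member requires no code change.
The EBI profile is the three named attributes: Organism (ontology-term,
NCBI Taxonomy), Material (ontology-term, any indexed ontology), Sex
(value-set). Sex has no documented range on the EBI side, so the NCBI sex
value set is used, keeping the repositories comparable.

## Validation

* **Boolean** — trimmed, lowercased value ∈ {true, false}.
* **Integer** — `[+-]?[0-9]+` (ASCII only): no thousands separators,
  floats, scientific notation, or non-ASCII digits. "Parses as an
  integer" is read strictly.
* **Timestamp** — pattern-level grammar: `D-Mmm-YYYY` (1–2 digit day
  1–31, English 3-letter month, 4-digit year), `Mmm-YYYY`, `YYYY`,
  `YYYY-mm` (01–12), `YYYY-mm-dd` (01–31), `YYYY-mm-ddThh:mm:ss`
  (hh 00–23, mm/ss 00–59). Month abbreviations match case-insensitively;
  no timezone designators; no calendar check (31-Feb passes the pattern)
  and no semantic year range. These are format checks, not date
  semantics, and each choice is localized in one compiled regular
  expression.
* **Value set** — trimmed value equals a member ignoring letter case
  (casefold); interior characters must match exactly, so `mal e` fails.
  An empty value set is a contract violation, not an invalid value.
* **Ontology term** — the trimmed value must exact-match a term in the
  designated ontology over preferred labels, synonyms and term
  identifiers, case-insensitively. The resolver is an interface; the
  shipped implementation is a local tab-delimited index (ontology,
  term id, label, pipe-separated synonyms). A remote exact-search service
  can stand behind the same contract, but resolution results from live
  terminology services drift over time, so the test suite pins everything
  to the local index. A resolver *failure* yields `untested` with reason
  `resolver_error` — never silently `invalid`.

Whitespace-only values are invalid (not untested): the attribute was
asserted but carries no usable value. Attributes with no spec or an
unchecked class are `untested`; every verdict carries a reason code.

## Reports

Per-class summaries count attributes and records; a record is "all valid"
for a class when every attribute of that class on it is well-specified
(both attribute-level and record-level counts are reported, since both
are informative and differ). Untested verdicts never enter totals, so
well-specified + invalid = total holds by construction. Percentages are
kept as floats and rounded to integers only for display. An optional
accession filter supports subset analyses (packaged records only;
accessions shared between repositories).

Report-time package labels: NCBI records without a package element belong
to the undocumented Generic package; EBI records are "Unpackaged" unless
they carry a `package` attribute. The term-source URI audit is purely
syntactic (scheme followed by `://`); URIs differing by a trailing slash
are distinct entries, deliberately. Concept groups (curated lists of
names describing the same aspect of a sample) and the top-name category
table are editable TSV fixtures, not code.

## Name clustering

Similarity is negated Levenshtein distance, computed with edlib (a C
alignment library) and a plain dynamic-programming fallback for alphabets
beyond edlib's 256-symbol limit; the test suite checks the implementation
against the textbook recursive definition. Clustering is scikit-learn
affinity propagation on the precomputed similarity matrix with damping
0.5, max 1000 iterations, convergence window 15, and a seeded
`random_state` so identical inputs give identical clusterings. The
preference defaults to the **median off-diagonal** similarity: including
the zero diagonal (as the library default does) inflates the preference
and biases toward singleton clusters, splitting obvious variant groups.
Distances are computed on raw, case-sensitive strings — unit-cost edits
already group case variants — with an opt-in casefold mode. On
non-convergence the names are returned as singleton clusters with a
`converged=False` flag rather than raising. The similarity matrix is
dense, so clustering the full tens-of-thousands name universe of a real
snapshot is a cluster-scale job; desk-scale runs use a frequency
threshold or a name subset.

## Synthetic corpora

The generator emulates the statistical structure of a snapshot: a package
mix (default 85% Generic for the NCBI profile), a rising 2009–2017
submission-year histogram, 12 attributes per record, a custom-name rate
of 15% of attribute occurrences, and per-class validity fractions
(boolean 27%, integer 74%, timestamp 74%, value set 92%, ontology term
32% for the NCBI profile; Organism 87%, Sex 90% for the EBI profile) —
the quality profile of a curated 2017 snapshot, so that passing tests
demonstrate recovery of realistic, not convenient, conditions.

All fractions become integer counts before any drawing: largest-remainder
apportionment for distributions, round-half-up for validity counts, and
shuffled assignment lists for placement. Acceptance is therefore equality
against the ledger, not a statistical tolerance. The ledger records, for
every generated attribute occurrence, its intended class, intended
validity, and (for custom names) the dictionary name it was perturbed
from; every generated attribute appears in the ledger exactly once, and
the ledger answers every report's expected value.

Invalid values are drawn from class-aware pools modeled on the kinds of
entries observed in real records, and every draw — valid or invalid — is
re-checked against the actual validators at generation time, so ledger
correctness does not depend on the pools staying in sync with the
grammars. Custom names are fabricated by `perturb_name`: a configured
number of single-character edits and/or one decoration affix
(`_kg`, ` (kg)`, …), with the edit-distance bound
`lev(name, variant) ≤ edit_rate + longest decoration` guaranteed; variants
are rejected and redrawn if they collide with a dictionary name.

What the generator does **not** emulate: real organism taxonomies,
biologically plausible value co-occurrence, free-text descriptions, or
the long-tailed name-frequency distributions of real snapshots. Tests
passing on synthetic corpora demonstrate that the pipeline measures what
is planted, exactly; they do not certify parser robustness against the
full messiness of real dumps (encoding quirks, vendor-specific XML
extensions), which the recoverable-error paths only partially cover.

## Problem sizes and numerical choices

The default test and acceptance runs use a 10,000-record corpus
(120,000 attributes), a 100,000-record streaming-parse check, 10⁴-string
grammar-oracle and 10⁴-triple metric checks, and clustering up to 500
names — sizes chosen so the full suite runs in well under a minute while
every check remains exact rather than sampled where exactness is the
point (exhaustive edit-distance oracle agreement covers all pairs of
strings up to length 4 over a three-letter alphabet, plus 10⁴ seeded
longer pairs). Ties in name ranking break lexicographically; apportion
ties break by insertion order; all randomness flows from a single integer
seed per corpus or clustering run.

## Known limitations

* Ontology-term validity is only as good as the term index; the bundled
  index is a small hand-assembled excerpt suitable for tests and
  synthetic corpora, not an ontology release.
* The NCBI profile's typed-group membership beyond the documented members
  is reconstructed, so absolute dictionary-vs-custom counts on *real*
  snapshots depend on replacing it with the upstream dictionary export.
* Edit-distance clustering is semantics-blind: `mass` and `weight` will
  never co-cluster. Exemplars are parameter-sensitive; cluster counts on
  real name sets should be read as indicative, not canonical.
* The EBI dialect writer materializes the corpus to lay out columns; the
  XML writer streams. Very wide synthetic corpora (many unique custom
  names) produce very wide SCD tables.
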