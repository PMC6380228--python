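"""Aggregation reports: summaries, censuses, distributions, intersections."""

import pytest

from metaqc import (
    Attribute,
    CorpusConfig,
    Repository,
    SampleRecord,
    ValueClass,
    attribute_name_census,
    bundled_concept_groups,
    concept_record_counts,
    generate_corpus,
    generate_paired_corpora,
    intersect_repositories,
    package_distribution,
    submissions_per_year,
    summarize_by_type,
    term_source_uri_census,
    validate_corpus,
)
from metaqc.quality_report import categorize_top_names, bundled_name_categories
from metaqc.validators import Status, ValidationResult


def _result(vc, ok, acc="SAMN1"):
    return ValidationResult(acc, "x", "v", vc, Status.WELL_SPECIFIED if ok else Status.INVALID)


def _record(acc, names, repository=Repository.NCBI, **kw):
    return SampleRecord(accession=acc, repository=repository,
                        attributes=[Attribute(n, "v") for n in names], **kw)


class TestSummarizeByType:
    def test_four_boolean_results_three_valid_is_75_percent(self):
        results = [_result(ValueClass.BOOLEAN, ok, acc=f"A{i}") for i, ok in enumerate([True, True, True, False])]
        s = summarize_by_type(results)[ValueClass.BOOLEAN]
        assert (s.attributes_total, s.attributes_well_specified) == (4, 3)
        assert s.percent_well_specified == 75.0 and s.percent_display == 75
        assert s.records_with_class == 4 and s.records_all_valid == 3

    def test_empty_results_have_zero_counts_and_no_percentage(self):
        for s in summarize_by_type([]).values():
            assert s.attributes_total == 0 and s.percent_well_specified is None

    def test_untested_results_never_enter_counts(self):
        results = [ValidationResult("A", "x", "v", ValueClass.UNCHECKED, Status.UNTESTED, "unchecked_class"),
                   ValidationResult("A", "y", "v", None, Status.UNTESTED, "no_spec")]
        assert all(s.attributes_total == 0 for s in summarize_by_type(results).values())

    def test_record_level_all_valid_semantics(self):
        # one record with a valid and an invalid boolean: counted once, not all-valid
        results = [_result(ValueClass.BOOLEAN, True), _result(ValueClass.BOOLEAN, False)]
        s = summarize_by_type(results)[ValueClass.BOOLEAN]
        assert s.records_with_class == 1 and s.records_all_valid == 0

    def test_trivial_filter_equals_unfiltered(self, small_ncbi_corpus, ncbi_registry, term_index):
        records, _ = small_ncbi_corpus
        results = list(validate_corpus(records, ncbi_registry, term_index))
        assert summarize_by_type(results, lambda acc: True) == summarize_by_type(results)

    def test_accession_subset_filter(self):
        results = [_result(ValueClass.INTEGER, True, "A"), _result(ValueClass.INTEGER, False, "B")]
        s = summarize_by_type(results, {"A"})[ValueClass.INTEGER]
        assert (s.attributes_total, s.attributes_well_specified) == (1, 1)

    def test_conservation_well_plus_invalid_is_total(self, small_ncbi_corpus, ncbi_registry, term_index):
        records, _ = small_ncbi_corpus
        results = list(validate_corpus(records, ncbi_registry, term_index))
        for s in summarize_by_type(results).values():
            assert s.attributes_well_specified + s.attributes_invalid == s.attributes_total


class TestPackageDistribution:
    def test_all_generic(self):
        records = [_record(f"A{i}", []) for i in range(4)]
        assert package_distribution(records) == {"Generic": (4, 100.0)}

    def test_counts_sum_to_corpus_size(self, small_ncbi_corpus):
        records, ledger = small_ncbi_corpus
        dist = package_distribution(records)
        assert sum(n for n, _ in dist.values()) == len(records)
        assert {k: n for k, (n, _) in dist.items()} == ledger.expected_package_distribution()

    def test_ebi_package_attribute_marks_packaged_records(self):
        records = [
            _record("E1", [], repository=Repository.EBI),
            SampleRecord(accession="E2", repository=Repository.EBI,
                         attributes=[Attribute("package", "Generic")]),
        ]
        dist = package_distribution(records)
        assert dist["Unpackaged"] == (1, 50.0) and dist["Generic"] == (1, 50.0)


class TestSubmissionsPerYear:
    def test_single_year_and_unknown_bucket(self):
        records = [_record("A1", [], submission_date="2015-01-02"),
                   _record("A2", [], submission_date="2015-06-30"),
                   _record("A3", [], submission_date="not a date")]
        assert submissions_per_year(records) == {"2015": 2, "unknown": 1}

    def test_planted_year_histogram_is_recovered_exactly(self, small_ncbi_corpus):
        records, ledger = small_ncbi_corpus
        assert submissions_per_year(records) == ledger.expected_year_histogram()

    def test_generic_split(self):
        records = [_record("A1", [], submission_date="2014-01-01"),
                   _record("A2", [], submission_date="2014-01-01", package="Human.1.0")]
        split = submissions_per_year(records, split_generic=True)
        assert split == {"2014": {"Generic": 1, "non-Generic": 1}}


class TestCensus:
    def test_dictionary_only_corpus_has_zero_custom_names(self, ncbi_registry):
        records = [_record("A1", ["sex", "strain"]), _record("A2", ["sex"])]
        census = attribute_name_census(records, ncbi_registry)
        assert census.custom_names == 0
        assert census.unique_names == census.dictionary_names_used == 2
        assert census.total_attributes == 3
        assert census.mean_attributes_per_record == 1.5

    def test_planted_typo_variants_are_counted_as_custom(self, ncbi_registry):
        records = [_record("A1", ["sex", "Altitude (m)", "weight_kg"])]
        census = attribute_name_census(records, ncbi_registry)
        assert census.custom_names == 2
        assert census.attributes_using_custom_names == 2
        assert census.records_touched_by_custom_names == 1

    def test_census_matches_generator_ledger_exactly(self, small_ncbi_corpus, ncbi_registry):
        records, ledger = small_ncbi_corpus
        census = attribute_name_census(records, ncbi_registry)
        assert census.__dict__ == ledger.expected_census()

    def test_union_unique_names_is_monotone(self, ncbi_registry):
        part1 = [_record("A1", ["sex", "foo"])]
        part2 = [_record("B1", ["bar"])]
        u = attribute_name_census(part1 + part2, ncbi_registry).unique_names
        assert u >= max(attribute_name_census(p, ncbi_registry).unique_names for p in (part1, part2))


class TestIntersection:
    def test_disjoint_and_identical(self):
        a = [_record("A1", ["x"]), _record("A2", ["y"])]
        b = [_record("B1", ["x"], repository=Repository.EBI)]
        rep = intersect_repositories(a, b)
        assert rep.shared_accessions == set()
        assert rep.shared_attribute_names == {"x"}
        same = intersect_repositories(a, a)
        assert same.shared_accessions == {"A1", "A2"}

    def test_planted_overlap_is_recovered_exactly(self):
        ncbi_cfg = CorpusConfig(n_records=120, seed=3)
        ebi_cfg = CorpusConfig.for_repository(Repository.EBI, n_records=80, seed=4)
        ncbi, nl, ebi, el = generate_paired_corpora(ncbi_cfg, ebi_cfg, overlap_fraction=0.25, seed=9)
        rep = intersect_repositories(ncbi, ebi)
        assert rep.shared_accessions == nl.shared_accessions == el.shared_accessions
        assert len(rep.shared_accessions) == round(0.25 * 80)


class TestTermSourceUris:
    def test_no_term_sources(self):
        assert term_source_uri_census([_record("A1", ["x"])]) == {}

    def test_malformed_and_trailing_slash_distinct(self):
        rec = SampleRecord(accession="E1", repository=Repository.EBI, attributes=[
            Attribute("Organism", "human", term_source_ref="http//example.org/ncbitaxon"),
            Attribute("Sex", "male", term_source_ref="http://example.org/efo"),
            Attribute("Material", "tissue sample", term_source_ref="http://example.org/efo/"),
        ])
        census = term_source_uri_census([rec])
        assert census["http//example.org/ncbitaxon"] == (1, "malformed")
        assert census["http://example.org/efo"] == (1, "well_formed")
        assert census["http://example.org/efo/"] == (1, "well_formed")
        assert len(census) == 3

    def test_planted_uris_match_ledger(self, small_ebi_corpus):
        records, ledger = small_ebi_corpus
        census = term_source_uri_census(records)
        assert {uri: n for uri, (n, _) in census.items()} == ledger.expected_uri_census()


class TestConceptCounts:
    def test_record_with_two_member_names_counts_once(self):
        groups = {"Age": ["age", "age_years"], "Weight": ["weight"]}
        records = [_record("A1", ["age", "age_years"]), _record("A2", ["weight", "age"])]
        assert concept_record_counts(records, groups) == {"Age": 2, "Weight": 1}

    def test_no_usage_counts_zero(self):
        assert concept_record_counts([_record("A1", ["x"])], {"Age": ["age"]}) == {"Age": 0}

    def test_overlapping_groups_warn(self):
        with pytest.warns(UserWarning, match="concept groups"):
            concept_record_counts([], {"A": ["age"], "B": ["age"]})

    def test_bundled_groups_recover_ledger_counts(self, small_ncbi_corpus):
        records, ledger = small_ncbi_corpus
        groups = bundled_concept_groups()
        assert concept_record_counts(records, groups) == ledger.expected_concept_counts(groups)


class TestTopNameCategorization:
    def test_ranked_names_join_category_fixture(self):
        categories = {"Measurement": ["age"], "Date": ["collection_date"]}
        records = [_record("A1", ["age", "collection_date", "mystery"]),
                   _record("A2", ["age"])]
        top = categorize_top_names(records, categories, top_n=3)
        assert top[0] == ("age", 2, "Measurement")
        assert ("mystery", 1, "unmapped") in top

    def test_bundled_category_fixture_loads(self):
        cats = bundled_name_categories()
        assert "Geographic location" in cats and "lat_lon" in cats["Geographic location"]
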