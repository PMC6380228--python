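"""Parsing, serialization and round-trip behavior of the two dialects."""

import io
import tracemalloc

import pytest

from metaqc import (
    Attribute,
    CorpusConfig,
    ParseError,
    ParseLog,
    Repository,
    SampleRecord,
    find_duplicate_accessions,
    generate_corpus,
    parse_ncbi_xml,
    parse_sampletab,
    serialize_records,
    write_records,
)

NCBI_ONE_RECORD = b"""<?xml version="1.0" encoding="UTF-8"?>
<BioSampleSet>
  <BioSample accession="SAMN00000001" id="1" submission_date="2015-03-02" publication_date="2015-03-05" last_update="2016-01-01">
    <Ids><Id db="BioSample" is_primary="1">SAMN00000001</Id></Ids>
    <Description>
      <Title>Liver biopsy</Title>
      <Organism taxonomy_id="9606" taxonomy_name="Homo sapiens"><OrganismName>Homo sapiens</OrganismName></Organism>
    </Description>
    <Owner><Name>Example Lab</Name></Owner>
    <Package>Human.1.0</Package>
    <Attributes>
      <Attribute attribute_name="sex">female</Attribute>
      <Attribute attribute_name="tissue">liver</Attribute>
      <Attribute attribute_name="smoker">Yes</Attribute>
    </Attributes>
  </BioSample>
</BioSampleSet>
"""

SAMPLETAB_NAMED = (
    "[MSI]\n"
    "Submission Title\tExample submission\n"
    "[SCD]\n"
    "Sample Name\tOrganism\tTerm Source REF\tTerm Source ID\n"
    "sample-1\tHomo sapiens\tNCBI Taxonomy\t9606\n"
)


class TestParseNcbiXml:
    def test_single_biosample_with_three_attributes(self):
        (rec,) = parse_ncbi_xml(io.BytesIO(NCBI_ONE_RECORD))
        assert rec.accession == "SAMN00000001"
        assert rec.repository is Repository.NCBI
        assert rec.package == "Human.1.0"
        assert rec.organism_name == "Homo sapiens"
        assert rec.organism_taxon_id == "9606"
        assert rec.owner == "Example Lab"
        assert [a.name for a in rec.attributes] == ["sex", "tissue", "smoker"]
        assert [a.value for a in rec.attributes] == ["female", "liver", "Yes"]

    def test_empty_biosampleset(self):
        assert list(parse_ncbi_xml(io.BytesIO(b"<BioSampleSet></BioSampleSet>"))) == []

    def test_malformed_xml_raises_parse_error(self):
        with pytest.raises(ParseError, match=r"line \d+"):
            list(parse_ncbi_xml(io.BytesIO(b"<BioSampleSet><BioSample>")))

    def test_missing_accession_is_collected_and_parsing_continues(self):
        xml = (
            b"<BioSampleSet>"
            b"<BioSample id='1'><Attributes/></BioSample>"
            b"<BioSample accession='SAMN1' id='2'><Attributes/></BioSample>"
            b"</BioSampleSet>"
        )
        log = ParseLog()
        recs = list(parse_ncbi_xml(io.BytesIO(xml), log=log))
        assert [r.accession for r in recs] == ["SAMN1"]
        assert len(log.errors) == 1 and "accession" in log.errors[0]

    def test_missing_package_leaves_package_unset(self):
        xml = b"<BioSampleSet><BioSample accession='SAMN1'/></BioSampleSet>"
        (rec,) = parse_ncbi_xml(io.BytesIO(xml))
        assert rec.package is None


class TestParseSampletab:
    def test_named_attribute_with_term_source(self):
        (rec,) = parse_sampletab(io.StringIO(SAMPLETAB_NAMED))
        assert rec.repository is Repository.EBI
        assert rec.accession == "sample-1"
        (attr,) = rec.attributes
        assert attr.name == "Organism"
        assert attr.value == "Homo sapiens"
        assert attr.term_source_ref == "NCBI Taxonomy"
        assert attr.term_source_id == "9606"
        assert rec.organism_name == "Homo sapiens"
        assert rec.organism_taxon_id == "9606"

    def test_msi_only_file_yields_empty_sequence_with_warning(self):
        log = ParseLog()
        recs = list(parse_sampletab(io.StringIO("[MSI]\nSubmission Title\tfoo\n"), log=log))
        assert recs == []
        assert any("SCD" in w for w in log.warnings)

    def test_characteristic_columns_become_attributes(self):
        text = "[SCD]\nSample Name\tCharacteristic[time point]\ns1\tday 3\n"
        (rec,) = parse_sampletab(io.StringIO(text))
        assert rec.attributes == [Attribute("time point", "day 3")]

    def test_duplicate_sample_names_yield_two_records_flagged(self):
        text = "[SCD]\nSample Name\tOrganism\ns1\thuman\ns1\tmouse\n"
        recs = list(parse_sampletab(io.StringIO(text)))
        assert len(recs) == 2
        assert find_duplicate_accessions(recs) == {"s1": 2}

    def test_ragged_long_row_is_skipped_with_error(self):
        text = "[SCD]\nSample Name\tOrganism\ns1\thuman\textra\tcells\ns2\tmouse\n"
        log = ParseLog()
        recs = list(parse_sampletab(io.StringIO(text), log=log))
        assert [r.accession for r in recs] == ["s2"]
        assert len(log.errors) == 1


class TestSerialization:
    def test_empty_sequence_ncbi_is_wellformed_empty_document(self):
        text = serialize_records([], Repository.NCBI)
        assert list(parse_ncbi_xml(io.BytesIO(text.encode()))) == []

    def test_one_record_ebi_has_header_and_one_row(self):
        rec = SampleRecord(accession="E1", repository=Repository.EBI,
                           attributes=[Attribute("Organism", "human"), Attribute("age unit", "year")])
        lines = serialize_records([rec], Repository.EBI).strip().splitlines()
        assert lines[0] == "[SCD]"
        assert len(lines) == 3  # marker, header, one sample row

    def test_record_without_accession_is_rejected(self):
        rec = SampleRecord(accession="", repository=Repository.NCBI)
        with pytest.raises(ValueError, match="accession"):
            serialize_records([rec], Repository.NCBI)

    @pytest.mark.parametrize("bad_attr", [
        Attribute("a\tb", "v"),                  # tab in name
        Attribute("name", "v\t1"),               # tab in value
        Attribute("name", ""),                   # unrepresentable empty value
        Attribute("Sample Name", "v"),           # reserved-column collision
    ])
    def test_ebi_dialect_rejects_unrepresentable_attributes(self, bad_attr):
        rec = SampleRecord(accession="E1", repository=Repository.EBI, attributes=[bad_attr])
        with pytest.raises(ValueError):
            serialize_records([rec], Repository.EBI)

    @pytest.mark.parametrize("repository,dialect", [
        (Repository.NCBI, Repository.NCBI),
        (Repository.EBI, Repository.EBI),
    ])
    def test_round_trip_preserves_all_fields(self, repository, dialect):
        config = CorpusConfig.for_repository(repository, n_records=60, seed=11)
        records, _ = generate_corpus(config)
        text = serialize_records(records, dialect)
        if dialect is Repository.NCBI:
            back = list(parse_ncbi_xml(io.BytesIO(text.encode())))
        else:
            back = list(parse_sampletab(io.StringIO(text)))
        assert back == records

    @pytest.mark.parametrize("dialect", [Repository.NCBI, Repository.EBI])
    def test_serialize_parse_serialize_is_byte_identical(self, dialect):
        config = CorpusConfig.for_repository(dialect, n_records=100, seed=5)
        records, _ = generate_corpus(config)
        first = serialize_records(records, dialect)
        if dialect is Repository.NCBI:
            back = list(parse_ncbi_xml(io.BytesIO(first.encode())))
        else:
            back = list(parse_sampletab(io.StringIO(first)))
        assert serialize_records(back, dialect) == first

    def test_count_conservation_through_both_dialects(self, small_ncbi_corpus):
        records, _ = small_ncbi_corpus
        ncbi_text = serialize_records(records, Repository.NCBI)
        assert sum(1 for _ in parse_ncbi_xml(io.BytesIO(ncbi_text.encode()))) == len(records)
        ebi_text = serialize_records(records, Repository.EBI)
        assert sum(1 for _ in parse_sampletab(io.StringIO(ebi_text))) == len(records)


def test_xml_streaming_memory_is_bounded(tmp_path):
    """Parsing 10^5 records lazily must not accumulate the whole corpus."""
    n = 100_000
    path = tmp_path / "big.xml"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("<BioSampleSet>\n")
        for i in range(n):
            fh.write(
                f'<BioSample accession="SAMN{i:08d}" submission_date="2015-01-01">'
                f'<Attributes><Attribute attribute_name="sex">male</Attribute></Attributes>'
                f"</BioSample>\n"
            )
        fh.write("</BioSampleSet>\n")
    tracemalloc.start()
    with open(path, "rb") as fh:
        count = sum(1 for _ in parse_ncbi_xml(fh))
    _, peak = tracemalloc.get_traced_memory()
    tracemalloc.stop()
    assert count == n
    assert peak < 50 * 1024 * 1024  # far below the ~100 MB a materialized corpus needs
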