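# EBI BioSamples named-attribute profile.
#
# The EBI repository documents only three attribute names. Organism values
# should be scientific names resolvable in the NCBI Taxonomy (carried with a
# Term Source REF/ID in SampleTab); Material values should be terms in some
# biomedical ontology; Sex has no pre-defined range in the EBI documentation,
# so the NCBI BioSample sex value set is used to keep the two repositories
# comparable.
profile: EBI
value_sets:
  sex:
    - "male"
    - "female"
    - "pooled male and female"
    - "neuter"
    - "hermaphrodite"
    - "intersex"
    - "not determined"
    - "missing"
    - "not applicable"
    - "not collected"
attributes:
  - name: "Organism"
    class: ontology_term
    ontology: NCBITAXON
  - name: "Material"
    class: ontology_term
    ontology: ANY
  - name: "Sex"
    class: value_set
    value_set: sex
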