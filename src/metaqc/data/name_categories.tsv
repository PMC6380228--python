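# Editable category fixture for top-ranked attribute names: category <TAB> attribute name.
# One row per (category, name); names missing from this file are reported as "unmapped".
Biomedical characteristic	breed
Biomedical characteristic	ethnicity
Biomedical characteristic	host
Biomedical characteristic	sample_type
Biomedical characteristic	organism
Biomedical characteristic	tissue
Biomedical characteristic	species
Biomedical characteristic	strain
Biomedical characteristic	sex
Biomedical characteristic	body site
Biomedical characteristic	cell type
Biomedical characteristic	cell_type
Biomedical characteristic	genotype
Biomedical characteristic	disease state
Biomedical characteristic	disease
Biomedical characteristic	isolate
Biomedical characteristic	isolation_source
Biomedical characteristic	phenotype
Biomedical characteristic	cultivar
Biomedical characteristic	dev_stage
Biomedical characteristic	Sex
Biomedical characteristic	Organism
Biomedical characteristic	Material
Date	collection date
Date	collection_date
Date	collection timestamp
Date	time point
Geographic location	geo_loc_name
Geographic location	geographic location
Geographic location	lat_lon
Geographic location	country
Geographic location	latitude and longitude
Geographic location	grographic location (country and/or sea)
Measurement	depth
Measurement	elevation
Measurement	elev
Measurement	age
Measurement	altitude
Measurement	host_age
Measurement	temp
Identifier	sample id
Identifier	package
Identifier	model
Identifier	gap_accession
Identifier	gap_sample_id
Identifier	bioproject_accession
Identifier	sample_name
Textual description	Sample_title
Textual description	project name
Textual description	Sample Name
Textual description	label
Textual description	title
Textual description	study name
Textual description	common name
Textual description	secondary description
Textual description	source name
Textual description	description
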