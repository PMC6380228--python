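# Local ontology term index: ontology <TAB> term_id <TAB> preferred_label <TAB> pipe-separated synonyms.
# Synthetic excerpt: a small hand-assembled slice of DOID, PATO, NCBITAXON, BTO,
# CL, CLO, ENVO, EFO and CHEBI sufficient for exact-match resolution in tests
# and synthetic corpora; it is not a dump of any ontology release.
DOID	DOID:4	disease
DOID	DOID:162	cancer	malignant neoplasm
DOID	DOID:9253	gastrointestinal stromal tumor	GIST
DOID	DOID:526	human immunodeficiency virus infectious disease	HIV|HIV infection
DOID	DOID:3907	lung squamous cell carcinoma	lung squamous carcinoma|squamous cell carcinoma of the lung
DOID	DOID:1612	breast cancer	breast carcinoma
DOID	DOID:9352	type 2 diabetes mellitus	type II diabetes mellitus
DOID	DOID:2841	asthma
DOID	DOID:10763	hypertension	high blood pressure
DOID	DOID:7148	rheumatoid arthritis
DOID	DOID:1324	lung cancer	lung neoplasm
DOID	DOID:684	hepatocellular carcinoma
PATO	PATO:0000384	male
PATO	PATO:0000383	female
PATO	PATO:0000461	normal	wild type
PATO	PATO:0000460	abnormal	deviant
PATO	PATO:0001997	decreased weight	reduced weight
PATO	PATO:0000582	increased weight
PATO	PATO:0001422	resistant to	resistant
PATO	PATO:0001178	resistance to	susceptibility loss
NCBITAXON	9606	Homo sapiens	human
NCBITAXON	10090	Mus musculus	house mouse
NCBITAXON	10116	Rattus norvegicus	Norway rat
NCBITAXON	562	Escherichia coli	E. coli
NCBITAXON	4932	Saccharomyces cerevisiae	baker's yeast
NCBITAXON	7227	Drosophila melanogaster	fruit fly
NCBITAXON	6239	Caenorhabditis elegans
NCBITAXON	7955	Danio rerio	zebrafish
NCBITAXON	9913	Bos taurus	cattle|cow
NCBITAXON	9031	Gallus gallus	chicken
NCBITAXON	3702	Arabidopsis thaliana	thale cress
NCBITAXON	11676	Human immunodeficiency virus 1	HIV-1
BTO	BTO:0000759	liver
BTO	BTO:0000142	brain
BTO	BTO:0000089	blood	whole blood
BTO	BTO:0000763	lung
BTO	BTO:0000671	kidney
BTO	BTO:0000562	heart
BTO	BTO:0001253	skin
BTO	BTO:0000887	muscle	muscular tissue
BTO	BTO:0000713	leaf
BTO	BTO:0001188	root
CL	CL:0000057	fibroblast
CL	CL:0000084	T cell	T lymphocyte
CL	CL:0000236	B cell	B lymphocyte
CL	CL:0000235	macrophage
CL	CL:0000540	neuron	nerve cell
CL	CL:0000232	erythrocyte	red blood cell
CLO	CLO:0003684	HeLa cell	HeLa
CLO	CLO:0007606	MCF-7 cell	MCF-7|MCF7
CLO	CLO:0001601	A549 cell	A549
CLO	CLO:0009001	HEK293 cell	HEK293|HEK-293
ENVO	ENVO:00000428	biome
ENVO	ENVO:01000177	grassland biome	grassland
ENVO	ENVO:00002030	aquatic biome
ENVO	ENVO:01000339	polar biome
ENVO	ENVO:00001998	soil
ENVO	ENVO:00002149	sea water	seawater
ENVO	ENVO:00002011	fresh water	freshwater
ENVO	ENVO:00002007	sediment
ENVO	ENVO:00002003	fecal material	feces|faeces
EFO	EFO:0000635	organism part
EFO	EFO:0000322	cell line
EFO	EFO:0002034	whole organism
EFO	EFO:0000565	tissue sample
CHEBI	CHEBI:16991	deoxyribonucleic acid	DNA
CHEBI	CHEBI:33697	ribonucleic acid	RNA
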