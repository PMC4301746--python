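query_class	subquery_class	query
Trait	Stress response	Salt stress
Trait	Agronomic traits	Yield
Trait	Morphological/phenotypic traits	Ear emergence
Trait	Stress response	Barley salt stress
Trait	Agronomic traits	Barley yield
Biological entity	Protein name/ID	WUS protein
Biological entity	Gene name/ID	WUS
Biological entity	Gene name/ID	WUS Arabidopsis
Taxonomy	Cultivar name	Barley Morex
Taxonomy	Geography	Barley fertile crescent
Taxonomy	Subspecies name	Hordeum vulgare spontaneum seed
Affiliation	Institute name	MIPS muenchen
Affiliation	Institute name	Barley IPK
Metabolic function	Catalytic process	Sucrose synthase
Metabolic function	Primary metabolism	Photosynthesis barley leaf
Metabolic function	Metabolic engineering	Rice phytoene synthase
Metabolic function	Secondary metabolism	GABA barley
Regulatory function	Regulation of enzyme activity	Regulation of starch synthase activity
Regulatory function	Regulation of process	WUS regulation
Regulatory function	Regulation of process	WUS meristem
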