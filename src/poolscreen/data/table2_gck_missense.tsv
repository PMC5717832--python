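gene	cdna_change	protein_change	consequence	cases	early_onset	controls	ages	polyphen2	sift	mutationtaster	cadd_scaled	prior_mody_report	population_af	dbsnp	acmg_class
GCK	c.484G>A	p.G162S	missense	1	1	0	13	probably_damaging	tolerated	disease_causing	26.5	1 family			3
GCK	c.952G>A	p.G318R	missense	1	1	0	14	possibly_damaging	deleterious	disease_causing	27.2	4 families			4
GCK	c.617C>T	p.T206M	missense	1	1	0	19	probably_damaging	deleterious	disease_causing	33	13 families			4
GCK	c.238G>A	p.G80S	missense	1	1	0	24	probably_damaging	deleterious	disease_causing	32	2 families		rs193922317	4
GCK	c.1349C>T	p.A450V	missense	1	1	0	27	probably_damaging	deleterious	disease_causing	29.7				3
GCK	c.911T>C	p.L304P	missense	1	1	0	28	probably_damaging	tolerated	disease_causing	24.6	3 families			4
GCK	c.559G>T	p.D187Y	missense	1	1	0	28	probably_damaging	deleterious	disease_causing	33	3 families			4
GCK	c.214G>A	p.G72R	missense	1	1	0	29	probably_damaging	deleterious	disease_causing	34	18 families		rs193922289	5
GCK	c.118G>A	p.E40K	missense	1	1	0	30	probably_damaging	deleterious	disease_causing	33	5 families			4
GCK	c.562G>A	p.A188T	missense	1	1	0	30	probably_damaging	deleterious	disease_causing	35	22 families	0.0001	rs751279776	4
GCK	c.640T>G	p.Y214D	missense	1	1	0	33	probably_damaging	deleterious	disease_causing	27.2				3
GCK	c.131G>A	p.G44D	missense	1	1	0	34	probably_damaging	deleterious	disease_causing	29	4 families		rs193922279	4
GCK	c.572G>A	p.R191Q	missense	1	1	0	37	probably_damaging	deleterious	disease_causing	35	9 families			4
GCK	c.787_801del	p.263_267del	inframe_deletion	1	1	0	39								4
GCK	c.544G>A	p.V182M	missense	1	0	0	41	probably_damaging	deleterious	disease_causing	34	12 families		rs587780345	5
GCK	c.706G>A	p.E236K	missense	1	0	0	42	possibly_damaging	deleterious	disease_causing	33	2 families		rs587780347	4
GCK	c.394G>A	p.D132N	missense	1	0	0	56	benign	tolerated	disease_causing	23	1 family	0.000015		3
GCK	c.757G>A	p.V253I	missense	1	0	0	61	benign	tolerated	disease_causing	18.4		0.00006	rs748964205	3
GCK	c.31G>A	p.A11T	missense	2	1	0	32;45	benign	tolerated	polymorphism	12.8		0.024	rs116093166	2
GCK	c.35A>G	p.K12R	missense	0	0	1		benign	tolerated	polymorphism	16.8		0.000015	rs777958777	3
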