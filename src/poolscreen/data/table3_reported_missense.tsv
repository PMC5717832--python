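gene	cdna_change	protein_change	consequence	cases	early_onset	controls	ages	polyphen2	sift	mutationtaster	cadd_scaled	prior_mody_report	population_af	dbsnp	acmg_class
HNF1A	c.391C>T	p.R131W	missense	1	1	0		probably_damaging	deleterious	disease_causing	31	9 families		rs137853244	5
HNF1A	c.608G>A	p.R203H	missense	2	1	0		possibly_damaging	deleterious	disease_causing	29	19 individuals		rs587780357	4
HNF1A	c.812G>A	p.R271Q	missense	1	1	0		probably_damaging	deleterious	disease_causing	34	13 individuals	0.00007	rs779184183	4
HNF1A	c.779C>T	p.T260M	missense	1	1	0		probably_damaging	deleterious	disease_causing	33	13 families			4
HNF1A	c.1340C>T	p.P447L	missense	1	1	0		probably_damaging	deleterious	disease_causing	34	11 studies		rs137853236	5
HNF1A	c.1135C>G	p.P379A	missense	1	1	0		probably_damaging	deleterious	disease_causing	25	10 studies	0.0006	rs754729248	4
HNF1A	c.815G>A	p.R272H	missense	1	0	0		probably_damaging	deleterious	disease_causing	34	20 families		rs137853238	5
HNF1A	c.1061C>T	p.T354M	missense	2	1	0		benign	tolerated	polymorphism	23	3 individuals	0.00006	rs757068809	3
HNF1A	c.1513C>A	p.H505N	missense	1	0	0		possibly_damaging	tolerated	disease_causing	26.1	3 individuals from one study	0.00017	rs577078110	4
HNF1A	c.1400C>T	p.P467L	missense	1	0	0		benign	deleterious	disease_causing	20.8	3 individuals	0.000015		3
HNF1A	c.481G>A	p.A161T	missense	0	0	1		possibly_damaging	deleterious	disease_causing	31	1 individual	0.00024	rs201095611	3
HNF1A	c.503G>A	p.R168H	missense	0	0	2		possibly_damaging	deleterious	disease_causing	32	1 individual	0.00006	rs377110124	3
HNF1A	c.403G>A	p.D135N	missense	1	1	0		possibly_damaging	deleterious	disease_causing	32	1 individual			3
HNF1A	c.1699G>A	p.V567I	missense	1	0	0		benign	tolerated	polymorphism	18.8	1 individual	0.0001		3
HNF4A	c.400C>T	p.R134W	missense	1	1	0		possibly_damaging	deleterious	disease_causing	35	5 families		rs370239205	4
HNF4A	c.406C>T	p.R136W	missense	2	0	0		possibly_damaging	deleterious	disease_causing	34	36 families	0.0001	rs137853336	5
HNF4A	c.929G>A	p.R310Q	missense	2	0	0		probably_damaging	tolerated	disease_causing	24.7	1 family with co-segregation	0.00003	rs371124358	4
ABCC8	c.886G>A	p.G296R	missense	1	1	0		benign	deleterious	disease_causing	27.1	individual with diabetes at 7 months	0.00006	rs148529020	3
ABCC8	c.1067A>G	p.Y356C	missense	1	0	0		probably_damaging	deleterious	disease_causing	26.1	early onset diabetes family	0.00005	rs59852838	4
ABCC8	c.2473C>T	p.R825W	missense	2	1	0		probably_damaging	deleterious	disease_causing	35	multiple individuals with NDM	0.00001	rs779736828	4
ABCC8	c.4136G>A	p.R1379H	missense	1	1	0		probably_damaging	deleterious	disease_causing	34	one individual with transient NDM			3
ABCC8	c.4516G>A	p.E1506K	missense	1	1	0		probably_damaging	deleterious	disease_causing	35	Finnish family		rs137852671	5
INS	c.16C>T	p.R6C	missense	1	0	0			deleterious	disease_causing	22.7	three-generation MODY family	0.00006	rs121908278	5
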