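gene	cdna_change	protein_change	consequence	cases	early_onset	controls	ages	polyphen2	sift	mutationtaster	cadd_scaled	prior_mody_report	population_af	dbsnp	acmg_class
GCK	c.871A>T	p.K291*	stopgain	1	1	0							rs193922335	5
GCK	c.1340_1368del	p.R447fs	frameshift_deletion	1	1	0								4
GCK	c.863+1G>T	p.?	splice_site	1	0	0								4
HNF1A	c.994delG	p.E332fs	frameshift_deletion	1	1	0								4
HNF1A	c.955+1G>T	p.?	splice_site	1	1	0								4
HNF1A	c.1730_1733dupACCT	p.Q579fs	frameshift_insertion	1	0	0								4
HNF1B	c.1005dupC	p.H336fs	frameshift_insertion	1	1	0	14							4
PPARG	c.465delC	p.H155fs	frameshift_deletion	1	0	0	41							4
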