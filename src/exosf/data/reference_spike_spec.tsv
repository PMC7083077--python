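chrom	pos	ref	alt	gene	consequence	assertion	evidence_codes	hgvs_c	hgvs_p	n_carriers	zygosity
17	41246531	A	AA	BRCA1	frameshift	pathogenic	PVS1,PM1,PM2,PP5,BS2	c.1016dupA	p.K339fs	1	het
13	32968825	G	A	BRCA2	canonical_splice	pathogenic	PVS1,PM2,PP3,PP5	c.9257-1G>A		1	het
7	6026469	C	T	PMS2	stop_gained	pathogenic	PVS1,PM1,PM2,PP5,BP4	c.1927C>T	p.Q643X	1	het
1	45797228	G	A	MUTYH	missense	likely_pathogenic	PS3,PM1,PP2,PP3	c.1187G>A	p.G396D	2	het
1	45797887	C	T	MUTYH	missense	pathogenic	PS3,PM2,PM3,PP3,PP5	c.884C>T	p.P295L	1	het
15	48748926	G	A	FBN1	missense	likely_pathogenic	PM1,PM2,PP2,PP3,PP5	c.5330G>A	p.C1777Y	1	het
1	156105714	AT	A	LMNA	frameshift	pathogenic	PVS1,PM1,PM2,PP5	c.959delT	p.R321fs	1	het
3	14183192	G	A	TMEM43	missense	likely_pathogenic	PM1,PM2,PP3,PP5	c.1100G>A	p.G367D	1	het
11	2869089	AC	A	KCNQ1	frameshift	pathogenic	PVS1,PM1,PM2	c.1506delC	p.G502fs	2	het
7	150644507	C	CC	KCNH2	frameshift	pathogenic	PVS1,PM2,PP5	c.3060dupC	p.S1021fs	1	het
7	150652569	C	T	KCNH2	missense	likely_pathogenic	PS3,PM2,PP2,PP3,PP5	c.23C>T	p.A8V	1	het
19	11231101	C	A	LDLR	stop_gained	pathogenic	PVS1,PM1,PM2,PP3,PP5	c.2043C>A	p.C681X	3	het
19	11240211	AG	A	LDLR	frameshift	pathogenic	PVS1,PM1,PM2,PP5	c.2412delG	p.L804fs	1	het
13	52511697	C	T	ATP7B	missense	likely_pathogenic	PS3,PM1,PM2,PP3,PP5	c.3818C>T	p.P1273L	1	het
13	52515322	C	T	ATP7B	missense	likely_pathogenic	PM1,PM2,PP3,PP5	c.3451C>T	p.R1151C	1	het
13	52509006	T	TT	ATP7B	frameshift	likely_pathogenic	PVS1,PM2	c.4283dupT	p.V1428fs	1	het
13	52531716	C	T	ATP7B	missense	likely_pathogenic	PM2,PP1,PP2,PP3,PP5	c.2383C>T	p.L795F	1	het
19	38937350	G	C	RYR1	missense	likely_pathogenic	PM1,PM2,PP2,PP3,PP5	c.742G>C	p.G248R	2	het
19	38964345	AG	A	RYR1	frameshift	pathogenic	PVS1,PM2,PP5	c.4094delG	p.G1365fs	1	het
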