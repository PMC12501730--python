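# Cohort variant table: 97 reported variant rows from a 94-patient inherited-retinal-dystrophy diagnostic panel cohort (published Table 2; transcribed verbatim, typography preserved).
patient_id	gene	cdna	protein	zygosity	dann	criteria	reported_class	inheritance
P1	ABCA4	c.3244G>T	(p.Val1082Leu)	Heterozygous	1.0	PM1PP2PM2PP3	LP	AR
P2	USH2A	c.12067–2A>G	(p.?)	Homozygous	0.99	PVS1PM2PM3PP1	P	AR
P2	ABCA4	c.5882G>A	(p.Gly1961Glu)	Heterozygous	1.0	PS3PM2PM5PP3PP2PP5	P	AR
P3	PROM1	c.2023C>T	(p.Arg675*)	Homozygous	0.98	PS4PVS1PM2	P	AR
P3	PRPF8	c.4980C>G	(p.Tyr1660*)	Heterozygous	1.0	PVS1PM2	LP	AD
P7	USH2A	c.12067–2A>G	(p.?)	Heterozygous	0.99	PVS1PM2PM3PP1	LP	AR
P7	USH2A	c.6485A>C	p.Gln2162Pro	Heterozygous		PM2PP4	LP	AR
P8	ABHD12	c.871delT	(p.Tyr291Ilefs*28)	Homozygous		PVS1PM2	LP	AR
P10	CRB1	c.2786T>C	(p.Met929Thr)	Heterozygous	0.95	PM3PM2PM5PM1PP2PP5	P	AR
P10	TTC8	c.9_10dupGG	(p.Glu4Glyfs*41)	Homozygous		PVS1PM2	LP	AR
P11	BBS1	c.479G>A	(p.Arg160Gln)	Homozygous	1.0	PM3PM2PP3PP2PP5	P	AR
P12	CYP4V2	c.414–1G>T	(p.?)	Homozygous	1.0	PVS1PM2	LP	AR
P14	CYP4V2	c.802–8_810delinsGC	(p.?)	Homozygous		PM3PVS1PM2PP5	P	AR
P15	RP1	c.269del	(p.His90Profs*26)	Homozygous		PVS1PM2PS4PP5	P	AD, AR
P16	CRB1	c.2230C>T	(p.Arg744*)	Homozygous	1.0	PVS1PM2PS4PP5	P	AR
P17	RDH12	c.295C>A	(p.Leu99Ile)	Homozygous	1.0	PM3PM2PP3PP2PS3PP1PP5	P	AD, AR
P18	CYP4V2	c.802–8_810delinsGC	(p.?)	Homozygous		PM3PVS1PM2PP5	P	AR
P19	USH2A	c.11864G>A	(p.Trp3955*)	Heterozygous	0.99	PVS1PM3PM2BS2PP5	P	AR
P19	USH2A	c.2276G>T	(p.Cys759Phe)	Heterozygous	0.99	PM3PP1PM2PS4PP3PM1PP4PP5	LP	AR
P20	MAK	c.668_671del	(p.Asp223Glyfs*11)	Homozygous		PVS1PM2PP5	P	AR
P21	RDH12	c.444C>A	(p.His148Gln)	Homozygous	0.99	PM2PM1PP3PP2PP5	LP	AD, AR
P22	ABCA4	c.5882G>A	(p.Gly1961Glu)	Heterozygous	1.0	PS3PM2PM5PP3PP2PP5	P	AR
P22	ABCA4	c.3808G>T	(p.Glu1270*)	Heterozygous	1.0	PVS1PM2PS4PP5	P	AR
P23	CYP4V2	c.1198C>T	(p.Arg400Cys)	Homozygous	0.99	PM3PM2PM5PP3PM1PS2PP5	P	AR
P24	CRB1	c.1982C>A	(p.Ala661Glu)	Homozygous	0.96	PM2PP2PP4	LP	AR
P25	GRK1	c.1610_1613del	(p.Asp537Valfs*7)	Homozygous		PM3PM2PVS1PP5	P	AR
P26	ABCA4	c.5882G>A	(p.Gly1961Glu)	Heterozygous	1.0	PS3PM2PM5PP3PP2PP5	P	AR
P26	ABCA4	c.2288C>A	(p.Ala763Asp)	Heterozygous	1.0	PS4PM2PM5PM1PP3PP2PP5	P	AR
P28	ABCA4	c.203C>T	(p.Pro68Leu)	Heterozygous	1.0	PS4PP3PM2PM5PM1PP2PP5	P	AR
P28	ABCA4	c.2966T>A	(p.Val989Asp)	Heterozygous	0.99	PM2PM5PM1PP3PP2	LP	AR
P29	ABCA4	c.3749T>C	(p.Leu1250Pro)	Homozygous	1.0	PP3PS4PM2PP2PP5	P	AR
P30	ABCA4	c.3808G>T	(p.Glu1270*)	Heterozygous	1.0	PVS1PM2PS4PP5	P	AR
P31	KCNV2	c.1356+3_1356+6del	(p.?)	Homozygous		PP3PM2PM3PP4PP5	LP	AR
P35	PAX6	c.467G>A	(p.Trp156*)	Heterozygous	1.0	PVS1PM2PS4PP5	P	AD
P36	CNGB3	c.1006G>T	(p.Glu336*)	Heterozygous	1.0	PVS1PM3PM2PP5	P	AR
P37	KCNJ13	c.500T>A	(p.Ile167Asn)	Homozygous	0.99	PP3PM2PP4	LP	AR
P38	CRB1	c.1894C>T	(p.Arg632*)	Homozygous	1.0	PVS1PM2PS4PP5	P	AR
P38	PDE6B	c.2399del	(p.Leu800Argfs*19)	Heterozygous		PVS1PM2	LP	AR
P39	PROM1	c.1090C>T	(p.Arg364Cys)	Heterozygous	0.92	PS4PM2PP5	LP	AD, AR
P40	CNGA1	c.947C>T	(p.Ser316Phe)	Homozygous	1.0	PM3PP3PM2PS3PP1PP5	P	AR
P40	POMGNT1	c.1462C>T	(p.Arg488*)	Heterozygous	1.0	PVS1PM3PM2PP5	P	AR
P41	PCARE	c.958del	(p.Arg320Alafs*3)	Homozygous		PVS1PM3PM2PP5	P	AR
P42	ABCA4	c.5315G>A	(p.Trp1772*)	Homozygous	1.0	PVS1PM2PS4PP5	P	AR
P43	TULP1	c.888T>G	(p.Asn296Lys)	Homozygous	1.0	PM3PM2PP3PM1PP5	LP	AR
P44	BBS4	c.587A>G	(p.Asp196Gly)	Homozygous	1.0	PP5PP3PM2	LP	AR
P44	USH2A	c.12569T>C	(p.Val4190Ala)	Heterozygous	1.0	PM3PM2PM1PP1PP5	LP	AR
P47	ALMS1	c.7313C>A	(p.Ser2438*)	Homozygous	1.0	PVS1PM3PM2PP1PP5	P	AR
P47	RHO	c.520G>A	(p.Gly174Ser)	Heterozygous	1.0	PP3PM2PP2	P	AD, AR
P48	USH2A	c.11156G>A	(p.Arg3719His)	Homozygous	1.0	PM3PM2PM5PP1PP5	P	AR
P48	ABCA4	c.5882G>A	(p.Gly1961Glu)	Heterozygous	1.0	PS3PM2PM5PP3PP2PP5	P	AR
P49	IFT172	c.3228+13G>A	(p.?)	Homozygous		PP4PM2BP7	LP	AR
P50	CERKL	c.316C>A	(p.Arg106Ser)	Homozygous	1.0	PM3PM2PM5PP5	P	AR
P50	PDE6B	c.1108–3C>G	(p.?)	Heterozygous		PP3PM2PP4	LP	AR
P51	RDH12	c.379G>T	p.Gly127*	Homozygous	0.99	PVS1PM3PM2PP5	P	AD, AR
P51	ABCA4	c.5882G>A	(p.Gly1961Glu)	Heterozygous	1.0	PS3PM2PM5PP3PP2PP5	P	AR
P52	USH2A	c.6127_6128dup	(p.Ser2043ArgfsTer6)	Homozygous		PVS1PM3PM2PP5	P	AR
P53	CNGB1	c.413–1G>A	(p.?)	Homozygous	0.95	PVS1PM3PM2PP5	P	AR
P55	ABCA4	c.1554+3_1554+4del	(p.?)	Homozygous		PM2PP4	LP	AR
P56	MYO7A	c.6539T>C	(p.Leu2180Pro)	Homozygous	1.0	PP4PP3PM2	LP	AR
P59	BBS7	c.849+1G>T	(p.?)	Homozygous	1.0	PVS1PM2	LP	AR
P62	CNGB3	c.1179–2A>T	(p.?)	Homozygous	0.99	PVS1PM3PM2PP5	P	AR
P62	CNGB1	c.2629G>A	(p.Gly877Arg)	Heterozygous	1.0	PP3PM3PM2PP5	P	AR
P63	USH2A	c.11156G>A	(p.Arg3719His)	Heterozygous	1.0	PM3PM2PM5PP1PP5	P	AR
P64	ALMS1	c.3154C>T	(p.Gln1052*)	Homozygous	0.99	PVS1PM2	LP	AR
P65	RS1	c.52+1G>C	(p.?)	Hemizygous	0.99	PVS1PM2	LP	XLR
P66	PRPH2	c.461_464delinsTGGTCT	(p.Lys154Metfs*103)	Homozygous		PVS1PM2PS4PP5	P	AD, AR
P67	TULP1	c.1199G>T	(p.Arg400Leu)	Homozygous	1.0	PM2PM5PM1PP3	LP	AR
P69	ABCA4	c.5172G>A	(p.Trp1724*)	Heterozygous	1.0	PVS1PM2PS4PP5	P	AR
P69	ABCA4	c.5882G>A	(p.Gly1961Glu)	Heterozygous	1.0	PS3PM2PM5PP3PP2PP5	P	AR
P70	ABCA4	c.5909T>C	(p.Leu1970Pro)	Homozygous	1.0	PS4PP3PM2PM5PM1PP2PP5	P	AR
P72	ARL6	c.276del	(p.Phe92Leufs*9)	Homozygous		PVS1PM2	LP	AR
P73	PDE6A	c.1166C>T	(p.Pro389Leu)	Homozygous	1.0	PP3PM2PP5	LP	AR
P74	BEST1	c.1013G>A	(p.Trp338*)	Homozygous	1.0	PVS1PM2PS4PP5	P	AR
P75	RHO	c.491C>T	(p.Ala164Val)	Heterozygous	1.0	PS4PM2PM5PM1PP2PP5	P	AD, AR
P75	TULP1	c.1082G>A	(p.Arg361Gln)	Heterozygous	1.0	PM2PP5PP3PM1	LP	AR
P76	RHO	c.403C>T	(p.Arg135Trp)	Heterozygous	1.0	PP1PS2PM2PM5PM1PP3PP2	P	AD, AR
P77	PRPH2	c.470A>G	(p.Asp157Gly)	Heterozygous	1.0	PS4PP3PM2PM5PM1PP2PP5	P	AD, AR
P77	BBS2	c.1015C>T	(p.Arg339*)	Heterozygous	1.0	PVS1PM3PM2PP5	P	AR
P78	USH2A	c.12574C>G	(p.Arg 4192Gly)	Homozygous	0.99	PM2PM5PM1	LP	AR
P78	ABCA4	c.3149G>A	(p.Gly1050Asp)	Heterozygous	1.0	PM3PM2PM1PP1PP5PM5	P	AR
P79	PDE6B	c.169_239dup	(p.Leu83Cysfs*91)	Homozygous		PVS1PM2PP5	P	AR
P80	MERTK	c.1744_1751delinsT	(p.Ile582*)	Homozygous		PVS1PM3PM2PP5	P	AR
P81	PROM1	c.2118G>T	(p.Gly706Gly)	Homozygous		PM2PP3PP4	LP	AR
P82	ABCA4	c.571–2A>T	(p.?)	Homozygous	0.99	PVS1PS4PM2PP5	P	AR
P83	EYS	c.1185–3C>A	(p.?)	Homozygous	N	PM2PP3	LP	AR
P84	RP1	c.109C>T	(p.Arg37*)	Homozygous	1.0	PVS1PM2	LP	AD, AR
P84	HMCN1	c.12095G>A	(p.Gly4032Asp)	Homozygous	0.99	PM2PP3	LP	AD
P85	SCLT1	c.37C>T	(p.Arg13*)	Heterozygous	1.0	PVS1PM2PP5	P	AR
P86	MYO7A	c.4793T>C	(p.Leu1598Pro)	Homozygous	1.0	PP3PM2	LP	AR
P87	LCA5	c.103C>T	(p.Arg35*)	Homozygous	1.0	PVS1PM3PM2PP5	P	AR
P88	OAT	c.748C>T	(p.Arg250*)	Homozygous	1.0	PVS1PM3PM2PP5	P	AR
P89	IMPG2	c.1491del	(p.Leu498Cysfs*15)	Homozygous		PVS1PM2PS4PP5	P	AR
P90	PDE6B	c.1935C>G	(p.Tyr645*)	Homozygous	1.0	PVS1PM2	LP	AR
P91	ABCA4	c.286A>G	(p.Asn96Asp)	Heterozygous	1.0	PM3PM2PM5PM1PP5PP3PP2	P	AR
P92	IMPDH1	c.809T>C	(p.Leu270Pro)	Homozygous	1.0	PP3PM2PM5	LP	AD
P93	LRAT	c.481T>C	(p.Cys161Arg)	Homozygous	1.0	PM2PP3PM1PM3PP5	LP	AR
P94	PDE6B	c.243del	(p.Arg82Alafs*68)	Homozygous		PVS1PM2	LP	AR
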