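# Novel-variant list: 28 previously unreported variants from the same cohort (published Table 3; transcribed verbatim).
patient_id	gene	transcript	cdna	protein	zygosity	dann	reported_class
P1	ABCA4	NM:000350.3	c.3244G>T	p.Val1082Leu	Heterozygous	0.9979	LP
P3	PRPF8	NM:006445	c.4980C>G	p.Tyr1660*	Heterozygous	0.9958	LP
P7	USH2A	NM:206933	c.6485A>C	p.Gln2162Pro	Heterozygous	0.9957	LP
P8	ABHD12	NM:001042472	c.871delT	p.Tyr291Ilefs*28	Homozygous	N/A	LP
P10	TTC8	NM:144596.4	c.9_10dupGG	p.Glu4Glyfs*41	Homozygous	N/A	LP
P12	CYP4V2	NM:207352	c.414‐1G>T	—	Homozygous	0.995	LP
P24	CRB1	NM:001193640	c.1982C>A	p.Ala661Glu	Homozygous	0.9631	LP
P28	ABCA4	NM:000350.3	c.2966T>A	p.Val989Asp	Heterozygous	0.9867	LP
P37	KCNJ13	NM:001172417	c.500T>A	p.Ile167Asn	Homozygous	0.9938	LP
P38	PDE6B	NM:000283	c.2399del	p.Leu800Argfs*19	Heterozygous	N/A	LP
P49	IFT172	NM:015662	c.3228+13G>A	—	Homozygous	N/A	LP
P50	PDE6B	NM:000283	c.1108‐3C>G	—	Heterozygous	N/A	LP
P56	MYO7A	NM:000260.4	c.6539T>C	p.Leu2180Pro	Homozygous	0.9979	LP
P59	BBS7	NM:176824.3	c.849+1G>T	—	Homozygous	0.9958	LP
P64	ALMS1	NM:001378454	c.3154C>T	p.Gln1052*	Homozygous	0.9906	LP
P65	RS1	NM:000330	c.52+1G>C	—	Hemizygous	0.9935	LP
P67	TULP1	NM:003322	c.1199G>T	p.Arg400Leu	Homozygous	0.9986	LP
P72	ARL6	NM:001278293	c.276del	p.Phe92Leufs*9	Homozygous	N/A	LP
P78	USH2A	NM:206933	c.12574C>G	p.Arg 4192Gly	Homozygous	0.9931	LP
P81	PROM1	NM:006017	c.2118G>T	p.Gly706Gly	Homozygous	N/A	LP
P83	EYS	NM:001142800	c.1185–3C>A	—	Homozygous	N/A	LP
P84	RP1	NM:006269	c.109C>T	p.Arg37*	Homozygous	0.9979	LP
P84	HMCN1	NM:031935	c.12095G>A	p.Gly4032Asp	Homozygous	0.9944	LP
P86	MYO7A	NM:000260.4	c.4793T>C	p.Leu1598Pro	Homozygous	0.9992	LP
P89	IMPG2	NM:016247	c.1491del	p.Leu498Cysfs*15	Homozygous	N/A	LP
P90	PDE6B	NM:000283	c.1935C>G	p.Tyr645*	Homozygous	0.9959	LP
P92	IMPDH1	NM_000883	c.809T>C	p.Leu270Pro	Heterozygous	0.999	LP
P94	PDE6B	NM:000283	c.243del	p.Arg82Alafs*68	Homozygous	N/A	LP
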