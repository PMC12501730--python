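# Demographics and clinical information by clinical subgroup (published Table 1; percentages as printed, one row per subgroup plus the cohort total).
group	n	age_mean	age_sd	onset_mean	onset_sd	female_pct	male_pct	consanguinity_yes_pct	consanguinity_no_pct	family_history_yes_pct	family_history_no_pct	extraocular_yes_pct	extraocular_no_pct
RP	28	34.07	16.41	16.00	11.92	53.58	46.42	82.14	17.86	53.58	46.42	25.00	75.00
LCA	10	15.70	12.42	4.60	8.13	50.00	50.00	90.00	10.00	40.00	60.00	30.00	70.00
Bietti	4	27.25	11.79	13.25	3.86	75.00	25.00	100.00	0.00	50.00	50.00	25.00	75.00
Usher	7	31.86	14.96	18.71	8.90	57.14	42.86	85.71	14.29	71.43	28.57	100.00	0.00
STARGARDT	8	19.50	10.57	12.38	4.37	62.50	37.50	62.50	37.50	62.50	37.50	14.29	85.71
BBS	4	17.25	3.30	11.75	9.77	25.00	75.00	75.00	25.00	25.00	75.00	100.00	0.00
Other	9	17.44	10.53	7.55	8.52	44.44	55.56	100.00	0.00	33.33	66.67	66.67	33.33
Undiagnosed	24	37.67	21.99	22.71	19.09	20.84	79.16	41.67	58.33	20.83	79.17	54.17	45.83
Total	94	29.03	17.98	15.29	13.74	44.68	55.32	73.40	26.60	42.55	57.45	44.68	55.32
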