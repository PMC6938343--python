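variant_id	gene	pct0	pct1	pct2	note
rs10889334	DOCK7	7.57	43.53	48.9	
rs61771778	LOC105378797	42.34	52.41	5.24	
rs2994429	SSX2IP/LPAR3	100.0	0.0	0.0	
rs10798572	LOC100506128/SEC16B	0.0	1.06	98.94	
rs943763	LOC100506128/SEC16B	50.75	35.36	13.89	
rs1052238	PTPRC	59.0	40.92	0.08	
rs568938	APOB/LOC100129278	22.79	64.53	12.68	
rs56197751	RBKS				ancestry columns not printed in source
rs6760908	RBKS	0.0	8.73	91.27	
rs12622858	NRXN1	37.62	62.38	0.0	
rs17033788	LOC102724373/LOC105374786	95.74	4.26	0.0	
rs13186242	LOC391834	53.59	46.41	0.0	
rs4958487	SPARC	62.82	37.12	0.06	column semantics inconsistent with admixed classification in source; excluded from certification
rs9349379	PHACTR1	13.3	29.44	57.26	
rs79239785	CDKAL1	100.0	0.0	0.0	
rs1728312	LOC101927890	36.41	62.61	0.98	
rs2390859	STK31/NPY	36.22	62.66	1.12	
rs2106922	JAZF1	100.0	0.0	0.0	
rs114374279	NPC1L1	0.0	4.35	95.65	
rs11983880	STX1A	80.68	19.3	0.02	
rs10974448	GLIS3	5.18	66.94	27.89	
rs2756916	GRIN3A/ARL2BPP7	99.52	0.48	0.0	
rs7923036	ADARB2	29.5	70.5	0.0	
rs787037	APBB1IP	17.56	81.95	0.49	
rs17875327	IDE	100.0	0.0	0.0	
rs942008	TLL2	100.0	0.0	0.0	
rs76394293	B7H6	0.0	44.61	55.39	
rs1939120	ARL2BPP7/SLC22A11	19.37	80.59	0.05	
rs17376366	LOC100506393/PDE3A	99.51	0.48	0.02	
rs115487129	DUSP6/POC1B	2.9	20.14	76.96	
rs7139221	CCDC63	0.0	9.98	90.02	
rs10774711	LOC100506452/LOC100506465	17.01	47.6	35.39	
rs60136502	RCCD1/PRC1	2.39	61.58	36.03	
rs11865790	ITFG1	96.58	3.42	0.0	
rs8058543	CHD9	34.84	43.71	21.46	
rs2926143	RPS15AP34/LOC729217	62.47	37.31	0.22	
rs4260044	LOC100506467/LINC00311	30.88	69.09	0.03	
rs4334353	HLF	90.23	9.69	0.08	
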