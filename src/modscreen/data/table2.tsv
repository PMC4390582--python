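# Second-chromosome mis-expression alleles called as His1 modifiers in the
# published viability screen: raw adult counts for both cross arms plus the
# NE / P columns as printed. screen_* = knockdown-driver mothers,
# control_* = driver-only mothers; ne "INF" marks a zero control Cy+ count.
allele_id	father_zygosity	screen_cy	screen_cyplus	control_cy	control_cyplus	ne	p_fet	p_bin	gene_symbol	flybase_id
EP2543-Dap160	homozygous	135	0	70	4	0.00	6.1E-08	4.3E-10	Dap160	FBgn0023388
G3075	homozygous	92	0	58	5	0.00	1.2E-07	3.0E-13	bsh	FBgn0000529
G18270	homozygous	135	0	97	6	0.00	6.1E-06	4.3E-08	phyl	FBgn0013725
G12649-gbb	heterozygous	66	0	31	24	0.00	1.2E-07	4.1E-11	gbb	FBgn0024234
G2573	homozygous	67	0	87	3	0.00	2.6E-06	2.8E-11	CG10631	FBgn0032817
G3720	homozygous	63	0	114	36	0.00	6.4E-06	1.3E-10	CG15611	FBgn0034194
G8310-slim	homozygous	81	0	56	8	0.00	5.8E-07	1.7E-09	slim	FBgn0261477
EU639-mrj	homozygous	111	0	107	2	0.00	2.8E-03	8.6E-03	mrj	FBgn0034091
EP2251-pain	homozygous	113	0	81	2	0.00	1.3E-04	2.2E-04	pain	FBgn0060296
G3660-RpS15	heterozygous	73	1	141	55	0.11	1.9E-06	1.0E-09	RpS15	FBgn0034138
G2283-CG5846	homozygous	63	2	71	76	0.16	2.5E-05	3.8E-08	CG5846	FBgn0032171
G2720-vis	homozygous	65	3	39	39	0.23	7.8E-04	1.0E-07	vis	FBgn0033748
EP2347-MESK2	homozygous	62	4	18	35	0.24	4.1E-03	1.5E-06	MESK2	FBgn0043070
G8286-CG5742	homozygous	97	3	68	31	0.25	2.0E-05	3.5E-12	CG5742	FBgn0034304
G2957	homozygous	82	4	56	42	0.28	7.1E-03	4.2E-05	hbs	FBgn0029082
G7338-Nedd8	homozygous	87	5	99	97	0.29	2.6E-07	3.3E-13	Nedd8	FBgn0032725
G2655-TBCB	heterozygous	82	4	35	19	0.30	3.5E-03	1.0E-03	TBCB	FBgn0034451
G18007-CG13751	homozygous	72	4	82	62	0.32	1.1E-03	6.6E-08	CG13751	FBgn0033340
G2736-CG8155	homozygous	105	6	92	71	0.32	2.0E-04	7.2E-11	CG8155	FBgn0034009
G18268-CG3838	homozygous	57	6	33	44	0.41	3.3E-03	9.8E-05	CG3838	FBgn0032130
G3545-Ipk2	homozygous	135	12	141	135	0.41	2.9E-07	1.7E-14	Ipk2	FBgn0031267
G5845-nopo	homozygous	59	6	48	50	0.44	3.3E-03	6.7E-05	nopo	FBgn0034314
GE10665-inv	homozygous	76	1	49	4	0.46	7.7E-06	2.6E-11	inv	FBgn0001269
EP2582-lea	homozygous	54	1	106	12	0.47	2.5E-04	7.1E-08	lea	FBgn0002543
G2920-zf30C	homozygous	64	1	68	6	0.50	4.8E-05	2.3E-09	zf30C	FBgn0022720
EP437	homozygous	71	6	65	39	0.51	6.7E-03	2.6E-06	GEFmeso	FBgn0050115
GE15547-coro	homozygous	84	13	45	64	0.52	9.2E-03	1.0E-04	coro	FBgn0265935
EP2202-spict	homozygous	94	19	37	79	0.54	9.4E-03	1.0E-03	spict	FBgn0032451
EP2424-CG12484	homozygous	99	12	77	61	0.57	2.4E-04	8.0E-15	CG12484	FBgn0086604
G2846-AGO1	homozygous	81	10	67	52	0.59	3.2E-03	1.8E-05	AGO1	FBgn0262739
EP2162-Pka-R2	homozygous	117	18	72	73	0.60	5.3E-03	3.7E-06	Pka-R2	FBgn0022382
G7969-CG3358	homozygous	71	14	35	49	0.62	9.3E-03	4.4E-03	CG3358	FBgn0033117
G2643-CG3476	homozygous	103	17	76	77	0.63	4.0E-03	1.3E-10	CG3476	FBgn0031881
EP2378-spi	heterozygous	90	10	137	59	0.63	7.9E-04	1.4E-11	spi	FBgn0005672
G3647-RtGEF	homozygous	51	9	95	105	0.63	5.3E-03	3.2E-06	RtGEF	FBgn0015803
EP1153-uzip	homozygous	113	21	67	73	0.66	8.5E-03	1.9E-08	uzip	FBgn0004055
EP2612-Arf51F	homozygous	136	22	110	91	0.68	1.5E-03	3.2E-13	Arf51F	FBgn0013750
EP2141-homer	homozygous	104	18	67	59	0.69	9.5E-03	8.8E-09	homer	FBgn0025777
EP2644-Oatp30B	homozygous	94	16	91	77	0.70	7.8E-03	3.9E-08	Oatp30B	FBgn0032123
G19340	homozygous	128	24	110	96	0.73	7.5E-03	9.9E-08	Gbp	FBgn0034199
G3678	homozygous	124	23	114	85	0.79	9.7E-03	2.6E-07	CG13220	FBgn0033608
GE13306-CG12744	homozygous	65	43	30	29	1.27	9.6E-03	4.7E-03	CG12744	FBgn0033459
G2796-stau	homozygous	101	65	69	70	1.28	2.2E-03	1.4E-03	stau	FBgn0003520
EP2537-lola	heterozygous	91	38	106	51	1.28	8.5E-03	6.3E-03	lola	FBgn0005630
G2086	homozygous	69	48	60	59	1.28	8.1E-03	2.1E-03	Spp	FBgn0031260
G6155-Sep5	homozygous	50	55	42	98	1.31	3.8E-06	1.2E-07	Sep5	FBgn0026361
EP2520	heterozygous	116	59	97	46	1.34	2.4E-03	2.4E-03	Lar	FBgn0000464
EP608-EPc	homozygous	86	55	99	109	1.34	2.5E-03	1.4E-03	E(Pc)	FBgn0000581
G3215-Thiolase	homozygous	69	56	56	55	1.35	1.1E-03	9.1E-04	Thiolase	FBgn0025352
EP2390-EDTP	homozygous	68	69	78	84	1.37	1.4E-03	2.2E-04	EDTP	FBgn0027506
G12586	homozygous	82	67	82	94	1.39	7.9E-03	6.7E-03	CG13551	FBgn0040660
G19466-CG43340	homozygous	71	63	92	88	1.40	2.9E-04	7.3E-05	CG43340	FBgn0263077
G17999-Elba2	homozygous	54	44	88	76	1.43	2.3E-03	2.0E-03	Elba2	FBgn0031435
G2762-Socs36E	homozygous	93	76	70	58	1.47	5.3E-04	1.1E-04	Socs36E	FBgn0041184
EP993	homozygous	51	44	68	57	1.48	1.3E-03	1.1E-03	CG30069	FBgn0050069
EP2515	heterozygous	67	44	98	39	1.59	5.8E-03	3.2E-03	dnr1	FBgn0260866
EP310-pAbp	homozygous	78	41	106	57	1.62	5.5E-03	2.7E-03	pAbp	FBgn0265297
GE15185-JhI21	homozygous	113	35	106	36	1.74	7.2E-03	4.9E-06	Jhl-21	FBgn0028425
G2213	homozygous	61	35	173	54	1.97	7.4E-03	3.8E-03	Chd1	FBgn0250786
EP2115-c2M	homozygous	43	52	42	21	2.15	1.3E-05	1.7E-06	c(2)M	FBgn0028525
EP578-Traf4	homozygous	84	5	91	0	INF	7.1E-04	1.1E-08	Traf4	FBgn0026319
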