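accession	symbol	protein_class	length_bp	cai_wt	cai_opt	gc_wt_pct	gc_opt_pct	codons_altered_n	codons_altered_pct	expression_ratio	expression_call
NM_001514	TFIIB	TF	948	0.77	0.97	44	62	213	67	1.18	+
NM_004379	CREB1	TF	981	0.76	0.96	47	63	213	65	2.80	+
NM_014596	ZNRD1	TF	409	0.83	0.98	54	64	69	55	3.41	+
NM_016269	Lef1	TF	1197	0.82	0.97	51	63	232	58	3.28	+
NM_006331	EMG1	RB	763	0.79	0.97	51	64	149	61	2.25	+
NM_139071	SMARCD1	RB	1305	0.82	0.98	52	62	248	57	1.85	+
NM_002648	PIM1	PK	939	0.85	0.97	59	62	137	44	1.12	+
NM_006875	PIM2	PK	933	0.82	0.97	60	65	167	54	1.28	+
NM_001001852	PIM3	PK	978	0.87	0.97	69	66	130	40	1.01	=
NM_025195	Trb1	PK	1116	0.84	0.97	61	64	200	54	1.23	+
NM_004972	JAK2	PK	3396	0.77	0.98	39	60	784	69	6.00	+
NM_002110	HCK	PK	1578	0.88	0.98	57	62	224	43	2.40	+
NM_005356	LCK	PK	1527	0.87	0.98	58	63	222	44	1.90	+
NM_002019	FLT1	PK	4014	0.80	0.98	45	60	821	61	3.94	+
NM_002755	MAP2K1	PK	1179	0.84	0.97	53	62	207	53	1.05	=
NM_004073	PLK3	PK	1938	0.84	0.97	61	64	322	50	1.15	+
NM_002745	Erk2	PK	1080	0.81	0.98	47	61	204	57	1.34	+
NM_001315	p38a	PK	1080	0.82	0.98	47	62	213	59	2.57	+
NM_002750	JNK1	PK	1152	0.78	0.98	42	60	261	68	2.78	+
NM_002753	JNK3	PK	1266	0.81	0.98	45	60	238	56	14.73	+
NM_001292	CLK3	PK	487	0.85	0.97	60	67	92	61	0.97	=
NM_001892	CK1a	PK	1011	0.79	0.98	44	60	201	60	1.95	+
NM_003042	GAT1	MP	1797	0.87	0.98	56	61	254	42	1.19	+
NM_001045	Serotonin-TP	MP	1890	0.83	0.97	53	60	322	51	1.27	+
NM_030956	TLR10	MP	2433	0.76	0.98	38	58	551	68	only_opt	+
NM_014437	SLC39A1	MP	972	0.83	0.96	62	65	160	49	0.29	-
NM_000220	KCNJ1	MP	1173	0.81	0.98	45	60	231	59	only_opt	+
NM_001651	AQP5	MP	795	0.87	0.96	63	63	112	42	9.05	+
NM_001753	CAV1	MP	534	0.84	0.99	50	59	88	49	1.04	=
NM_000593	TAP1	MP	2424	0.82	0.96	60	65	446	55	1.97	+
NM_000544	TAP2	MP	2109	0.84	0.96	59	64	345	49	2.37	+
NM_005561	LAMP1	MP	1251	0.84	0.97	56	62	206	49	1.28	+
NM_002294	LAMP2	MP	1230	0.78	0.98	43	61	280	68	only_opt	+
NM_014398	LAMP3	MP	1248	0.78	0.97	50	64	269	65	2.80	+
NM_000086	CLN3	MP	1314	0.84	0.97	60	64	211	48	2.64	+
NM_014319	LEMD3	MP	2733	0.76	0.96	52	64	583	64	1.29	+
NM_000914	OPRM1	MP	1200	0.83	0.98	49	60	212	53	2.70	+
NM_023921	TAS2R10	MP	921	0.75	0.99	36	55	204	66	only_opt	+
NM_024006	VKORC1	MP	520	0.83	0.98	59	65	73	45	0.76	-
NM_002507	NGFR	MP	1281	0.88	0.97	66	66	170	40	1.15	+
NM_000585	IL-15	IM	486	0.73	0.98	36	58	126	78	only_opt	+
NM_011337.2	Mip1a	IM	276	0.82	0.97	52	59	52	57	1.48	+
NM_000586	IL-2	IM	459	0.78	0.97	39	58	98	64	only_opt	+
NP_000610	IFNg	IM	498	0.77	0.98	39	56	116	69	1.81	+
NM_006850	IL-24	IM	618	0.82	0.98	50	62	103	50	1.20	+
NM_000572	IL-10	IM	534	0.86	0.98	51	59	80	45	1.35	+
NM_002985	RANTES	IM	304	0.84	0.96	56	62	46	51	1.04	=
NM_024013	IFNa	IM	567	0.85	0.97	50	61	99	52	1.16	+
NM_001012271	BIRC5	other	495	0.84	0.96	54	61	84	51	4.24	+
NM_001786	CDC2	other	891	0.76	0.98	39	59	217	73	2.85	+
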