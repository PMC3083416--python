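CHR	SNP	BP	A1	F_A	F_U	A2	CHISQ	OR	BAND	LOCATION	GENE	UNADJ	FDR_BH	BONF	SUBTYPE	N_CASES
5	rs2277049	147883281	A	0.115	0.081	C	13.71	1.48	5q33.1	Intron	HTR4	0.0002	0.0017	0.0041	Language-impaired	639
9	rs757099	25727567	C	0.391	0.447	T	12.94	0.79	9p21.2	CNV		0.0003	0.0017	0.0061	Language-impaired	639
7	rs7785107	10247968	T	0.031	0.056	G	12.79	0.54	7p21.3	CNV		0.0003	0.0017	0.0066	Language-impaired	639
5	rs7725785	147882896	A	0.114	0.082	C	12.71	1.44	5q33.1	Intron (boundary)	HTR4	0.0004	0.0017	0.0069	Language-impaired	639
5	rs2287581	31341022	A	0.078	0.053	G	11.62	1.51	5p13.3	Intron (boundary)	CDH6	0.0007	0.0022	0.0124	Language-impaired	639
9	rs1231339	25730863	A	0.534	0.480	C	11.54	1.24	9p21.2	CNV		0.0007	0.0022	0.0129	Language-impaired	639
22	rs2180055	47722427	T	0.146	0.113	C	10.1	1.34	22q13.32	CNV		0.0015	0.0040	0.0281	Language-impaired	639
19	rs11671930	8023308	C	0.135	0.160	T	4.809	0.82	19p13.2	Promoter	CCL25	0.0283	0.0598	0.5379	Language-impaired	639
7	rs7785107	10247968	T	0.083	0.056	G	10.01	1.52	7p21.3	CNV		0.0016	0.0296	0.0296	Intermediate	478
11	rs7950390	4587928	G	0.107	0.080	T	7.51	1.38	11p15.4	Promoter	TRIM68	0.0061	0.0370	0.1166	Intermediate	478
10	rs12266938	3852940	C	0.236	0.198	T	7.14	1.25	10p15.1	CNV		0.0075	0.0370	0.1432	Intermediate	478
11	rs3861787	4604346	T	0.102	0.076	G	7.081	1.38	11p15.4	CNV		0.0078	0.0370	0.1480	Intermediate	478
2	rs1827924	228377979	G	0.256	0.326	A	14.2	0.71	2q36.3	Promoter	CCL20	0.0002	0.0031	0.0031	Moderate	363
14	rs17738966	54371969	A	0.131	0.090	G	11.99	1.52	14q22.2	Downstream	GCH1	0.0005	0.0042	0.0102	Moderate	363
11	rs7950390	4587928	G	0.044	0.080	T	11.59	0.53	11p15.4	Promoter	TRIM68	0.0007	0.0042	0.0126	Moderate	363
11	rs3861787	4604346	T	0.043	0.076	G	10.49	0.54	11p15.4	CNV		0.0012	0.0047	0.0229	Moderate	363
5	rs317985	66773558	A	0.321	0.264	G	10.45	1.32	5q13.1	CNV		0.0012	0.0047	0.0233	Moderate	363
5	rs7725785	147882896	A	0.058	0.082	C	5.168	0.69	5q33.1	Intron (boundary)	HTR4	0.0230	0.0729	0.4372	Moderate	363
10	rs12266938	3852940	C	0.137	0.198	T	16.33	0.64	10p15.1	CNV		0.0001	0.0009	0.0010	Mild	387
16	rs730168	73707776	A	0.173	0.234	G	14.34	0.68	16q23.1	Intron	LDHD	0.0002	0.0009	0.0029	Mild	387
2	rs10519124	67819501	A	0.187	0.137	G	13.99	1.46	2p14			0.0002	0.0009	0.0035	Mild	387
10	rs6482516	18879356	A	0.310	0.247	G	13.91	1.37	10p12.33	Intron	NSUN6	0.0002	0.0009	0.0037	Mild	387
19	rs11671930	8023308	C	0.212	0.160	T	13.21	1.42	19p13.2	Promoter	CCL25	0.0003	0.0011	0.0053	Mild	387
9	rs2297172	71563166	C	0.093	0.139	T	11.92	0.64	9q21.11	Intron	PTAR1	0.0006	0.0018	0.0106	Mild	387
5	rs317985	66773558	A	0.212	0.264	G	9.317	0.75	5q13.1	CNV		0.0023	0.0062	0.0431	Mild	387
2	rs1827924	228377979	G	0.380	0.326	A	8.45	1.26	2q36.3	Promoter	CCL20	0.0037	0.0087	0.0693	Mild	387
9	rs1231339	25730863	A	0.436	0.480	C	5.283	0.83	9p21.2	CNV		0.0215	0.0455	0.4092	Mild	387
9	rs757099	25727567	C	0.486	0.447	T	4.051	1.17	9p21.2	CNV		0.0441	0.0839	0.8386	Mild	387
5	rs7725785	147882896	A	0.062	0.082	C	3.814	0.74	5q33.1	Intron (boundary)	HTR4	0.0508	0.0878	0.9655	Mild	387
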