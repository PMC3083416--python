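CHR	SNP	BP	A1	F_A	F_U	A2	CHISQ	OR	UNADJ	FDR_BH	BONF	SUBTYPE	N_CASES
5	rs1896731	25934777	C	0.415	0.362	T	7.61	1.25	0.0058	0.0266	0.0348	Moderate	363
5	rs10038113	25938099	C	0.471	0.420	T	6.85	1.23	0.0088	0.0266	0.0531	Moderate	363
5	rs7704909	25934678	C	0.315	0.351	T	3.57	0.85	0.0589	0.0740	0.3533	Moderate	363
5	rs4327572	26008578	T	0.314	0.349	C	3.38	0.85	0.0660	0.0740	0.3957	Moderate	363
5	rs12518194	25987318	G	0.314	0.348	A	3.23	0.86	0.0725	0.0740	0.4350	Moderate	363
5	rs4307059	26003460	C	0.312	0.345	T	3.19	0.86	0.0740	0.0740	0.4441	Moderate	363
5	rs4307059	26003460	C	0.332	0.345	T	1.74	0.94	0.1870	0.3607	1.0000	Combined	1867
5	rs12518194	25987318	G	0.334	0.348	A	1.68	0.94	0.1954	0.3607	1.0000	Combined	1867
5	rs4327572	26008578	T	0.336	0.349	C	1.53	0.94	0.2155	0.3607	1.0000	Combined	1867
5	rs7704909	25934678	C	0.339	0.351	T	1.38	0.95	0.2405	0.3607	1.0000	Combined	1867
5	rs10038113	25938099	C	0.425	0.420	T	0.28	1.02	0.5978	0.7173	1.0000	Combined	1867
5	rs1896731	25934777	C	0.365	0.362	T	0.10	1.02	0.7476	0.7476	1.0000	Combined	1867
5	rs1896731	25934777	C	0.340	0.362	T	2.00	0.91	0.1576	0.4388	0.9456	Language-impaired	639
5	rs10038113	25938099	C	0.402	0.420	T	1.28	0.93	0.2579	0.4388	1.0000	Language-impaired	639
5	rs4307059	26003460	C	0.332	0.345	T	0.83	0.94	0.3629	0.4388	1.0000	Language-impaired	639
5	rs4327572	26008578	T	0.336	0.349	C	0.77	0.94	0.3800	0.4388	1.0000	Language-impaired	639
5	rs12518194	25987318	G	0.335	0.348	A	0.71	0.95	0.3991	0.4388	1.0000	Language-impaired	639
5	rs7704909	25934678	C	0.340	0.351	T	0.60	0.95	0.4388	0.4388	1.0000	Language-impaired	639
5	rs7704909	25934678	C	0.358	0.351	T	0.15	1.03	0.6983	0.9830	1.0000	Intermediate	478
5	rs4327572	26008578	T	0.351	0.349	C	0.02	1.01	0.8895	0.9830	1.0000	Intermediate	478
5	rs12518194	25987318	G	0.346	0.348	A	0.01	0.99	0.9403	0.9830	1.0000	Intermediate	478
5	rs10038113	25938099	C	0.418	0.420	T	0.00	1.00	0.9469	0.9830	1.0000	Intermediate	478
5	rs1896731	25934777	C	0.361	0.362	T	0.00	1.00	0.9634	0.9830	1.0000	Intermediate	478
5	rs4307059	26003460	C	0.345	0.345	T	0.00	1.00	0.9830	0.9830	1.0000	Intermediate	478
5	rs7704909	25934678	C	0.337	0.351	T	0.57	0.94	0.4485	0.7486	1.0000	Mild	387
5	rs4307059	26003460	C	0.334	0.345	T	0.37	0.95	0.5455	0.7486	1.0000	Mild	387
5	rs4327572	26008578	T	0.339	0.349	C	0.31	0.96	0.5759	0.7486	1.0000	Mild	387
5	rs12518194	25987318	G	0.337	0.348	A	0.31	0.96	0.5763	0.7486	1.0000	Mild	387
5	rs10038113	25938099	C	0.429	0.420	T	0.24	1.04	0.6239	0.7486	1.0000	Mild	387
5	rs1896731	25934777	C	0.364	0.362	T	0.02	1.01	0.8853	0.8853	1.0000	Mild	387
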