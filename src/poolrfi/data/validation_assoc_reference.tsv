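chrom	snp	pos	p_value	gene	location
13	rs317270265	12853825	8.12e-06	CANX	Downstream
21	rs14286155	6350615	3.06e-05	CDC42	Intron
2	rs315791208	23470408	4.36e-05	GNG11	Intron
13	rs317965159	10726350	0.000684	CYFIP2	Intron
2	rs315951802	56946139	0.001189	ATP9B	Intron
15	.	7489912	0.001298	MN1	Extron
1	rs15213482	25118696	0.001437	TES	Intron
Z	rs312714432	7564759	0.002362	FAM219A	Intron
1	rs14080181	468436	0.003409	PPP6R2	Intron
1	rs318069175	25124828	0.003993	TES	Intron
15	rs15775634	7501967	0.004145	MN1	Intron
Z	.	46332884	0.005222	STARD4	Upstream
15	rs314540962	7528893	0.005293	PITPNB	Downstream
1	rs315382419	130499091	0.005896	GABRG3	Intron
1	rs317493245	130499100	0.006448	GABRG3	Intron
6	rs14588839	27221456	0.007046	CCDC186	Intron
18	.	4638932	0.007055	UNC13D,ENSGALG00000002278	Downstream
4	.	66157841	0.008525	TXK,TEC	Upstream
6	.	20250604	0.008611	HHEX	Downstream
10	rs316109660	1504159	0.008684	NEO	Intron
7	rs316483815	26455736	0.009332	ADCY5	Intron
27	rs14301531	1697235	0.011689	PSMC5,FTSJ3,ENSGALG00000000293,SMARCD2	Upstream,Extron,Downstream,Downstream
7	rs15872356	26615279	0.015109	ADCY5	Intron
7	rs315234262	26817253	0.019031	MYLK	Intron
Z	.	6813606	0.019644	KIAA1328	Intron
20	rs13633836	8919435	0.020108	HAR1A	Upstream
Z	.	6847225	0.02043	KIAA1328	Intron
6	rs312986238	27242319	0.020633	TDRD1	Upstream
5	.	16429960	0.022312	TPCN2	Intron
2	rs15931222	28639260	0.024226	BZW2	Intron
4	rs315081661	12239357	0.024332	USP12P1	Downstream
4	.	36460098	0.024731	GRID2	Intron
4	rs318158632	5122558	0.026111	NOX1,ENSGALG00000006637,ENSGALG00000020303	Upstream,Intron,Downstream
26	rs14300622	4106086	0.027252	SCUBE3	Intron
15	rs14092096	7493037	0.029197	MN1	Intron
3	rs15269609	8547001	0.030645	MSH2	Intron
4	rs15588679	56165356	0.033439	CAMK2D	Intron
2	rs313915675	39376196	0.034241	CMC1	Intron
4	rs16400807	45122907	0.034602	NUDT9,ENSGALG00000010963	Upstream
6	.	20691988	0.039963	BLNK	Intron
4	rs13523480	56160482	0.041005	CAMK2D	Intron
2	.	145118378	0.042982	TRAPPC9	Intron
4	.	67677262	0.045337	GRXCR1	Intron
2	rs15067942	16967429	0.048495	KIAA1217	Intron
3	rs14316028	8484254	0.049147	FAM179A,TEC	Upstream
13	rs313110716	3909846	0.049643	SLIT3	Intron
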