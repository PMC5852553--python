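snp	chrom	pos	genotype	n	lsm	sd	letters	additive_effect	dominance_effect
rs15213482	chr1	25118696	AA	125	35.02	7.65	B	14.41	-10.70
rs15213482	chr1	25118696	AG	330	9.91	4.69	A	14.41	-10.70
rs15213482	chr1	25118696	GG	320	6.20	4.76	A	14.41	-10.70
rs318069175	chr1	25124828	AA	318	6.08	4.79	A	-12.95	-8.31
rs318069175	chr1	25124828	AG	329	10.72	4.71	A	-12.95	-8.31
rs318069175	chr1	25124828	GG	127	31.98	7.63	B	-12.95	-8.31
chr2:145118378	chr2	145118378	CC	276	1.57	5.14	A	-12.65	0.17
chr2:145118378	chr2	145118378	TC	357	14.39	4.50	AB	-12.65	0.17
chr2:145118378	chr2	145118378	TT	141	26.86	7.18	B	-12.65	0.17
rs315791208	chr2	23470408	AA	166	-3.58	6.62	A	-8.82	12.43
rs315791208	chr2	23470408	AG	380	17.67	4.36	B	-8.82	12.43
rs315791208	chr2	23470408	GG	230	14.05	5.61	B	-8.82	12.43
rs313915675	chr2	39376196	AA	623	9.67	3.44	a	10.14	29.01
rs313915675	chr2	39376196	AC	123	28.55	7.72	b	10.14	29.01
rs313915675	chr2	39376196	CC	27	-10.60	16.47	a	10.14	29.01
rs315951802	chr2	56946139	AA	64	-1.63	10.68	a	-10.64	-3.53
rs315951802	chr2	56946139	AG	293	5.49	5.00	a	-10.64	-3.53
rs315951802	chr2	56946139	GG	417	19.66	4.2	b	-10.64	-3.53
rs318158632	chr4	5122558	AA	249	14.44	5.41	b	8.36	11.93
rs318158632	chr4	5122558	AG	362	18.01	4.50	b	8.36	11.93
rs318158632	chr4	5122558	GG	167	-2.29	6.59	a	8.36	11.93
rs315081661	chr4	12239357	CC	215	15.95	5.82	b	8.83	10.09
rs315081661	chr4	12239357	TC	386	17.21	4.35	b	8.83	10.09
rs315081661	chr4	12239357	TT	175	-1.71	6.45	a	8.83	10.09
chr5:16429960	chr5	16429960	AA	246	23.49	5.46	b	10.08	-5.28
chr5:16429960	chr5	16429960	AT	363	8.13	4.50	a	10.08	-5.28
chr5:16429960	chr5	16429960	TT	164	3.33	6.70	a	10.08	-5.28
rs316109660	chr10	1504159	AA	50	32.29	12.03	b	7.97	-20.56
rs316109660	chr10	1504159	AG	325	3.76	4.72	a	7.97	-20.56
rs316109660	chr10	1504159	GG	400	16.34	4.27	b	7.97	-20.56
chr18:4638932	chr18	4638932	CC	223	23.67	5.72	B	10.90	-1.90
chr18:4638932	chr18	4638932	CG	361	10.86	4.48	AB	10.90	-1.90
chr18:4638932	chr18	4638932	GG	193	1.86	6.16	A	10.90	-1.90
chrZ:46332884	chrZ	46332884	AA	133	12.64	7.68	AB	-2.78	-20.25
chrZ:46332884	chrZ	46332884	AG	145	-4.82	7.53	A	-2.78	-20.25
chrZ:46332884	chrZ	46332884	GG	497	18.21	3.90	B	-2.78	-20.25
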