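breed	trait	lrfi_mean	lrfi_sd	hrfi_mean	hrfi_sd
BeijingYou	rfi	-239.73	74.97	300.67	120.98
BeijingYou	dfi	88.34	15.11	107.28	16.43
BeijingYou	initial_bw	820.58	115.79	805.15	95.36
BeijingYou	final_bw	1364.38	254.89	1357.27	218.45
BeijingYou	adg	19.42	5.49	19.54	4.72
BeijingYou	fcr	4.70	0.58	5.62	0.63
Cobb	rfi	-93.83	7.29	104.09	54.41
Cobb	dfi	141.12	14.36	157.52	6.11
Cobb	initial_bw	1012.71	66.78	1018.92	58.71
Cobb	final_bw	2109.06	175.07	2139.08	96.29
Cobb	adg	78.31	11.22	80.01	5.15
Cobb	fcr	1.82	0.12	1.97	0.05
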