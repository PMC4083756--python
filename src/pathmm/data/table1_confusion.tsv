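concept	algorithm	tp	fp	tn	fn	accuracy	precision	specificity	sensitivity	npv	mcc	auc
musculoskeletal	SIFT	4730	37701	23323	944	0.61	0.57	0.38	0.83	0.70	0.24	0.64
musculoskeletal	PolyPhen-2	5278	44047	34859	714	0.66	0.61	0.44	0.88	0.79	0.36	0.71
musculoskeletal	FATHMM	5902	51596	29202	201	0.66	0.60	0.36	0.97	0.92	0.41	0.73
musculoskeletal	Disease-Specific	4120	3123	77675	1983	0.82	0.95	0.96	0.68	0.75	0.66	0.93
developmental	SIFT	845	41586	23983	284	0.56	0.54	0.37	0.75	0.59	0.12	0.56
developmental	PolyPhen-2	920	48405	35337	236	0.61	0.58	0.42	0.80	0.67	0.23	0.63
developmental	FATHMM	1006	52429	33278	188	0.62	0.58	0.39	0.84	0.71	0.26	0.59
developmental	Disease-Specific	621	710	84997	573	0.76	0.98	0.99	0.52	0.67	0.58	0.90
endocrine	SIFT	3084	39347	23443	824	0.58	0.56	0.37	0.79	0.64	0.18	0.60
endocrine	PolyPhen-2	2890	46435	35031	542	0.64	0.60	0.43	0.84	0.73	0.30	0.67
endocrine	FATHMM	3597	49466	33522	316	0.66	0.61	0.40	0.92	0.83	0.38	0.71
endocrine	Disease-Specific	2392	1015	81973	1521	0.80	0.98	0.99	0.61	0.72	0.65	0.94
metabolic	SIFT	10731	31700	21913	2354	0.61	0.58	0.41	0.82	0.69	0.25	0.64
metabolic	PolyPhen-2	11337	37988	33788	1785	0.67	0.62	0.47	0.86	0.78	0.36	0.72
metabolic	FATHMM	13068	39914	33271	648	0.70	0.64	0.45	0.95	0.91	0.47	0.80
metabolic	Disease-Specific	10767	3209	69976	2949	0.87	0.95	0.96	0.78	0.82	0.75	0.95
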