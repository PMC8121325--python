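aa	codon	count_w	rscu_w	count_g	rscu_g
Phe	UUU	161	1.5	141	1.5
Phe	UUC	53	0.5	47	0.5
Leu	UUA	206	3.07	196	2.94
Leu	UUG	32	0.48	39	0.58
Leu	CUU	54	0.8	68	1.02
Leu	CUC	12	0.18	16	0.24
Leu	CUA	79	1.18	66	0.99
Leu	CUG	20	0.3	15	0.23
Ile	AUU	257	1.62	263	1.67
Ile	AUC	61	0.38	52	0.33
Met	AUA	211	1.7	206	1.73
Met	AUG	37	0.3	32	0.27
Val	GUU	35	1.33	33	1.22
Val	GUC	9	0.34	11	0.41
Val	GUA	53	2.02	50	1.85
Val	GUG	8	0.3	14	0.52
Ser	UCU	54	1.5	42	1.21
Ser	UCC	14	0.39	23	0.66
Ser	UCA	102	2.83	95	2.73
Ser	UCG	6	0.17	8	0.23
Pro	CCU	61	1.73	48	1.41
Pro	CCC	21	0.6	24	0.71
Pro	CCA	53	1.5	57	1.68
Pro	CCG	6	0.17	7	0.21
Thr	ACU	76	1.55	79	1.6
Thr	ACC	43	0.88	31	0.63
Thr	ACA	68	1.39	79	1.6
Thr	ACG	9	0.18	9	0.18
Ala	GCU	30	1.41	26	1.51
Ala	GCC	12	0.56	11	0.64
Ala	GCA	38	1.79	28	1.62
Ala	GCG	5	0.24	4	0.23
Tyr	UAU	117	1.45	111	1.42
Tyr	UAC	44	0.55	45	0.58
His	CAU	53	1.41	63	1.4
His	CAC	22	0.59	27	0.6
Gln	CAA	90	1.64	110	1.71
Gln	CAG	20	0.36	19	0.29
Asn	AAU	240	1.54	261	1.57
Asn	AAC	72	0.46	71	0.43
Lys	AAA	329	1.8	324	1.77
Lys	AAG	36	0.2	43	0.23
Asp	GAU	44	1.47	56	1.65
Asp	GAC	16	0.53	12	0.35
Glu	GAA	111	1.66	111	1.72
Glu	GAG	23	0.34	18	0.28
Cys	UGU	24	1.33	18	1.29
Cys	UGC	12	0.67	10	0.71
Trp	UGA	65	1.71	67	1.65
Trp	UGG	11	0.29	14	0.35
Arg	CGU	13	1.06	9	0.84
Arg	CGC	1	0.08	3	0.28
Arg	CGA	31	2.53	27	2.51
Arg	CGG	4	0.33	4	0.37
Ser	AGU	29	0.81	28	0.81
Ser	AGC	18	0.5	20	0.58
Ser	AGA	47	1.31	42	1.21
Ser	AGG	18	0.5	20	0.58
Gly	GGU	25	0.98	39	1.51
Gly	GGC	4	0.16	10	0.39
Gly	GGA	46	1.8	38	1.48
Gly	GGG	27	1.06	16	0.62
Stop	UAA	152	1.73	179	1.77
Stop	UAG	24	0.27	23	0.23
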