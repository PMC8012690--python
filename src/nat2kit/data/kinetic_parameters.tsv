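drug	allele	km_mean	km_se	vmax_mean	vmax_se	clint_mean	clint_se	km_letters	vmax_letters	clint_letters
AGT	*4	76.24	2.49	45.18	1.52	0.593	0.010			
AGT	*5	104.07	8.65	10.87	0.65	0.105	0.004		a	a
AGT	*6	187.75	26.36	6.70	0.51	0.037	0.003	a,b	a,b	a,b
AGT	*7	188.83	5.56	5.44	0.18	0.029	0.001	a,b	a,b	a,b
DDP	*4	98.17	8.60	24.73	1.67	0.255	0.018			
DDP	*5	85.31	10.69	4.86	0.06	0.059	0.006		a	a
DDP	*6	15.30	0.44	0.54	0.03	0.035	0.001	a,b	a,b	a
DDP	*7	5.21	0.26	0.96	0.01	0.185	0.008	a,b	a,b	a,b,c
HLZ	*4	5.79	0.26	1023.20	33.02	177.09	4.94			
HLZ	*5	4.68	0.19	224.78	3.85	48.15	1.42	a	a	a
HLZ	*6	2.97	0.17	45.78	1.65	15.46	0.41	a,b	a,b	a,b
HLZ	*7	4.76	0.26	28.29	1.38	5.95	0.10	a,c	a,b	a,b
INH	*4	128.10	4.54	1496.50	57.79	11.706	0.422			
INH	*5	139.80	16.33	196.35	8.57	1.449	0.126		a	a
INH	*6	135.20	9.81	61.94	2.22	0.462	0.019		a,b	a,b
INH	*7	230.50	22.29	69.22	2.00	0.306	0.021	a,b,c	a,b	a,b
PZ	*4	192.20	11.70	67.02	5.27	0.348	0.012			
PZ	*5	134.50	11.59	13.27	0.97	0.102	0.014		a	a
PZ	*6	174.35	23.60	7.30	0.38	0.044	0.006		a	a,b
PZ	*7	376.68	28.77	6.81	0.07	0.018	0.001	a,b,c	a	a,b
PA	*4	193.13	15.16	78.33	2.19	0.410	0.019			
PA	*5	164.65	6.65	19.63	0.28	0.120	0.006		a	a
PA	*6	220.30	9.34	17.04	0.25	0.078	0.002	b	a	a
PA	*7	167.73	4.22	10.13	0.24	0.061	0.002	c	a,b,c	a,b
SMZ	*4	86.24	6.58	4.83	0.17	0.056	0.002			
SMZ	*5	136.00	5.87	0.98	0.06	0.007	0.000	a	a	a
SMZ	*6	85.95	2.92	0.34	0.00	0.004	0.001	b	a,b	a
SMZ	*7	12.37	1.15	0.21	0.01	0.017	0.002	a,b,c	a,b	a,b,c
SP	*4	174.90	20.79	63.53	4.73	0.369	0.019			
SP	*5	162.70	12.93	13.44	0.17	0.084	0.006		a	a
SP	*6	142.88	14.10	6.18	0.13	0.044	0.003		a	a
SP	*7	27.50	1.10	4.60	0.07	0.168	0.010	a,b,c	a	a,b,c
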