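trait	year	regime	mean	se	gcv	pcv	h2	ga	gam
FY	2018	control	704.91	11.08	19.62	22.26	77.70	251.19	35.63
FY	2018	drought	492.53	6.33	14.25	18.21	61.22	113.10	22.96
FY	2019	control	1496.05	19.24	17.54	18.23	92.58	520.23	34.77
FY	2019	drought	1026.22	10.59	13.67	14.62	87.33	269.98	26.31
DY	2018	control	349.11	6.06	19.97	24.61	65.83	116.51	33.37
DY	2018	drought	280.70	4.76	19.48	24.01	65.82	91.36	32.55
DY	2019	control	804.37	11.46	19.35	20.19	91.88	307.41	38.22
DY	2019	drought	621.29	7.73	16.43	17.64	86.80	195.94	31.54
A	2018	control	13.04	0.06	6.43	7.02	83.87	1.58	12.13
A	2018	drought	2.82	0.08	36.11	39.81	82.27	1.90	67.46
A	2019	control	15.25	0.09	7.72	8.23	88.09	2.28	14.93
A	2019	drought	4.42	0.12	36.29	37.31	94.59	3.21	72.70
gs	2018	control	0.22	0.002	15.84	16.23	95.21	0.07	31.83
gs	2018	drought	0.05	0.002	46.54	47.18	97.34	0.05	94.60
gs	2019	control	0.26	0.003	15.23	15.53	96.28	0.08	30.79
gs	2019	drought	0.07	0.002	39.66	41.52	91.25	0.05	78.05
Tr	2018	control	3.46	0.02	10.26	10.51	95.37	0.71	20.64
Tr	2018	drought	0.84	0.02	31.23	32.04	94.97	0.53	62.69
Tr	2019	control	3.79	0.02	13.33	13.47	97.94	1.03	27.18
Tr	2019	drought	1.13	0.02	21.60	23.54	84.22	0.46	40.83
Chl	2018	control	9.92	0.03	4.37	4.73	85.36	0.83	8.32
Chl	2018	drought	6.84	0.04	6.63	7.49	78.40	0.83	12.10
Chl	2019	control	10.48	0.04	4.55	4.82	89.24	0.93	8.86
Chl	2019	drought	7.32	0.03	5.32	5.62	89.74	0.76	10.39
FvFm	2018	control	0.71	0.003	6.48	6.94	87.06	0.09	12.45
FvFm	2018	drought	0.52	0.005	11.90	12.68	88.05	0.12	22.99
FvFm	2019	control	0.75	0.005	5.50	6.05	82.72	0.09	10.31
FvFm	2019	drought	0.59	0.004	9.48	9.85	92.57	0.11	18.78
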