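module	invivo_9h_LD	invivo_9h_HD	invivo_33h_LD	invivo_33h_HD	invitro_12h_LD	invitro_12h_HD	invitro_24h_LD	invitro_24h_HD
Dilatation	1.51	2.72	5.65	10.45	0.51	2.94	0.63	2.59
Hyaline cast	2.38	3.54	4.29	9.64	0.32	1.73	0.41	1.20
Degeneration	2.55	3.09	4.74	7.58	2.74	1.10	0.31	0.96
Necrosis	5.05	6.10	3.45	6.70	1.57	2.74	1.77	1.72
Fibrogenesis	2.07	2.79	2.18	3.67	3.03	5.11	1.03	2.34
Intracytoplasmic inclusion body	0.68	1.43	0.17	3.50	1.51	4.88	0.39	0.85
Hypertrophy	0.32	-0.43	-0.04	1.50	-0.21	0.80	0.65	-0.52
Cellular infiltration	-1.63	-1.04	2.15	0.04	4.06	2.05	1.35	0.82
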