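case	prostate_gland_cm3	gtv_union_cm3	prostate_minus_cm3	ctv_minus_cm3	gtv_fraction_pct	sensitivity_case
1	25.64	2.76	22.49	17.23	10.76	0
2	41.02	6.01	34.76	19.68	14.65	1
3	60.26	2.21	57.52	30.58	3.67	0
4	48.67	5.47	42.70	19.51	11.24	0
5	23.59	1.66	21.85	12.78	7.04	1
6	55.66	4.62	51.11	25.13	8.30	1
7	48.01	18.79	28.88	20.69	39.14	0
8	37.40	3.15	34.15	19.17	8.42	0
9	35.60	4.75	30.89	19.22	13.34	0
10	56.73	6.85	49.98	22.46	12.07	0
11	48.25	3.03	45.28	24.36	6.28	0
12	42.33	6.98	35.10	21.02	16.49	0
13	38.41	2.23	36.34	23.25	5.81	0
14	24.36	3.85	20.63	15.83	15.80	0
15	38.55	2.32	36.19	17.85	6.02	0
16	33.16	3.25	29.96	19.74	9.80	0
17	46.74	5.13	41.61	20.20	10.98	1
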