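sample_id	DDX3Y	KDM5D	ZFY	EIF2S3Y	EIF1AY	LOC110255320	LOC110257894	LOC396706	LOC100625207	LOC110255257	sigma_cpm_published
E1-25DA-M	151.46	7.52	24.81	162.23	40.64	12.04	9.71	1.53	61.73	15.17	486.84
E2-25DA-M	166.54	7.64	31.68	197.73	45.16	12.30	11.81	1.95	61.00	17.72	553.53
E3-25DC-M	167.21	9.56	28.67	211.97	45.86	13.23	12.79	2.21	66.52	15.07	573.09
E4-25DC-M	170.76	10.15	29.78	189.79	46.39	11.43	12.41	2.11	71.81	17.90	562.53
E5-25DC-M	149.28	6.56	24.94	180.78	36.55	13.47	10.47	1.43	55.29	16.46	495.23
E6-25DC-M	156.64	9.19	30.92	192.23	40.76	12.14	10.99	2.30	68.56	16.24	539.97
E7-25DC-M	166.10	9.43	33.57	192.23	44.92	12.31	11.43	1.84	71.78	17.03	560.64
F1-35DC-M	193.41	5.35	26.07	130.67	44.65	9.79	6.25	1.23	52.46	13.16	483.04
F2-35DC-M	167.28	7.11	28.43	135.38	39.84	10.25	7.19	1.41	56.20	15.04	468.13
F3-35DC-M	168.09	7.05	31.32	141.53	37.80	10.96	7.26	1.78	58.09	13.03	476.91
F4-35DA-M	157.51	8.17	26.77	119.45	33.45	9.30	6.46	2.06	51.27	12.85	427.29
F5-35DA-M	200.33	8.04	24.02	126.13	45.09	12.20	6.56	2.13	45.83	12.20	482.53
F6-35DA-M	187.01	6.47	24.02	128.61	41.58	10.35	8.01	2.02	45.54	13.43	467.04
F7-35DA-M	180.78	7.06	29.27	133.42	41.14	11.74	6.57	2.10	50.78	13.20	476.06
F8-35DC-M	178.15	10.68	33.04	155.57	43.49	11.29	9.23	2.06	62.94	17.32	523.77
F9-35DA-M	143.33	10.28	27.83	135.33	31.42	12.33	8.65	1.55	53.79	12.73	437.24
F10-35DA-M	173.51	10.40	26.69	128.32	36.71	12.62	6.88	1.91	58.19	15.37	470.60
E1-25DA-F	0.00	0.07	0.00	0.00	0.07	0.00	0.00	0.00	0.00	0.00	0.14
E2-25DA-F	0.00	0.00	0.00	0.00	0.07	0.00	0.00	0.00	0.00	0.07	0.14
E3-25DC-F	0.00	0.00	0.07	0.07	0.00	0.00	0.00	0.00	0.00	0.00	0.14
E4-25DC-F	0.28	0.00	0.07	0.07	0.07	0.00	0.00	0.00	0.00	0.00	0.49
E5-25DC-F	0.00	0.00	0.00	0.15	0.00	0.00	0.00	0.00	0.07	0.15	0.37
E6-25DC-F	0.00	0.00	0.14	0.00	0.07	0.00	0.00	0.00	0.00	0.00	0.21
E7-25DC-F	0.00	0.00	0.15	0.08	0.00	0.00	0.00	0.00	0.00	0.00	0.23
E8-25DC-F	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00
E9-25DC-F	0.00	0.00	0.00	0.00	0.07	0.00	0.00	0.00	0.00	0.07	0.14
E10-25DC-F	0.00	0.00	0.08	0.08	0.08	0.00	0.00	0.00	0.00	0.00	0.24
E11-25DA-F	0.13	0.00	0.07	0.13	0.07	0.00	0.00	0.00	0.20	0.00	0.60
F1-35DA-F	0.08	0.00	0.08	0.00	0.00	0.00	0.00	0.00	0.00	0.08	0.24
F2-35DA-F	0.00	0.08	0.23	0.00	0.08	0.00	0.00	0.00	0.00	0.00	0.39
F3-35DA-F	0.16	0.00	0.00	0.25	0.08	0.00	0.00	0.00	0.08	0.00	0.57
F4-35DC-F	0.00	0.00	0.07	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.07
F5-35DA-F	0.71	0.00	0.32	0.48	0.08	0.00	0.00	0.00	0.16	0.00	1.75
F6-35DA-F	0.22	0.07	0.14	0.29	0.07	0.00	0.00	0.00	0.22	0.00	1.01
F7-35DA-F	0.00	0.00	0.07	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.07
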