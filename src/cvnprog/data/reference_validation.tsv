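dataset	years	fingerprint	n_patients	n_na	odds_ratio	or_ci_low	or_ci_high	or_pvalue	kappa	auc	auc_pvalue
MSKCC	2-3	Fp_0	110	1.7	15.4	4.05	58.71	0.0001	0.4	0.68	0.003
MSKCC	3-4	Fp_0	93	3.77	13.11	2.71	63.26	0.0007	0.32	0.70	0.0006
GSE70769	2-3	Fp_0	39	10.1	12	1.68	85.70	0.02	0.42	0.77	0.007
GSE46602	2-3	Fp_0	30	1.2	9.2	1.38	62.36	0.06	0.33	0.72	0.01
GSE53922	2-3	Fp_0	89	14.32	8.33	1.65	41.90	0.01	0.26	0.64	0.02
GSE46602	3-4	Fp_14	30	5.06	9	1.50	53.96	0.03	0.43	0.78	0.005
GSE53922	3-4	Fp_14	90	26.08	20	3.68	108.53	0.003	0.43	0.82	0.0001
MSKCC	2-3	Fp_1	110	3.9	8.66	2.64	28.40	0.0007	0.37	0.69	9.70E-05
GSE46602	2-3	Fp_1	30	4.05	30	4.22	213.15	0.002	0.59	0.86	0.0003
GSE46602	3-4	Fp_1	30	1.69	40	4.48	356.46	0.0005	0.65	0.83	0.0009
GSE46602	2-3	Fp_12	30	3.7	25	3.76	166.22	0.003	0.59	0.86	0.0006
GSE84042	2-3	Fp_12	65	7.3	18.33	1.38	242.77	0.12	0.37	0.88	0.002
MSKCC	2-3	Fp_30	110	2.36	13.83	1.82	105.08	0.02	0.18	0.61	0.04
GSE54460	3-4	Fp_30	31	1.47	20	0.99	401.64	0.16	0.48	0.79	0.05
GSE46602	2-3	Fp_30	30	5.3	13.5	2.21	82.28	0.01	0.47	0.82	0.002
GSE53922	2-3	Fp_30	89	7.66	12	1.75	82.08	0.004	0.21	0.70	0.001
MSKCC	2-3	Fp_20	110	4.6	8.5	2.43	29.77	0.001	0.34	0.67	0.006
MSKCC	3-4	Fp_20	93	2.2	22.47	3.58	140.98	0.0006	0.32	0.70	0.001
GSE46602	3-4	Fp_20	30	0.5	30	4.53	198.56	0.001	0.55	0.83	0.001
GSE53922	2-3	Fp_20	89	4.0	16	3.16	80.95	0.002	0.43	0.79	0.0007
GSE37199	HR-LR	Fp_20	107	28.2	10.88	2.26	52.33	0.001	0.33	0.69	0.001
GSE84042	4-5	Fp_37	145	20.4	19.9	4.03	98.86	0.000017	0.46	0.87	1.90E-06
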