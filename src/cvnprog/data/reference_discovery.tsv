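fingerprint	years	selection	n_patients	n_na	odds_ratio	or_ci_low	or_ci_high	or_pvalue	kappa	auc	auc_pvalue	logrank_pvalue	lookahead
Fp_0	2-3	pareto	53	1	13	1.2	139.9	0.03	0.29	0.72	0.005	1.60E-05	2
Fp_1	3-4	ng	37	3	20	2.0	192.6	0.01	0.54	0.70	0.01	1.50E-05	0
Fp_12	2-3	pareto	39	3	21	1.7	254.2	0.01	0.47	0.62	0.16	0.004	1
Fp_14	4-5	pareto	19	2	12	0.93	153.8	0.1	0.49	0.71	0.05	0.08	1
Fp_30	3-4	ng	25	0	18.75	1.6	209.5	0.01	0.53	0.72	0.03	0.01	0
Fp_20	2-3	ng	39	2	17.14	1.7	172.0	0.008	0.43	0.79	0.01	0.0009	0
Fp_37	3-4	pareto	31	0	16	2.6	96.4	0.001	0.59	0.78	0.004	7.07E-05	1
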