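target	pdb_id	n_residues	chemical_class	sen_pct	prec_pct	mcc	ratio_pct
T0518	3NMB	288	metal	57.14	57.14	0.56	2.43
T0521	3MSE	179	metal	33.33	33.33	0.30	5.03
T0529	3MWT	569	metal	50.00	9.09	0.20	0.70
T0539	2L0B	81	metal	37.50	50.00	0.38	9.88
T0548	3NNQ	106	metal	100.00	66.67	0.81	3.77
T0582	3O14	222	metal	100.00	66.67	0.81	1.80
T0585	3NE8	234	metal	60.00	75.00	0.66	2.14
T0625	3ORU	233	metal	66.67	22.22	0.37	1.29
T0629	2XGF	216	metal	100.00	73.68	0.85	6.48
T0635	3N1U	191	metal	100.00	33.33	0.57	1.57
T0570	3NO3	258	hybrid	50.00	44.44	0.45	3.10
T0607	3PFE	471	hybrid	57.14	32.00	0.41	2.97
T0615	3NQW	179	hybrid	26.67	44.44	0.30	8.38
T0515	3MT1	365	non-metal	50.00	20.69	0.29	3.29
T0516	3NO6	229	non-metal	30.77	50.00	0.36	5.68
T0524	3MWX	325	non-metal	53.85	77.78	0.64	4.00
T0526	3NRE	290	non-metal	11.11	5.56	0.04	3.10
T0547	3NZP	611	non-metal	58.82	26.32	0.37	2.78
T0565	3NPF	326	non-metal	41.67	62.50	0.50	3.68
T0584	3NF2	352	non-metal	23.08	25.00	0.21	3.69
T0591	3NRA	406	non-metal	41.67	83.33	0.58	2.96
T0597	3NIE	429	non-metal	31.58	37.50	0.32	4.43
T0599	3OS6	399	non-metal	7.69	11.11	0.07	3.26
T0604	3NLC	549	non-metal	9.09	16.67	0.08	6.01
T0609	3OS7	340	non-metal	70.00	70.00	0.69	2.94
T0613	3OBI	287	non-metal	26.67	44.44	0.32	5.23
T0622	3NKL	138	non-metal	20.00	37.50	0.21	10.87
T0632	3NWZ	168	non-metal	18.75	37.50	0.21	9.52
T0636	3P1T	336	non-metal	23.53	66.67	0.38	5.06
T0641	3NYI	296	non-metal	11.11	66.67	0.26	6.08
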