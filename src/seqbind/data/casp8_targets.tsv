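target	pdb_id	n_residues	ligands	chemical_class	sen_pct	prec_pct	mcc	ratio_pct
T0391	3d89	157	FES	metal	44.44	80.00	0.58	5.73
T0406	3di5	167	NI	metal	100.00	100.00	1.00	1.80
T0407	3e38	363	ZN ZN ZN	metal	88.89	66.67	0.76	2.48
T0410	3d3l	541	FE	metal	12.50	6.90	0.06	2.96
T0425	3czx	181	ZN	metal	33.33	100.00	0.57	4.97
T0426	3da2	283	ZN	metal	33.33	18.75	0.22	3.18
T0440	3dcp	275	FE ZN FE	metal	100.00	42.86	0.64	3.27
T0444	2vux	326	FE	metal	75.00	8.82	0.24	1.23
T0453	3ded	91	CA CA CA	metal	25.00	33.33	0.26	4.40
T0457	3dev	320	MG	metal	100.00	19.05	0.43	1.25
T0461	3dh1	189	ZN	metal	100.00	27.27	0.51	1.59
T0470	3djb	223	MG	metal	100.00	26.67	0.50	1.79
T0476	2k5c	108	ZN	metal	100.00	100.00	1.00	3.70
T0478	3d19	283	MG FE	metal	71.43	100.00	0.84	2.47
T0480	2k4x	55	ZN	metal	75.00	75.00	0.73	7.27
T0487	3f73	685	MG	metal	25.00	5.00	0.10	0.58
T0394	3dcy	275	PO4	non-metal	33.33	57.14	0.42	4.36
T0396	396	105	FAD	non-metal	13.04	75.00	0.26	21.90
T0422	3d8b	357	ADP	non-metal	41.18	38.89	0.37	4.76
T0430	3dlz	357	AMP	non-metal	14.29	37.50	0.20	5.88
T0431	3dax	491	HEM	non-metal	10.53	18.18	0.11	3.87
T0450	3da1	561	FAD	non-metal	41.03	27.59	0.28	6.95
T0477	3dkp	242	ADP MG	non-metal	60.00	50.00	0.53	4.13
T0483	3dls	335	ADP MG	non-metal	39.13	42.86	0.37	6.87
T0485	3dlc	218	SAM	non-metal	5.26	100.00	0.22	8.72
T0490	3dme	369	FAD	non-metal	29.41	35.71	0.26	9.21
T0508	3dou	197	SAM	non-metal	36.84	70.00	0.47	9.64
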