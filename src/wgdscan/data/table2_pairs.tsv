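species	gene_a	gene_b	n_flank	ks_mean	ks_sd	date_mya
Gmax	GmHsf-05	GmHsf-26	14	0.12	0.02	9.84
Gmax	GmHsf-25	GmHsf-45	15	0.12	0.01	9.84
Gmax	GmHsf-06	GmHsf-33	16	0.13	0.01	10.66
Gmax	GmHsf-13	GmHsf-15	16	0.13	0.02	10.66
Gmax	GmHsf-04	GmHsf-27	14	0.14	0.02	11.48
Gmax	GmHsf-01	GmHsf-20	16	0.15	0.01	12.30
Gmax	GmHsf-11	GmHsf-16	15	0.15	0.02	12.30
Gmax	GmHsf-24	GmHsf-46	16	0.15	0.02	12.30
Gmax	GmHsf-34	GmHsf-42	12	0.16	0.02	13.11
Gmax	GmHsf-32	GmHsf-36	11	0.16	0.01	13.11
Gmax	GmHsf-12	GmHsf-17	14	0.16	0.01	13.11
Gmax	GmHsf-23	GmHsf-30	7	0.17	0.02	13.93
Gmax	GmHsf-29	GmHsf-39	16	0.17	0.03	13.93
Gmax	GmHsf-03	GmHsf-28	16	0.18	0.02	14.75
Gmax	GmHsf-07	GmHsf-43	6	0.18	0.03	14.75
Gmax	GmHsf-09	GmHsf-14	16	0.18	0.03	14.75
Gmax	GmHsf-35	GmHsf-41	7	0.18	0.06	14.75
Gmax	GmHsf-18	GmHsf-38	5	0.38	0.10	31.15
Gmax	GmHsf-08	GmHsf-23	4	0.57	0.02	46.72
Gmax	GmHsf-10	GmHsf-41	7	0.58	0.11	47.54
Gmax	GmHsf-10	GmHsf-35	6	0.59	0.10	48.36
Gmax	GmHsf-09	GmHsf-42	4	0.62	0.04	50.82
Gmax	GmHsf-21	GmHsf-25	5	0.62	0.08	50.82
Gmax	GmHsf-08	GmHsf-30	4	0.65	0.07	53.28
Gmax	GmHsf-14	GmHsf-34	4	0.65	0.06	53.28
Gmax	GmHsf-22	GmHsf-44	8	0.65	0.07	53.28
Gmax	GmHsf-14	GmHsf-42	5	0.66	0.04	54.10
Gmax	GmHsf-24	GmHsf-38	5	0.71	0.10	58.20
Gmax	GmHsf-38	GmHsf-46	6	0.72	0.10	59.02
Gmax	GmHsf-12	GmHsf-32	6	0.77	0.04	63.11
Gmax	GmHsf-17	GmHsf-32	6	0.77	0.06	63.11
Gmax	GmHsf-12	GmHsf-36	6	0.79	0.04	64.75
Gmax	GmHsf-17	GmHsf-36	6	0.80	0.06	65.57
Gmax	GmHsf-28	GmHsf-40	4	0.85	0.17	69.67
Gmax	GmHsf-03	GmHsf-40	4	0.91	0.12	74.59
Mtruncatula	MtHsf-11	MtHsf-19	5	0.77	0.10	63.05
Mtruncatula	MtHsf-03	MtHsf-16	5	0.80	0.03	65.66
Ccajan	CcHsf-10	CcHsf-11	5	0.74	0.14	60.66
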