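dataset	collection	enriched_nd	enriched_d	de_pathways	overlap_nd	overlap_d	p_nd	p_d	background
EMT	HALLMARK	8	10	25	7	8	4.28e-2	6.70e-2	46
EMT	KEGG	46	41	52	22	22	3.21e-2	4.84e-3	145
EMT	REACTOME	40	40	68	15	15	2.16e-2	2.16e-2	292
EMT	GOBP	404	372	762	151	136	3.97e-8	1.02e-6	2927
EMT	GOMF	149	149	149	40	37	2.55e-1	4.97e-1	608
Serine Starvation	HALLMARK	9	10	34	8	7	2.45e-1	7.71e-1	46
Serine Starvation	KEGG	55	51	44	17	14	4.43e-1	7.08e-1	150
Serine Starvation	REACTOME	127	113	96	53	51	7.55e-6	5.20e-7	349
Serine Starvation	GOBP	414	448	985	200	204	6.31e-16	7.43e-13	3206
Serine Starvation	GOMF	166	163	147	32	28	5.41e-1	8.11e-1	762
NECS Age	HALLMARK	12	9	8	1	1	9.30e-1	8.52e-1	46
NECS Age	KEGG	28	27	37	3	3	9.96e-1	9.95e-1	133
NECS Age	REACTOME	24	25	29	4	7	4.60e-1	4.52e-2	202
NECS Age	GOBP	362	312	634	71	71	5.71e-1	3.87e-1	2728
NECS Age	GOMF	76	69	74	13	16	2.25e-1	3.83e-3	450
NECS EL	HALLMARK	13	13	8	1	2	9.47e-1	7.34e-1	46
NECS EL	KEGG	33	28	37	4	3	9.96e-1	9.96e-1	133
NECS EL	REACTOME	25	22	29	4	3	4.99e-1	6.44e-1	202
NECS EL	GOBP	378	366	634	76	82	9.49e-1	6.80e-1	2728
NECS EL	GOMF	93	75	74	11	15	9.38e-1	2.26e-1	450
M005 Kidney	HALLMARK	9	8	11	3	3	3.66e-1	2.84e-1	46
M005 Kidney	KEGG	32	26	9	5	4	2.68e-2	5.73e-2	143
M005 Kidney	REACTOME	32	26	8	3	3	4.16e-2	2.36e-2	303
M005 Kidney	GOBP	333	288	264	64	44	1.50e-10	1.11e-4	2997
M005 Kidney	GOMF	134	120	50	22	17	1.32e-4	2.36e-2	631
M005 Liver	HALLMARK	7	6	17	4	4	2.16e-1	1.24e-1	46
M005 Liver	KEGG	36	30	38	20	20	2.14e-5	2.46e-7	140
M005 Liver	REACTOME	29	24	27	5	5	1.42e-1	7.26e-2	273
M005 Liver	GOBP	296	241	251	74	62	5.75e-19	2.08e-16	2834
M005 Liver	GOMF	112	111	88	31	24	2.89e-4	5.31e-2	548
M005 Gastroc	HALLMARK	7	6	2	2	2	2.12e-2	2.12e-2	45
M005 Gastroc	KEGG	19	14	4	0	0	1	1	116
M005 Gastroc	REACTOME	15	13	2	0	0	1	1	169
M005 Gastroc	GOBP	202	165	60	7	5	2.28e-1	3.87e-2	2427
M005 Gastroc	GOMF	54	45	7	0	0	1	1	431
M005 Plasma	HALLMARK	6	4	3	2	2	5.59e-2	2.47e-2	38
M005 Plasma	KEGG	7	6	4	3	2	3.76e-2	1.91e-1	28
M005 Plasma	REACTOME	3	5	10	0	0	1	1	33
M005 Plasma	GOBP	112	114	55	12	8	1.75e-3	1.03e-1	1295
M005 Plasma	GOMF	35	33	4	3	3	2.65e-2	2.23e-2	173
ROSMAP	HALLMARK	11	10	17	4	2	6.51e-1	9.53e-1	46
ROSMAP	KEGG	32	29	34	11	9	7.73e-2	1.94e-1	146
ROSMAP	REACTOME	29	29	35	7	7	2.62e-2	2.62e-2	321
ROSMAP	GOBP	342	320	490	77	73	5.11e-4	4.82e-4	3062
ROSMAP	GOMF	103	90	110	28	28	1.44e-3	1.09e-4	678
COVID Urine	HALLMARK	4	4	8	0	0	1	1	46
COVID Urine	KEGG	31	37	12	1	4	9.64e-1	4.33e-1	134
COVID Urine	REACTOME	23	19	18	1	1	9.12e-1	8.62e-1	191
COVID Urine	GOBP	267	215	157	13	14	7.81e-1	3.51e-1	2732
COVID Urine	GOMF	73	74	29	4	5	6.37e-1	4.35e-1	499
COVID Serum	HALLMARK	4	6	2	0	0	1	1	44
COVID Serum	KEGG	22	17	4	1	1	7.21e-1	6.13e-1	82
COVID Serum	REACTOME	13	15	14	1	1	9.27e-1	9.53e-1	83
COVID Serum	GOBP	187	162	55	4	3	7.55e-1	8.24e-1	2050
COVID Serum	GOMF	49	53	5	1	2	6.59e-1	2.78e-1	255
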