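dataset	de_metabolites	mapped_nd	mapped_d	de_genes	overlap_nd	overlap_d	p_nd	p_d	background
EMT	169	211	175	698	124	107	6.77e-3	1.99e-3	1376
Serine Starvation	36	672	577	833	273	233	2.14e-3	7.63e-3	2309
NECS Age	291	118	98	142	33	28	1.10e-2	1.45e-5	722
NECS EL	274	132	102	142	34	26	3.63e-2	7.45e-2	722
M005 Kidney	328	331	271	150	50	42	7.17e-4	1.34e-4	1482
M005 Liver	227	322	275	402	122	108	4.50e-2	2.27e-2	1291
M005 Gastroc	227	74	49	28	2	2	7.76e-1	5.49e-1	762
M005 Plasma	143	40	34	55	20	15	1.04e-2	1.04e-1	164
ROSMAP	61	169	128	152	23	11	2.99e-2	6.46e-1	1652
COVID Urine	367	163	125	94	28	26	4.89e-3	3.25e-5	859
COVID Serum	384	108	95	20	7	7	6.20e-1	4.52e-1	301
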