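amino_acid	codon	k	hb_rscu	hb_rfsc	hb_hf_mark	jc_rscu	jc_rfsc	jc_hf_mark	me_rscu	me_rfsc	me_hf_mark	rc_rscu	rc_rfsc	rc_hf_mark	anomaly
A	GCU	4	1.27	31.66	0	0.90	22.52	0	1.37	34.26	0	1.33	33.33	0	0
A	GCC	4	0.76	18.92	0	0.54	13.51	0	0.51	12.75	0	0.43	10.64	0	0
A	GCA	4	1.84	45.95	1	2.09	52.26	1	1.83	45.82	1	1.90	47.52	1	0
A	GCG	4	0.14	3.47	0	0.47	11.71	0	0.29	7.17	0	0.34	8.51	0	0
C	UGU	2	1.03	51.55	0	1.13	56.60	0	0.86	43.09	0	0.88	43.94	0	0
C	UGC	2	0.97	48.45	0	0.87	43.40	0	1.14	56.91	0	1.12	56.06	0	0
D	GAU	2	1.45	72.49	1	1.28	63.86	1	1.37	63.33	1	1.45	72.45	1	0
D	GAC	2	0.55	27.51	0	0.72	36.14	0	0.51	36.67	0	0.55	27.55	0	0
E	GAA	2	1.20	59.89	0	1.35	67.35	1	1.83	62.87	1	1.27	63.64	1	0
E	GAG	2	0.80	40.11	0	0.65	32.65	0	0.29	37.13	0	0.73	36.36	0	0
F	UUU	2	1.00	50.22	0	0.98	49.17	0	1.05	52.27	0	1.02	51.16	0	0
F	UUC	2	1.00	49.78	0	1.02	50.83	0	0.95	47.73	0	0.98	48.84	0	0
G	GGU	4	1.17	29.28	0	1.35	33.87	0	1.06	26.53	0	1.16	29.03	0	0
G	GGC	4	0.78	19.42	0	0.52	12.90	0	0.72	17.96	0	0.77	19.35	0	0
G	GGA	4	1.37	34.20	0	1.52	37.91	1	1.36	33.88	0	1.34	33.56	0	0
G	GGG	4	0.68	17.10	0	0.61	15.32	0	0.87	21.63	0	0.72	18.06	0	0
H	CAU	2	0.95	47.37	0	1.02	50.79	0	1.05	64.43	1	1.27	63.53	1	0
H	CAC	2	1.05	52.63	0	0.98	49.21	0	0.90	35.57	0	0.73	36.47	0	0
I	AUU	3	1.11	37.15	0	1.10	36.62	0	1.09	36.44	0	1.11	37.02	0	0
I	AUC	3	1.08	35.97	0	0.93	30.99	0	1.09	36.44	0	1.07	35.71	0	0
I	AUA	3	0.81	26.88	0	0.97	32.39	0	0.81	27.12	0	0.82	27.27	0	0
K	AAA	2	0.84	41.83	0	0.96	47.95	0	1.57	46.34	0	0.94	47.19	0	0
K	AAG	2	1.16	58.17	0	1.04	52.05	0	0.43	53.66	0	1.06	52.81	0	0
L	UUA	6	0.73	12.14	0	0.92	15.35	0	0.58	9.64	0	0.74	12.26	0	0
L	UUG	6	0.87	14.47	0	0.85	14.17	0	0.92	15.30	0	1.06	17.62	0	0
L	CUU	6	1.69	28.18	1	1.84	30.72	1	1.47	24.53	0	1.52	25.29	1	0
L	CUC	6	1.02	17.05	0	0.83	13.78	0	1.17	19.50	0	0.78	13.03	0	0
L	CUA	6	0.73	12.14	0	0.59	9.84	0	0.72	11.95	0	0.90	14.94	0	0
L	CUG	6	0.96	16.02	0	0.97	16.14	0	1.14	19.08	0	1.01	16.86	0	0
M	AUG	1	1.00	100.00	0	1.00	100.00	0	1.00	100.00	0	1.00	100.00	0	0
N	AAU	2	1.19	59.32	0	1.16	58.00	0	1.18	50.19	0	0.95	47.59	0	0
N	AAC	2	0.81	40.68	0	0.84	42.00	0	0.82	49.81	0	1.05	52.41	0	0
P	CCU	4	1.39	34.80	0	1.12	27.91	0	1.05	26.25	0	1.33	33.33	0	0
P	CCC	4	0.53	13.17	0	0.68	17.05	0	0.90	22.50	0	0.68	17.01	0	0
P	CCA	4	1.81	45.13	1	1.71	42.64	1	1.75	43.75	1	1.74	43.54	1	0
P	CCG	4	0.28	6.90	0	0.50	12.40	0	0.30	7.50	0	0.24	6.12	0	0
Q	CAA	2	1.21	60.68	1	1.25	62.58	1	1.75	58.77	0	1.24	61.88	1	0
Q	CAG	2	0.79	39.32	0	0.75	37.42	0	0.30	41.23	0	0.76	38.12	0	0
R	CGU	6	0.61	10.14	0	0.53	8.82	0	0.59	9.82	0	0.42	7.06	0	0
R	CGC	6	0.37	6.20	0	0.18	2.94	0	0.18	2.98	0	0.32	5.29	0	0
R	CGA	6	0.49	8.17	0	0.42	7.06	0	0.68	11.31	0	0.32	5.29	0	0
R	CGG	6	0.25	4.23	0	0.46	7.65	0	0.27	4.46	0	0.25	4.12	0	0
R	AGA	6	2.74	45.63	1	3.25	54.12	1	2.68	44.64	1	3.28	54.71	1	0
R	AGG	6	1.54	25.63	1	1.16	19.41	0	1.61	26.79	1	1.41	23.53	0	0
S	UCU	6	1.44	23.94	0	1.40	23.31	0	1.29	21.49	0	1.31	21.77	0	0
S	UCC	6	0.72	11.97	0	0.94	15.68	0	0.88	14.68	0	0.83	13.88	0	0
S	UCA	6	1.43	23.77	0	1.37	22.88	0	1.54	25.74	1	1.61	26.81	1	0
S	UCG	6	0.25	4.23	0	0.25	4.24	0	0.27	4.47	0	0.25	4.10	0	0
S	AGU	6	0.98	16.37	0	0.71	11.86	0	0.88	14.68	0	0.93	15.46	0	0
S	AGC	6	1.18	19.72	0	1.32	22.03	0	1.14	18.94	0	1.08	17.98	0	0
T	ACU	4	1.50	37.50	1	1.51	37.80	1	1.18	29.57	0	1.62	40.47	1	0
T	ACC	4	0.80	20.12	0	0.78	19.51	0	0.82	20.60	0	0.71	17.67	0	0
T	ACA	4	1.35	33.84	0	1.39	34.76	0	1.57	39.20	1	1.47	36.74	0	0
T	ACG	4	0.34	8.54	0	0.32	7.93	0	0.43	10.63	0	0.20	5.12	0	0
V	GUU	4	1.47	36.81	0	1.46	36.43	0	1.37	34.34	0	1.24	31.01	0	0
V	GUC	4	0.60	15.00	0	0.85	21.19	0	0.57	14.35	0	0.68	17.05	0	0
V	GUA	4	0.75	18.64	0	0.58	14.41	0	0.71	17.83	0	1.15	28.68	0	0
V	GUG	4	1.18	29.55	0	1.12	27.97	0	1.34	33.48	0	0.93	23.26	0	0
W	UGG	1	1.00	100.00	0	1.00	100.00	0	1.00	100.00	0	1.00	100.00	0	0
Y	UAU	2	1.07	53.38	0	0.98	49.18	0	1.29	49.14	0	1.10	55.07	0	0
Y	UAC	2	0.93	46.62	0	1.02	50.82	0	0.88	50.86	0	0.90	44.93	0	0
TER	UGA	3	1.95	65.00	1	1.38	2.54	0	1.55	51.79	1	1.58	52.81	1	1
TER	UAA	3	0.79	26.25	0	0.95	57.00	1	1.54	29.50	0	0.91	30.34	0	1
TER	UAG	3	0.26	8.75	0	0.67	40.46	0	0.27	18.71	0	0.51	16.85	0	1
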