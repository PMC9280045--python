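amino_acid	codon	hb_at	hb_nt	hb_pt	hb_os	jc_at	jc_nt	jc_pt	jc_os	me_at	me_nt	me_pt	me_os	rc_at	rc_nt	rc_pt	rc_os
A	GCU	0.53	0.48	0.68	0.76	0.33	0.30	0.43	0.48	0.60	0.54	0.77	0.86	0.54	0.49	0.70	0.78
A	GCC	0.87	0.72	0.91	0.29	0.55	0.45	0.58	0.18	0.61	0.50	0.64	0.20	0.48	0.39	0.50	0.16
A	GCA	1.24	0.94	1.08	1.26	1.25	0.94	1.08	1.26	1.29	0.98	1.12	1.31	1.25	0.95	1.09	1.27
A	GCG	0.18	0.28	0.44	0.06	0.54	0.84	1.32	0.18	0.39	0.61	0.96	0.13	0.44	0.68	1.06	0.15
C	UGU	0.87	0.93	0.82	1.47	1.07	1.15	1.01	1.82	0.99	1.06	0.93	1.68	0.90	0.97	0.85	1.53
C	UGC	1.19	1.19	0.97	0.69	1.20	1.20	0.97	0.70	1.91	1.91	1.55	1.11	1.68	1.68	1.36	0.98
D	GAU	0.68	0.68	0.60	0.99	0.54	0.54	0.48	0.79	0.51	0.51	0.45	0.74	0.63	0.63	0.56	0.92
D	GAC	0.55	0.56	0.66	0.34	0.66	0.67	0.79	0.40	0.63	0.64	0.76	0.38	0.51	0.52	0.62	0.31
E	GAA	1.16	1.11	0.98	1.85	1.09	1.03	0.92	1.72	1.11	1.05	0.94	1.76	1.07	1.02	0.91	1.70
E	GAG	0.83	0.91	0.82	0.69	0.56	0.61	0.56	0.47	0.70	0.76	0.69	0.58	0.65	0.71	0.64	0.54
F	UUU	0.95	0.82	0.80	1.58	1.02	0.88	0.86	1.69	1.04	0.90	0.87	1.73	0.99	0.86	0.83	1.65
F	UUC	0.99	1.14	1.17	0.91	1.11	1.27	1.31	1.02	1.00	1.15	1.18	0.92	1.00	1.15	1.18	0.92
G	GGU	0.83	0.83	1.03	1.25	0.71	0.71	0.88	1.07	0.58	0.57	0.71	0.86	0.66	0.66	0.82	1.00
G	GGC	1.33	1.09	1.20	0.42	0.65	0.54	0.59	0.20	0.94	0.77	0.85	0.29	1.07	0.88	0.96	0.33
G	GGA	0.89	0.93	0.95	1.36	0.73	0.76	0.78	1.11	0.67	0.70	0.72	1.03	0.70	0.73	0.75	1.07
G	GGG	1.06	1.03	0.94	0.63	0.70	0.68	0.62	0.42	1.02	0.99	0.91	0.61	0.90	0.87	0.80	0.54
H	CAU	1.07	1.11	0.93	1.31	0.87	0.90	0.76	1.06	1.37	1.41	1.19	1.67	1.28	1.32	1.11	1.56
H	CAC	1.89	1.89	1.98	1.19	1.34	1.34	1.40	0.84	1.20	1.20	1.26	0.75	1.17	1.17	1.22	0.74
I	AUU	0.80	0.62	0.59	1.21	0.91	0.70	0.67	1.38	0.82	0.64	0.60	1.25	0.87	0.67	0.64	1.31
I	AUC	0.90	1.20	1.09	0.86	0.89	1.19	1.09	0.85	0.96	1.27	1.16	0.91	0.97	1.30	1.18	0.93
I	AUA	0.99	0.89	0.83	1.41	1.37	1.24	1.15	1.97	1.05	0.94	0.88	1.50	1.09	0.98	0.92	1.56
K	AAA	0.65	0.62	0.59	1.26	1.00	0.95	0.90	1.93	0.85	0.80	0.77	1.63	0.89	0.84	0.81	1.72
K	AAG	0.86	0.84	0.86	0.87	1.02	1.00	1.03	1.04	0.93	0.90	0.93	0.94	0.94	0.92	0.95	0.95
L	UUA	0.68	0.64	0.58	1.41	1.15	1.09	0.98	2.40	0.71	0.67	0.61	1.48	0.82	0.78	0.70	1.72
L	UUG	0.49	0.46	0.40	0.70	0.65	0.61	0.53	0.92	0.69	0.64	0.56	0.98	0.72	0.68	0.59	1.02
L	CUU	0.83	0.83	0.69	1.31	1.22	1.22	1.01	1.93	0.95	0.96	0.79	1.51	0.90	0.90	0.74	1.42
L	CUC	0.75	0.98	0.86	0.47	0.82	1.07	0.93	0.51	1.14	1.49	1.30	0.71	0.69	0.90	0.79	0.43
L	CUA	0.87	0.91	0.71	1.12	0.95	1.00	0.78	1.22	1.13	1.19	0.93	1.45	1.29	1.36	1.06	1.66
L	CUG	1.16	1.11	0.77	0.54	1.57	1.51	1.05	0.73	1.83	1.75	1.22	0.85	1.47	1.41	0.98	0.69
M	AUG	1.00	0.98	1.04	1.03	0.84	0.83	0.88	0.87	1.12	1.09	1.16	1.15	0.99	0.97	1.03	1.02
N	AAU	1.57	1.25	1.26	2.31	1.47	1.17	1.18	2.17	1.15	0.91	0.92	1.69	1.16	0.92	0.93	1.71
N	AAC	1.15	1.34	1.54	1.29	1.13	1.32	1.52	1.28	1.21	1.42	1.63	1.37	1.36	1.59	1.83	1.54
P	CCU	1.09	1.09	1.27	1.49	0.72	0.72	0.85	1.00	0.66	0.66	0.77	0.91	0.86	0.86	1.00	1.18
P	CCC	1.45	1.16	1.48	0.63	1.56	1.25	1.59	0.68	2.00	1.61	2.04	0.88	1.54	1.24	1.57	0.68
P	CCA	1.64	1.33	1.58	1.85	1.28	1.04	1.24	1.46	1.28	1.04	1.24	1.45	1.30	1.06	1.25	1.48
P	CCG	0.47	0.80	1.01	0.22	0.70	1.20	1.50	0.33	0.41	0.71	0.88	0.20	0.34	0.59	0.74	0.16
Q	CAA	2.01	1.88	1.86	2.88	1.88	1.76	1.74	2.70	1.83	1.72	1.70	2.64	1.89	1.77	1.75	2.72
Q	CAG	1.66	1.68	1.43	1.21	1.43	1.45	1.24	1.05	1.64	1.66	1.42	1.20	1.49	1.51	1.28	1.09
R	CGU	0.73	0.88	0.89	0.91	0.63	0.75	0.76	0.78	0.72	0.86	0.88	0.90	0.44	0.52	0.53	0.55
R	CGC	1.06	1.03	0.89	0.25	0.49	0.48	0.42	0.12	0.52	0.50	0.44	0.12	0.78	0.76	0.65	0.18
R	CGA	0.84	1.00	0.96	0.83	0.72	0.85	0.82	0.70	1.19	1.41	1.36	1.17	0.47	0.56	0.54	0.46
R	CGG	0.56	0.74	0.48	0.20	1.00	1.32	0.86	0.36	0.60	0.80	0.52	0.22	0.47	0.62	0.40	0.17
R	AGA	1.56	1.85	1.51	2.82	1.82	2.16	1.76	3.29	1.55	1.84	1.50	2.81	1.60	1.90	1.55	2.90
R	AGG	1.51	1.36	1.31	1.04	1.13	1.02	0.98	0.78	1.61	1.45	1.39	1.11	1.19	1.07	1.03	0.82
S	AGU	1.21	1.28	1.13	1.93	0.75	0.79	0.70	1.20	0.97	1.02	0.90	1.54	1.15	1.21	1.06	1.82
S	AGC	1.81	2.05	1.81	1.28	1.73	1.95	1.73	1.22	1.55	1.75	1.55	1.09	1.65	1.87	1.65	1.17
S	UCU	0.99	1.24	1.21	1.96	0.82	1.03	1.01	1.63	0.79	0.99	0.97	1.56	0.90	1.13	1.10	1.78
S	UCC	1.11	1.22	1.45	0.76	1.24	1.36	1.62	0.85	1.21	1.33	1.58	0.83	1.29	1.41	1.67	0.88
S	UCA	1.35	1.40	1.25	1.99	1.11	1.15	1.03	1.64	1.30	1.35	1.21	1.92	1.52	1.58	1.41	2.24
S	UCG	0.47	0.83	0.88	0.36	0.40	0.71	0.75	0.31	0.44	0.78	0.83	0.34	0.46	0.80	0.85	0.35
T	ACU	1.29	1.11	1.56	2.12	1.33	1.15	1.62	2.20	1.00	0.86	1.21	1.65	1.63	1.40	1.98	2.69
T	ACC	1.17	1.24	1.45	0.81	1.17	1.24	1.45	0.81	1.18	1.26	1.47	0.82	1.21	1.28	1.50	0.83
T	ACA	1.29	1.17	1.33	1.75	1.36	1.23	1.40	1.85	1.48	1.33	1.52	2.00	1.65	1.49	1.69	2.23
T	ACG	0.66	1.14	1.16	0.45	0.63	1.09	1.11	0.43	0.82	1.40	1.43	0.55	0.47	0.80	0.82	0.32
V	GUU	0.54	0.55	0.61	0.96	0.59	0.60	0.67	1.04	0.57	0.58	0.64	1.00	0.48	0.49	0.54	0.84
V	GUC	0.47	0.54	0.53	0.30	0.73	0.85	0.83	0.47	0.51	0.58	0.57	0.32	0.56	0.65	0.64	0.36
V	GUA	0.76	0.66	0.73	1.10	0.65	0.56	0.63	0.94	0.81	0.71	0.79	1.19	1.22	1.06	1.19	1.78
V	GUG	0.68	0.71	0.70	0.49	0.71	0.74	0.73	0.51	0.87	0.91	0.90	0.62	0.56	0.59	0.58	0.40
W	UGG	1.33	1.36	1.20	1.21	1.68	1.73	1.51	1.53	1.48	1.51	1.33	1.34	1.44	1.48	1.30	1.30
Y	UAU	0.99	0.81	0.89	1.44	0.77	0.63	0.69	1.13	0.77	0.63	0.69	1.12	0.85	0.70	0.76	1.24
Y	UAC	0.92	0.93	1.33	0.84	0.85	0.86	1.23	0.77	0.85	0.86	1.22	0.77	0.74	0.75	1.07	0.67
TER	UAA	4.27	3.49	9.60	5.49	12.95	10.59	29.14	16.65	8.95	7.33	20.15	11.51	9.82	8.03	22.09	12.63
TER	UAG	2.56	2.56	3.20	1.60	16.54	16.54	20.68	10.34	10.22	10.22	12.78	6.39	9.82	9.82	12.27	6.14
TER	UGA	7.92	9.51	13.58	7.92	14.10	16.92	24.17	14.10	11.79	14.15	20.22	11.79	12.82	15.38	21.98	12.82
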