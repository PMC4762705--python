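patient	d_ap	d_lr	d_ud	pitch	roll	yaw
1	-1.28	0.23	1.95	3.32	0.61	-0.07
2	-0.71	0.35	-0.45	-1.23	0.11	-3.39
3	-3.03	0.44	0.20	3.51	-0.36	1.54
4	-0.06	-0.84	-0.08	-0.86	0.55	1.59
5	3.61	-0.14	-1.17	5.81	0.81	-1.00
6	0.36	1.17	-0.13	1.27	1.73	-1.06
7	-0.05	1.41	3.92	-6.71	-0.75	-0.29
8	-2.25	1.21	1.06	0.17	-1.31	0.76
9	-0.21	-0.43	1.74	2.35	-1.48	0.06
10	-0.10	0.25	2.50	2.30	-0.68	1.56
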