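patient	d_ap	d_lr	d_ud	pitch	roll	yaw
1	-1.44	0.04	1.19	2.60	-0.73	1.00
2	-0.41	0.17	-1.52	-1.67	-2.23	0
3	-2.63	0.11	-0.68	2.34	-1.75	3.22
4	0.03	-0.16	-2.85	3.82	-0.04	0.22
5	3.71	-0.11	-3.45	5.87	0.79	-0.68
6	1.05	-0.09	-2.33	3.52	1.20	-0.59
7	-0.38	-0.66	2.67	-4.32	0.50	2.20
8	-2.02	1.22	0,26	-0.77	-1.42	-0.58
9	-1.35	1.44	-0.64	1.04	-0.87	-0.49
10	-1.12	0.91	2.88	1.26	-0.82	0.75
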