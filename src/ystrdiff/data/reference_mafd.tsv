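rank	locus	mafd	mutation_rate	ci_low	ci_high	in_yfiler
1	DYS392	0.3802	4.96e-4	2.14e-4	9.77e-4	1
2	DYS438	0.3507	3.51e-4	0.96e-4	8.99e-4	1
3	DYS635	0.3379	4.21e-3	2.97e-3	5.80e-3	1
4	DYS481	0.3359	4.88e-3	2.52e-3	8.51e-3	0
5	DYS449	0.3271	9.44e-3	5.78e-3	1.45e-2	0
6	DYS448	0.3257	1.39e-3	6.92e-4	2.48e-3	1
7	DYS533	0.3104	3.68e-3	1.68e-3	6.97e-3	0
8	DYS19	0.3053	2.20e-3	1.55e-3	3.04e-3	1
9	DYS393	0.2878	1.07e-3	6.11e-4	1.74e-3	1
10	DYS518	0.2786	1.46e-2	9.86e-3	2.08e-2	0
11	DYS627	0.2666	1.32e-2	8.95e-3	1.88e-2	0
12	DYS390	0.2504	2.08e-3	1.44e-3	2.91e-3	1
13	DYS389I	0.2494	2.72e-3	1.96e-3	3.69e-3	1
14	DYS570	0.2372	1.14e-2	7.67e-3	1.62e-2	0
15	DYS458	0.2345	6.17e-3	4.57e-3	8.15e-3	1
16	DYS460	0.2278	5.82e-3	2.80e-3	1.69e-2	0
17	DYS437	0.2273	1.32e-3	7.39e-4	2.18e-3	1
18	DYS439	0.2211	5.46e-3	4.19e-3	6.99e-3	1
19	DYS576	0.2136	1.26e-2	8.86e-3	1.73e-2	0
20	DYS389II	0.2131	4.33e-3	3.34e-3	5.51e-3	1
21	DYS456	0.2106	4.41e-3	3.07e-3	6.12e-3	1
22	DYS391	0.1891	2.53e-3	1.82e-3	3.43e-3	1
23	YGATAH4	0.1845	3.01e-3	1.98e-3	4.38e-3	1
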