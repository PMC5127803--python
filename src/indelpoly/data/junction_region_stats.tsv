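type	locus	indel_size	region	n	length	s_n	fixed_indels	pi_t	pi_fixed	D_xy	d_xy	tajima_d	n_indels	source
RGD	RGD1	4243	5p-4.7kb	21	643	0	0	0.0051	0	NA	0	-0.98	1	sequenced
RGD	RGD1	4243	5p-0.3kb	21	1088	0	0	0.0091	0	NA	0	1.49	1	sequenced
RGD	RGD1	4243	JR	21	600	37	5	0.0366	0.0329	0.0713	0.0628	2.86	1	sequenced
RGD	RGD1	4243	3p-0.3kb	21	1143	19	5	0.0128	0.009	NA	0.0172	1.17	1	sequenced
RGD	RGD1	4243	3p-4.5kb	21	597	0	0	0.0036	0	NA	0	-0.84	1	sequenced
RGD	RGD2	5057	5p-5.7kb	20	601	0	0	0.0144	0	NA	0	-0.72	1	sequenced
RGD	RGD2	5057	5p-2.2kb	21	605	0	0	0.0073	0	NA	0	1.55	1	sequenced
RGD	RGD2	5057	5p-JR	21	618	49	12	0.0517	0.0468	0.0952	0.0894	3.28	1	sequenced
RGD	RGD2	5057	3p-1.4kb	21	532	0	0	0.001	0	NA	0	1.57	1	sequenced
RGD	RGD2	5057	3p-4.3kb	21	719	25	2	0.0202	0.0192	NA	0.0368	2.51	1	sequenced
RGD	RGD2	5057	3p-8.0kb	21	698	0	0	0.0058	0	NA	0	-0.33	1	sequenced
RGD	RGD3	6266	5p-4.9kb	21	553	0	0	0.0046	0	NA	0	0.43	1	sequenced
RGD	RGD3	6266	5p-2.1kb	21	610	8	2	0.028	0.011	NA	0.0223	1.49	1	sequenced
RGD	RGD3	6266	5p-0.3kb	21	1161	9	3	0.0236	0.0144	NA	0.0297	1.6	1	sequenced
RGD	RGD3	6266	JR	21	600	15	3	0.0226	0.0126	0.0387	0.027	2.21	1	sequenced
RGD	RGD3	6266	3p-3.0kb	21	568	0	0	0.0049	0	NA	0	-1.22	1	sequenced
RGD	Rpm1	3764	JR	28	600	37	10	0.0396	0.0373	0.0799	0.073	3.07	1	genbank
RGD	Rps5	3990	JR	22	600	24	3	0.026	0.0219	0.0497	0.0423	2.62	1	genbank
NRD	NRD1	4524	JR	21	600	4	0	0.0092	0.0035	0.0115	0.0067	0.84	1	sequenced
NRD	NRD2	5584	JR	17	600	14	3	0.0197	0.0109	0.0332	0.0233	1.77	1	sequenced
NRD	NRD3	1076	JR	17	600	27	1	0.0287	0.0261	0.051	0.0417	2.51	1	sequenced
NRD	NRD4	807	JR	9	600	31	11	0.0268	0.0247	0.031	0.0417	2.31	1	sequenced
NRD	NRD5	404	JR	9	600	11	5	0.0123	0.0038	0.0192	0.0069	1.03	1	sequenced
NRD	NRD6	101	JR	9	600	30	4	0.0067	0.0056	0.0118	0.01	1.71	1	sequenced
NRD	NRD7	578	JR	8	600	5	1	0.0078	0	0.0101	0	0.47	1	sequenced
NRD	NRD8	121	JR	9	600	3	0	0.0138	0.0009	0.0139	0.0017	-1.80	1	sequenced
NRD	NRD9	135	JR	9	600	34	6	0.019	0.014	0.032	0.0252	1.65	1	sequenced
NRD	NRD10	1001	JR	9	600	2	1	0.0042	0.0009	0.0052	0.0017	-1.13	1	sequenced
NRD	NRD11	1397	JR	9	600	9	5	0.0057	0.0019	0.0083	0.0034	0.6	1	sequenced
NRD	NRD12	304	JR	9	600	8	0	0.0128	0.0047	0.0166	0.0084	-0.04	1	sequenced
NRD	NRD13	238/501	JR	9	600	NA	NA	0.0133	NA	NA	NA	0.39	2	sequenced
NRD	NRD14	345/340	JR	8	600	NA	NA	0.0089	NA	NA	NA	-1.18	2	sequenced
NRD	NRD15	205/335	JR	9	600	NA	NA	0.0058	NA	NA	NA	-0.89	2	sequenced
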