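gene	rho	p_value	p_adj	direction
MYBL2	0.574	3.86E-92	1.36E-87	pos
E2F2	0.538	5.92E-79	5.2E-75	pos
E2F1	0.485	2.15E-62	2.47E-59	pos
ZBED4	0.474	2.59E-59	2.02E-56	pos
TCF3	0.453	9.19E-54	3.63E-51	pos
FOXM1	0.433	9.84E-49	2.74E-46	pos
E2F8	0.432	1.99E-48	5.31E-46	pos
ZNF296	0.431	2.47E-48	6.46E-46	pos
ZNF367	0.418	2.95E-45	5.85E-43	pos
HMGB2	0.411	1.29E-43	2.14E-41	pos
MTA2	0.406	1.55E-42	2.27E-40	pos
PURA	-0.466	4.65E-57	2.57E-54	neg
AR	-0.462	4.42E-56	2.19E-53	neg
ZNF641	-0.422	3.17E-46	6.83E-44	neg
NFIC	-0.412	6.33E-44	1.07E-41	neg
ZNF25	-0.409	4.02E-43	6.25E-41	neg
NFIA	-0.408	5.57E-43	8.46E-41	neg
ZFPM2	-0.404	4.2E-42	5.9E-40	neg
CREBL2	-0.400	3.05E-41	3.97E-39	neg
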