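snp	test_allele	ref_allele	phase	phenotype	or_point	ci_low	ci_high	pvalue
rs11546155	A	G	U4C	overall	1.13	1.05	1.21	7.0E-04
rs11546155	A	G	U4C	er_negative	1.28	1.14	1.44	5.0E-05
rs11546155	A	G	GAME-ON	overall	1.05	0.99	1.10	0.11
rs11546155	A	G	GAME-ON	er_negative	1.13	1.03	1.25	0.013
rs1205339	G	A	U4C	overall	1.11	1.05	1.18	4.1E-04
rs1205339	G	A	U4C	er_negative	1.22	1.11	1.35	8.0E-05
rs1205339	G	A	GAME-ON	overall	1.02	0.98	1.07	0.3
rs1205339	G	A	GAME-ON	er_negative	1.09	1.01	1.17	0.021
rs4911154	A	G	U4C	overall	1.13	1.06	1.20	1.6E-04
rs4911154	A	G	U4C	er_negative	1.25	1.12	1.39	5.5E-05
rs4911154	A	G	GAME-ON	overall	1.02	0.98	1.07	0.31
rs4911154	A	G	GAME-ON	er_negative	1.09	1.01	1.17	0.02
rs6058107	C	T	U4C	overall	0.90	0.85	0.95	1.5E-04
rs6058107	C	T	U4C	er_negative	0.90	0.82	0.98	0.021
rs6058107	C	T	GAME-ON	overall	0.96	0.92	1.00	0.045
rs6058107	C	T	GAME-ON	er_negative	0.91	0.85	0.97	5.0E-03
rs6060047	G	T	U4C	overall	0.90	0.85	0.95	2.1E-04
rs6060047	G	T	U4C	er_negative	0.82	0.75	0.91	1.2E-04
rs6060047	G	T	GAME-ON	overall	0.96	0.91	1.00	0.066
rs6060047	G	T	GAME-ON	er_negative	0.90	0.84	0.97	7.7E-03
rs8116198	G	A	U4C	overall	0.93	0.81	1.07	0.33
rs8116198	G	A	U4C	er_negative	1.04	0.78	1.40	0.79
rs8116198	G	A	GAME-ON	overall	0.97	0.91	1.03	0.28
rs8116198	G	A	GAME-ON	er_negative	0.94	0.84	1.05	0.28
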