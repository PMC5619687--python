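snp	chrom	pos	test_allele	ref_allele	phenotype	study	or_point	ci_low	ci_high	pvalue
rs1205339	20	32924967	G	A	er_negative	BPC3	1.17	1.05	1.31	5.9E-03
rs1205339	20	32924967	G	A	er_negative	AABC	1.29	1.12	1.50	5.6E-04
rs1205339	20	32924967	G	A	er_negative	ROOT	1.39	1.10	1.76	5.6E-03
rs1205339	20	32924967	G	A	er_negative	SBCGS	1.06	0.89	1.26	0.51
rs1205339	20	32924967	G	A	er_negative	meta	1.20	1.11	1.29	1.8E-06
rs1205339	20	32924967	G	A	overall	CGEMS	1.05	0.91	1.23	0.49
rs1205339	20	32924967	G	A	overall	AABC	1.14	1.03	1.27	0.013
rs1205339	20	32924967	G	A	overall	ROOT	1.19	1.04	1.36	0.012
rs1205339	20	32924967	G	A	overall	SBCGS	1.07	0.97	1.18	0.18
rs1205339	20	32924967	G	A	overall	meta	1.11	1.05	1.18	4.2E-04
rs4911154	20	32996101	A	G	er_negative	BPC3	1.16	1.04	1.30	0.01
rs4911154	20	32996101	A	G	er_negative	AABC	1.32	1.14	1.54	2.9E-04
rs4911154	20	32996101	A	G	er_negative	ROOT	1.39	1.09	1.78	8.3E-03
rs4911154	20	32996101	A	G	er_negative	SBCGS	1.06	0.88	1.28	0.54
rs4911154	20	32996101	A	G	er_negative	meta	1.20	1.11	1.30	2.6E-06
rs4911154	20	32996101	A	G	overall	CGEMS	1.04	0.89	1.21	0.65
rs4911154	20	32996101	A	G	overall	AABC	1.15	1.03	1.28	0.014
rs4911154	20	32996101	A	G	overall	ROOT	1.23	1.07	1.42	3.5E-03
rs4911154	20	32996101	A	G	overall	SBCGS	1.09	0.98	1.21	0.11
rs4911154	20	32996101	A	G	overall	meta	1.13	1.06	1.20	1.6E-04
rs8116198	20	33114201	G	A	er_negative	BPC3	0.92	0.80	1.05	0.21
rs8116198	20	33114201	G	A	er_negative	AABC	1.11	0.79	1.57	0.54
rs8116198	20	33114201	G	A	er_negative	ROOT	0.87	0.49	1.54	0.63
rs8116198	20	33114201	G	A	er_negative	meta	0.92	0.80	1.04	0.30
rs8116198	20	33114201	G	A	overall	CGEMS	0.94	0.78	1.13	0.5
rs8116198	20	33114201	G	A	overall	AABC	1.04	0.82	1.33	0.73
rs8116198	20	33114201	G	A	overall	ROOT	0.67	0.45	1.00	0.052
rs8116198	20	33114201	G	A	overall	meta	0.93	0.81	1.07	0.33
rs6058107	20	33288546	C	T	er_negative	BPC3	0.87	0.78	0.97	8.7E-03
rs6058107	20	33288546	C	T	er_negative	AABC	0.84	0.73	0.96	0.014
rs6058107	20	33288546	C	T	er_negative	ROOT	0.80	0.64	0.99	0.041
rs6058107	20	33288546	C	T	er_negative	SBCGS	1.03	0.88	1.20	0.71
rs6058107	20	33288546	C	T	er_negative	meta	0.90	0.83	0.97	5.0E-04
rs6058107	20	33288546	C	T	overall	CGEMS	0.92	0.80	1.06	0.27
rs6058107	20	33288546	C	T	overall	AABC	0.91	0.83	1.01	0.072
rs6058107	20	33288546	C	T	overall	ROOT	0.83	0.73	0.94	4.00E-03
rs6058107	20	33288546	C	T	overall	SBCGS	0.92	0.84	1.00	0.057
rs6058107	20	33288546	C	T	overall	meta	0.90	0.85	0.95	1.4E-04
rs6060047	20	33367400	G	T	er_negative	BPC3	0.87	0.77	0.97	0.017
rs6060047	20	33367400	G	T	er_negative	AABC	0.75	0.65	0.86	7.5E-05
rs6060047	20	33367400	G	T	er_negative	ROOT	0.76	0.60	0.96	0.019
rs6060047	20	33367400	G	T	er_negative	SBCGS	0.98	0.83	1.16	0.81
rs6060047	20	33367400	G	T	er_negative	meta	0.84	0.78	0.91	7.3E-06
rs6060047	20	33367400	G	T	overall	CGEMS	0.91	0.78	1.07	0.27
rs6060047	20	33367400	G	T	overall	AABC	0.88	0.79	0.98	0.016
rs6060047	20	33367400	G	T	overall	ROOT	0.83	0.73	0.95	6.10E-03
rs6060047	20	33367400	G	T	overall	SBCGS	0.94	0.86	1.03	0.21
rs6060047	20	33367400	G	T	overall	meta	0.90	0.85	0.95	2.1E-04
rs11546155	20	33451148	A	G	er_negative	BPC3	1.19	1.04	1.35	9.1E-03
rs11546155	20	33451148	A	G	er_negative	AABC	1.32	1.14	1.54	3.3E-04
rs11546155	20	33451148	A	G	er_negative	ROOT	1.18	0.93	1.51	0.18
rs11546155	20	33451148	A	G	er_negative	SBCGS	1.26	0.94	1.70	0.13
rs11546155	20	33451148	A	G	er_negative	meta	1.23	1.13	1.35	2.0E-06
rs11546155	20	33451148	A	G	overall	CGEMS	1.12	0.94	1.34	0.21
rs11546155	20	33451148	A	G	overall	AABC	1.14	1.02	1.27	0.023
rs11546155	20	33451148	A	G	overall	ROOT	1.11	0.96	1.28	0.15
rs11546155	20	33451148	A	G	overall	SBCGS	1.16	0.98	1.38	0.089
rs11546155	20	33451148	A	G	overall	meta	1.13	1.05	1.21	7.0E-04
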