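gene	cytoband	n_model_snps	study	zscore	pvalue	fdr
TP53INP2	20q11.22	6	AABC	-3.708	2.09E-04	NA
TP53INP2	20q11.22	6	BPC3	-2.919	3.51E-03	NA
TP53INP2	20q11.22	6	ROOT	-2.703	6.87E-03	NA
TP53INP2	20q11.22	6	SBCGS	-0.417	6.77E-01	NA
TP53INP2	20q11.22	6	meta	-5.013	5.35E-07	0.0062
HP	16q22.2	20	AABC	1.424	1.54E-01	NA
HP	16q22.2	20	BPC3	3.302	9.61E-04	NA
HP	16q22.2	20	ROOT	1.851	6.41E-02	NA
HP	16q22.2	20	SBCGS	1.749	8.03E-02	NA
HP	16q22.2	20	meta	4.300	1.70E-05	0.098
DHODH	16q22.2	58	AABC	-1.121	2.62E-01	NA
DHODH	16q22.2	58	BPC3	-4.700	2.61E-06	NA
DHODH	16q22.2	58	ROOT	1.020	3.08E-01	NA
DHODH	16q22.2	58	SBCGS	-1.859	6.31E-02	NA
DHODH	16q22.2	58	meta	-4.119	3.80E-05	0.15
YJEFN3	19p13.11	20	AABC	-2.650	8.05E-03	NA
YJEFN3	19p13.11	20	BPC3	-2.797	5.16E-03	NA
YJEFN3	19p13.11	20	ROOT	0.154	8.78E-01	NA
YJEFN3	19p13.11	20	SBCGS	-1.549	1.21E-01	NA
YJEFN3	19p13.11	20	meta	-3.810	1.39E-04	0.34
MAP1LC3A	20q11.22	49	AABC	-2.077	3.78E-02	NA
MAP1LC3A	20q11.22	49	BPC3	-2.922	3.48E-03	NA
MAP1LC3A	20q11.22	49	ROOT	-1.751	7.99E-02	NA
MAP1LC3A	20q11.22	49	SBCGS	-0.157	8.75E-01	NA
MAP1LC3A	20q11.22	49	meta	-3.734	1.88E-04	0.34
DPY19L1	7p14.2	24	AABC	2.188	2.87E-02	NA
DPY19L1	7p14.2	24	BPC3	3.035	2.41E-03	NA
DPY19L1	7p14.2	24	ROOT	0.672	5.01E-01	NA
DPY19L1	7p14.2	24	SBCGS	0.791	4.29E-01	NA
DPY19L1	7p14.2	24	meta	3.731	1.91E-04	0.34
GCOM1	15q21.3	75	AABC	-1.841	6.56E-02	NA
GCOM1	15q21.3	75	BPC3	-3.295	9.85E-04	NA
GCOM1	15q21.3	75	ROOT	-0.854	3.93E-01	NA
GCOM1	15q21.3	75	SBCGS	-0.525	5.99E-01	NA
GCOM1	15q21.3	75	meta	-3.689	2.25E-04	0.34
AMOTL1	11q21	14	AABC	2.155	3.12E-02	NA
AMOTL1	11q21	14	BPC3	2.118	3.42E-02	NA
AMOTL1	11q21	14	ROOT	0.448	6.54E-01	NA
AMOTL1	11q21	14	SBCGS	2.509	1.21E-02	NA
AMOTL1	11q21	14	meta	3.675	2.38E-04	0.34
ITCH	20q11.22	12	AABC	-1.597	1.10E-01	NA
ITCH	20q11.22	12	BPC3	-3.861	1.13E-04	NA
ITCH	20q11.22	12	ROOT	0.203	8.39E-01	NA
ITCH	20q11.22	12	SBCGS	-0.318	7.51E-01	NA
ITCH	20q11.22	12	meta	-3.494	4.77E-04	0.61
TRPC4AP	20q11.22	26	AABC	2.385	1.71E-02	NA
TRPC4AP	20q11.22	26	BPC3	1.899	5.76E-02	NA
TRPC4AP	20q11.22	26	ROOT	2.536	1.12E-02	NA
TRPC4AP	20q11.22	26	SBCGS	0.127	8.99E-01	NA
TRPC4AP	20q11.22	26	meta	3.466	5.28E-04	0.61
SNX24	5q23.2	3	AABC	-0.902	3.67E-01	NA
SNX24	5q23.2	3	BPC3	-2.235	2.54E-02	NA
SNX24	5q23.2	3	ROOT	-1.612	1.07E-01	NA
SNX24	5q23.2	3	SBCGS	-2.022	4.32E-02	NA
SNX24	5q23.2	3	meta	-3.327	8.77E-04	0.91
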