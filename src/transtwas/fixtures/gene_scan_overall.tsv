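gene	cytoband	n_model_snps	study	zscore	pvalue	fdr
TP53INP2	20q11.22	6	AABC	-2.536	1.12E-02	NA
TP53INP2	20q11.22	6	CGEMS	-0.953	3.41E-01	NA
TP53INP2	20q11.22	6	ROOT	-3.023	2.50E-03	NA
TP53INP2	20q11.22	6	SBCGS	-1.683	9.23E-02	NA
TP53INP2	20q11.22	6	meta	-4.180	2.91E-05	0.34
BAG3	10q26.11	18	AABC	-2.109	3.49E-02	NA
BAG3	10q26.11	18	CGEMS	-1.145	2.52E-01	NA
BAG3	10q26.11	18	ROOT	-3.003	2.67E-03	NA
BAG3	10q26.11	18	SBCGS	-1.074	2.83E-01	NA
BAG3	10q26.11	18	meta	-3.660	2.52E-04	0.77
POLN	4p16.3	39	AABC	-2.291	2.20E-02	NA
POLN	4p16.3	39	CGEMS	-2.614	8.96E-03	NA
POLN	4p16.3	39	ROOT	-0.942	3.46E-01	NA
POLN	4p16.3	39	SBCGS	-1.624	1.04E-01	NA
POLN	4p16.3	39	meta	-3.644	2.68E-04	0.77
WDR37	10p15.3	9	AABC	-1.637	1.02E-01	NA
WDR37	10p15.3	9	CGEMS	-0.747	4.55E-01	NA
WDR37	10p15.3	9	ROOT	-0.292	7.70E-01	NA
WDR37	10p15.3	9	SBCGS	-4.144	3.42E-05	NA
WDR37	10p15.3	9	meta	-3.629	2.84E-04	0.77
TTLL5	14q24.3	26	AABC	2.717	6.59E-03	NA
TTLL5	14q24.3	26	CGEMS	2.087	3.69E-02	NA
TTLL5	14q24.3	26	ROOT	1.189	2.35E-01	NA
TTLL5	14q24.3	26	SBCGS	1.206	2.28E-01	NA
TTLL5	14q24.3	26	meta	3.588	3.33E-04	0.77
HP	16q22.2	19	AABC	2.424	1.53E-02	NA
HP	16q22.2	19	CGEMS	1.961	4.99E-02	NA
HP	16q22.2	19	ROOT	1.598	1.10E-01	NA
HP	16q22.2	19	SBCGS	1.147	2.52E-01	NA
HP	16q22.2	19	meta	3.529	4.18E-04	0.77
VTI1B	14q24.1	1	AABC	1.433	1.52E-01	NA
VTI1B	14q24.1	1	CGEMS	2.790	5.28E-03	NA
VTI1B	14q24.1	1	ROOT	0.902	3.67E-01	NA
VTI1B	14q24.1	1	SBCGS	2.151	3.15E-02	NA
VTI1B	14q24.1	1	meta	3.471	5.18E-04	0.77
HLA-DMA	6p21.32	30	AABC	-2.001	4.54E-02	NA
HLA-DMA	6p21.32	30	CGEMS	-0.756	4.50E-01	NA
HLA-DMA	6p21.32	30	ROOT	-1.603	1.09E-01	NA
HLA-DMA	6p21.32	30	SBCGS	-2.293	2.19E-02	NA
HLA-DMA	6p21.32	30	meta	-3.456	5.47E-04	0.77
MYOM2	8p23.3	109	AABC	2.338	1.94E-02	NA
MYOM2	8p23.3	109	CGEMS	-0.051	9.59E-01	NA
MYOM2	8p23.3	109	ROOT	2.153	3.14E-02	NA
MYOM2	8p23.3	109	SBCGS	1.955	5.06E-02	NA
MYOM2	8p23.3	109	meta	3.430	6.04E-04	0.77
MYO9B	19p13.11	6	AABC	1.643	1.00E-01	NA
MYO9B	19p13.11	6	CGEMS	0.887	3.75E-01	NA
MYO9B	19p13.11	6	ROOT	1.473	1.41E-01	NA
MYO9B	19p13.11	6	SBCGS	2.549	1.08E-02	NA
MYO9B	19p13.11	6	meta	3.373	7.44E-04	0.81
ZNF202	11q24.1	15	AABC	2.214	2.69E-02	NA
ZNF202	11q24.1	15	CGEMS	1.675	9.39E-02	NA
ZNF202	11q24.1	15	ROOT	0.003	9.98E-01	NA
ZNF202	11q24.1	15	SBCGS	2.644	8.20E-03	NA
ZNF202	11q24.1	15	meta	3.363	7.71E-04	0.81
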