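study	phenotype	n_cases	n_controls	population
AABC	overall	3016	2745	African American
AABC	er_negative	988	2745	African American
BPC3	er_negative	1998	3263	European American
CGEMS	overall	1142	1145	European American
ROOT	overall	1657	2029	African
ROOT	er_negative	403	2029	African
SBCGS	overall	2790	2176	Asian
SBCGS	er_negative	490	2176	Asian
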