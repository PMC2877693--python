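# Reference NNN inhibition parameters (%), fitted by rank-deficient SVD to
# 112 antisense S-DNA experiments (20-mer targets in CRAF1, BCL2, AKT2 and
# PKC-alpha mRNAs; A549 and T24 cell lines). Values are the published
# two-decimal parameters; individual triplet values are representative only
# (minimum-norm convention) — sums over realizable circular sequences are
# unique. No covariance matrix is published for this table.
[triplets]
AAA	2.98	2.08
AAC	5.96	1.45
AAG	0.48	1.82
AAU	-3.52	1.76
ACA	-3.78	1.67
ACC	4.63	2.79
ACG	1.82	1.69
ACU	3.81	1.66
AGA	3.23	1.99
AGC	3.86	1.46
AGG	4.83	1.82
AGU	-4.72	2.20
AUA	0.29	2.42
AUC	3.27	2.07
AUG	0.45	1.63
AUU	1.05	1.97
CAA	1.83	1.65
CAC	-1.51	1.31
CAG	-1.47	1.49
CAU	5.77	1.62
CCA	-0.99	2.14
CCC	-3.73	2.06
CCG	3.09	1.28
CCU	5.48	1.76
CGA	5.43	1.64
CGC	7.38	1.32
CGG	5.65	1.49
CGU	-5.02	1.96
CUA	13.27	2.79
CUC	1.37	1.75
CUG	0.87	1.75
CUU	-4.62	1.64
GAA	3.57	2.00
GAC	1.08	1.67
GAG	-2.19	1.07
GAU	4.87	1.71
GCA	6.89	1.64
GCC	-1.26	1.57
GCG	3.96	1.59
GCU	6.20	1.91
GGA	2.96	1.10
GGC	-2.70	1.10
GGG	2.06	1.28
GGU	8.28	1.99
GUA	-8.59	2.99
GUC	1.85	1.84
GUG	-3.40	1.46
GUU	10.43	2.95
UAA	-2.48	3.44
UAC	0.94	1.91
UAG	10.37	2.55
UAU	-2.06	2.69
UCA	2.50	1.75
UCC	4.20	1.98
UCG	4.57	2.47
UCU	-4.60	2.60
UGA	-4.28	1.93
UGC	7.26	1.14
UGG	-1.93	1.33
UGU	1.75	2.00
UUA	1.80	3.21
UUC	0.19	2.06
UUG	4.88	2.28
UUU	0.81	2.59
[covariates]
cell:A549	10.59	1.78
gene:AKT2	8.97	4.43
gene:BCL2	-3.10	1.85
gene:CRAF1	3.65	2.33
gene:PKCA	-3.75	2.76
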