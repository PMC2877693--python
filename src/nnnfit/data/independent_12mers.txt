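# 49 circular 12-mer sequences whose overlapping-triplet count vectors are
# linearly independent (a maximal set: the circular triplet count space has
# dimension 64 - 15 = 49). Composition: 4 homopolymers, 6 dinucleotide
# repeats, 20 trinucleotide repeats, 19 tetranucleotide repeats.
(ACU)4	ACUACUACUACU
(UUG)4	UUGUUGUUGUUG
(CG)6	CGCGCGCGCGCG
(AACU)3	AACUAACUAACU
(GGUC)3	GGUCGGUCGGUC
(UGC)4	UGCUGCUGCUGC
(UUAG)3	UUAGUUAGUUAG
(AACG)3	AACGAACGAACG
(AUC)4	AUCAUCAUCAUC
(GGUA)3	GGUAGGUAGGUA
(UCC)4	UCCUCCUCCUCC
(UUGC)3	UUGCUUGCUUGC
(AAGC)3	AAGCAAGCAAGC
(AGC)4	AGCAGCAGCAGC
(CCUG)3	CCUGCCUGCCUG
(CCG)4	CCGCCGCCGCCG
(A)12	AAAAAAAAAAAA
(GGAC)3	GGACGGACGGAC
(ACG)4	ACGACGACGACG
(UUCG)3	UUCGUUCGUUCG
(AAG)4	AAGAAGAAGAAG
(UUCA)3	UUCAUUCAUUCA
(CGG)4	CGGCGGCGGCGG
(G)12	GGGGGGGGGGGG
(GGCA)3	GGCAGGCAGGCA
(AGG)4	AGGAGGAGGAGG
(GGAU)3	GGAUGGAUGGAU
(AAC)4	AACAACAACAAC
(AAUC)3	AAUCAAUCAAUC
(UGG)4	UGGUGGUGGUGG
(U)12	UUUUUUUUUUUU
(ACC)4	ACCACCACCACC
(GGCU)3	GGCUGGCUGGCU
(AG)6	AGAGAGAGAGAG
(UUAC)3	UUACUUACUUAC
(UCG)4	UCGUCGUCGUCG
(AUG)4	AUGAUGAUGAUG
(AUU)4	AUUAUUAUUAUU
(CCAG)3	CCAGCCAGCCAG
(UG)6	UGUGUGUGUGUG
(AU)6	AUAUAUAUAUAU
(AAUG)3	AAUGAAUGAAUG
(AGU)4	AGUAGUAGUAGU
(UC)6	UCUCUCUCUCUC
(AAU)4	AAUAAUAAUAAU
(AC)6	ACACACACACAC
(UUC)4	UUCUUCUUCUUC
(C)12	CCCCCCCCCCCC
(AAGU)3	AAGUAAGUAAGU
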