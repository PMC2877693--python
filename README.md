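# nnnfit

Next-nearest-neighbor (NNN) analysis of antisense inhibition data: fit
triplet and covariate inhibition parameters to cell-culture knockdown
experiments by error-weighted, rank-deficient SVD least squares, and use
them to score and rank candidate mRNA target sites with propagated
uncertainties.

## The problem

Antisense oligodeoxynucleotides (typically 20-mer phosphorothioate DNAs,
"S-DNAs") knock down a gene by hybridizing to its mRNA. Which target sites
work is strongly sequence-dependent, but single positive/negative sequence
motifs are hard to quantify because motifs overlap. The smallest sequence
unit that captures effects *beyond* adjacent base pairs is the
trinucleotide: every position of a target contributes one overlapping
triplet (NNN), so a linear model over the 64 triplet counts encompasses all
overlapping combinations at once.

`nnnfit` is for researchers who have a table of in vivo antisense
experiments — target 20-mer, cell line, gene, percent reduction in
accumulated protein, measurement error — and want (a) triplet inhibition
parameters fitted from those data and (b) a ranked scan of a new mRNA for
promising target windows.

## The model

Each target is treated as a **closed circular** sequence, so a 20-mer
decomposes into exactly 20 overlapping triplets (no end terms; the
approximation costs 5–10% at the two windows spanning the seam). For
experiment *h* with per-experiment error σ<sub>h</sub>, the row of the
design matrix **N**<sub>h,k</sub> holds the 64 triplet counts, one
indicator for the more sensitive cell line, and one indicator per targeted
gene, all divided by σ<sub>h</sub>; the response I<sub>h</sub> is the
percent reduction divided by σ<sub>h</sub>. The system
**N**<sub>h,k</sub> P<sub>k</sub> = I<sub>h</sub> is solved by SVD.

The design is structurally singular: circular triplet counts obey 15
flow-balance constraints (for each doublet XY, Σ<sub>Z</sub> n(XYZ) =
Σ<sub>W</sub> n(WXY)), and the gene indicators sum to one, so a
112×69 design has exactly 16 zero singular values. The solver zeroes them,
returns the minimum-norm solution and a covariance built from retained
modes only, and reports χ², dof = n − effective rank, and the
goodness-of-fit probability Q (upper-tail χ² probability; Q > 0.1 is an
adequate fit). Individual triplet parameters are **not** meaningful on
their own — only estimable combinations are, such as the triplet sum of
any realizable circular sequence (with its covariate context), differences
of gene offsets, and the cell-line offset.

The package ships the published reference table of 64 triplet + 5
covariate parameters (fitted to 112 experiments on CRAF1, BCL2, AKT2 and
PKC-α in A549/T24 cells) and the companion list of 49 independent 12-mers.

## Worked example

Score the circular 12-mer (ACU)₄ with the packaged reference table:

```console
$ nnnfit score --seq ACUACUACUACU --circular
ACUACUACUACU    P = 72.1 +/- 15.1 (naive SE)
```

P = 72.1 means a predicted 72.1% reduction in net accumulated protein:
4 × (P(ACU) + P(CUA) + P(UAC)) = 4 × (3.81 + 13.27 + 0.94). The SE here is
the root-sum-of-squares approximation (the published table has no
covariance matrix; tables written by `nnnfit fit` do, and then exact
propagated SEs are reported).

Diagnose a linearly dependent set — (GGGA)₃ is not independent of the
reference 12-mers:

```console
$ nnnfit independence --seqs deps.txt
rank 3 / 4: dependent
one dependency: (G)12:+0.250, (AGG)4:+0.750, (GGGA)3:-1.000
```

i.e. in triplet-count space (GGGA)₃ = ¼·(G)₁₂ + ¾·(AGG)₄, and its score
(23.0) equals the same combination of their scores.

Simulate a 112-experiment data set with known truth and refit it:

```console
$ nnnfit simulate --n 112 --seed 1 --out sim.csv
$ nnnfit fit --experiments sim.csv
n=112 columns=69 rank=53 zero_sv=16 chi2=75.6423 dof=59 Q=0.07106 r=0.9680
```

The 16 zero singular values are the 15 circular-count constraints plus the
gene sum-to-one dependency; Q is uniform on [0,1] over replicates when the
model is correct. `nnnfit scan --fasta mrna.fa --window 20` ranks every
20-nt window of an mRNA by predicted P (TSV or BED output), and the same
operations are available as a library (`import nnnfit`).

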