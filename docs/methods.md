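# Methods

## Model

An antisense experiment measures the percent reduction in net accumulated
protein after transfecting a 20-mer phosphorothioate DNA complementary to
an mRNA target site. `nnnfit` models that reduction as linear in the
overlapping trinucleotide (next-nearest-neighbor, NNN) content of the
target plus categorical offsets:

    reduction_h = Σ_t n_h(t) · P(t) + cell_h · P(cell) + Σ_g δ_{g,h} · P(g) + ε_h,
    ε_h ~ N(0, σ_h²)

where n_h(t) are the circular triplet counts of target h, the cell
indicator is 1 for the more sensitive cell line, δ selects the targeted
gene, and σ_h is the known per-experiment standard error. Dividing each
row and response by σ_h makes ordinary least squares the χ² fit, so the
residual sum of squares of the weighted system is χ² and
Q = Γ_upper(dof/2, χ²/2)/Γ(dof/2) is the usual goodness-of-fit tail
probability (computed with `scipy.special.gammaincc`).

### Closed-circle convention

Targets are treated as closed circular sequences: every one of the L
positions contributes one triplet, so counts sum to L and no end-triplet
parameters are needed. For 20-mers the neglected end effects are of order
1/20 (nearest-neighbor-dominated) to 2/20 (triplet-dominated), i.e. 5–10%.
Window scanning circularizes each window for the same reason — scores stay
commensurate with fitted parameters. A linear counting mode (L−2 windows)
exists in `seqcore` for completeness but the fitting and scoring paths
always circularize.

### Identifiability

Circular count vectors satisfy, for every doublet XY, a flow-balance
equation Σ_Z n(XYZ) − Σ_W n(WXY) = 0. These 16 equations have rank 15, so
the triplet count space has dimension 64 − 15 = 49 (doublets: 16 − 3 = 13).
A maximal independent set of 49 circular 12-mers is packaged; appending any
further sequence yields a rank-49, dependent set and
`check_independence` reports one dependency explicitly (e.g. (GGGA)₃ =
¼·(G)₁₂ + ¾·(AGG)₄).

With the gene block included, the design gains one further exact
dependency: gene indicators sum to 1 in every row while triplet counts sum
to 20, so the direction (+1 on all 64 triplets, −20 on all genes) is in the
null space. Hence a full 112×69 design of generic 20-mers has exactly
15 + 1 = 16 zero singular values and effective rank 53.

A consequence worth spelling out: single triplet parameters — including the
four homotriplets AAA/CCC/GGG/UUU — are estimable in the pure count space
and in designs without the gene block, but **not** in the full design,
where they carry the constant-shift ambiguity against the gene average.
Estimable functionals of the full design include: any complete prediction
(counts of a circular sequence plus its cell/gene context), differences and
mean-centered combinations of gene offsets (the gene-minus-average
transform), and the cell offset. `is_estimable` tests membership of a
weight vector in the design row space; `recovery_report` projects the
ground truth onto the fitted row space so that synthetic-data recovery is
judged on estimable functionals only.

### SVD solution and uncertainties

The weighted system is solved by singular value decomposition. Singular
values below `sv_rel_tolerance` × (largest singular value) are treated as
exact zeros; their reciprocals are excluded from the minimum-norm solution
and from the covariance Σ_i v_i v_iᵀ / s_i², so only estimable combinations
have unique standard errors (`propagate_error` computes √(wᵀ C w)). The
default tolerance is 1e−8: in practice the structural zeros sit many orders
of magnitude below the smallest significant singular value, so any
threshold between the two clusters gives identical results; the value is
configurable everywhere it is used.

Degrees of freedom use the effective rank (dof = n − rank, 112 − 53 = 59
for the canonical layout), not the column count — non-identifiable columns
do not consume information. The fit report records n, rank and dof so
alternative conventions can be compared. The observed-vs-fitted Pearson r
is computed on unweighted reductions.

## Scoring

`score_sequence` returns P = Σ_t count(t)·P(t) plus requested covariate
offsets. Offsets are constants within a (cell, gene) stratum and do not
change rankings, so they may be omitted. When the parameter table carries a
covariance matrix (tables produced by `nnnfit fit` do), SEs are exact
propagated values; otherwise a root-sum-of-squares of component SEs is
offered, explicitly labeled "naive" — against the reference analysis it is
right to within ~10% on average but can mislead for strongly covaried
combinations. The packaged reference table stores the published
two-decimal values, so reconstructed sequence parameters agree with the
published ones to ±0.15 (≤ 12 summands of two-decimal roundings).

`scan_windows` scores every window of a linear mRNA, sorts by P descending
with ties broken by ascending start, and uses 0-based half-open
coordinates (BED-compatible).

## Synthetic data

`simdata` emulates the reference database's statistical structure so that
fitting, identifiability and calibration are testable without any external
data: 20-mer targets rejection-sampled (cap 10⁵ attempts) to have G+C
content in [0.30, 0.85] and no run of more than three G's — the selection
rules used when the real oligomers were designed (the G-run rule avoids
G-quadruplexes; the GC rule spans a wide hybrid-stability range). The GC
constraint is checked on the target, whose GC fraction equals its
antisense complement's. Constraints apply to the linear oligomer, not
across the circular seam.

Defaults, chosen once to mirror the reference analysis: 64 triplet
parameters drawn N(0, 4.5²)% (the reference values span roughly −9 to +13%
with sample SD ≈ 4.2); cell offset 10.6% (the observed A549−T24
difference); gene offsets (3.7, −3.1, 9.0, −3.8)% (the reference gene
parameters, rounded); per-experiment σ uniform on 3–10% (the real error
distribution is unpublished; configurable). Noise is Gaussian with known
σ — exactly the assumption under which the χ²/Q machinery is valid. A
`noise_scale` knob lets tests generate exact responses while keeping
honest weights. All randomness flows through `numpy.random.default_rng`
seeded from explicit integers; identical seeds give byte-identical outputs.

What the generator does **not** emulate: mRNA secondary structure and site
accessibility, RNase H kinetics, off-target binding, protein/mRNA
lifetimes, or any correlation between σ and sequence. Passing recovery and
calibration tests therefore demonstrates the statistical machinery, not
that the linear NNN model captures cellular reality.

## Numerical and design choices

- Triplet indexing is lexicographic over A<C<G<U on the mRNA strand, 5'→3',
  everywhere (tables, matrices, serialized files).
- DNA input is transliterated T→U on ingest; an explicit flag
  (`--as-antisense`) marks sequences given as the antisense strand, which
  are stored as their reverse-complement mRNA. Ambiguity codes are
  rejected: the model has no semantics for them.
- The cell covariate uses the asymmetric published scheme: one indicator
  column carrying 1 for the sensitive line (default: lexicographically
  first label; override with `sensitive_cell`). With more than two cell
  labels, one indicator per non-reference label (reference =
  lexicographically last). Genes always get one column per label.
- Rows without positive errors are rejected, not imputed — the weighting is
  integral to χ².
- Duplicate target sequences across cell lines are legitimate distinct rows
  (the reference data reuse 26 CRAF1 targets in both lines).
- Ranking ties break by ascending start coordinate; all window coordinates
  are 0-based half-open.
- Degenerate inputs: an all-zero design raises; dof ≤ 0 yields Q = NaN
  rather than an exception; `propagate_error` clamps tiny negative
  variances (roundoff) to zero.

## Problem sizes

The test suite and acceptance script run entirely at desk scale: the
canonical 112×69 design, 200-replicate Q-calibration, 100-replicate
z-calibration, and 2000 random 20-mers for the count-space rank
cross-check. Each completes in seconds on one CPU.

## Known limitations

- The packaged reference parameters derive from a small (112-experiment,
  4-gene, 2-cell-line) database; they are not general-purpose antisense
  efficacy predictors, and published external data sets are mostly poorly
  fit by them.
- Published SEs for the reference independent combinations cannot be
  reproduced exactly because the original covariance matrix is not
  published; only the naive approximation is available for that table.
- One published worked example, (GGGAGU)₂ = 4.4 ± 7.5%, is not reproduced
  by direct summation over the reference table (which gives −14.4; the
  printed value is recovered only if the AGU parameter enters with flipped
  sign). The package does not special-case it.
- No secondary-structure, genome-uniqueness or motif-catalog screening —
  those are separate steps in target selection.
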