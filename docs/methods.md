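# Methods

## Genotype representations

Genotypes are biallelic dosages in {0, 1, 2}. Two compressed layouts are
supported, with bit-exact conversions between them:

* **2-bit (PLINK 1 binary)** — SNP-major, four calls per byte, first
  individual in the least-significant bit pair. Code 0 is the A1
  homozygote, 1 a missing call, 2 the heterozygote, 3 the A2 homozygote.
  Dosage counts the A2 allele by default; `count_allele="a1"` flips the
  orientation (the right orientation for externally computed frequencies
  is a data-provenance question the file format cannot answer, so it is a
  flag rather than a guess). Pad bit-pairs must be zero and are verified
  on read.
* **5codes** — one byte per five SNPs, key = Σ m_t·3^(t−1) with the
  *first* SNP of the block as the 3⁰ digit. The key space has exactly
  3⁵ = 243 states, so the packing uses 8/5 = 1.6 bits per call, 80% of
  the 2-bit format. Missing calls are not representable in the key space;
  they are packed as dosage 0 and tracked in a sparse (individual, SNP)
  index used for post-hoc corrections. Trailing pad slots encode dosage 0
  and carry frequency 0, so centered pad contributions vanish
  identically.

Transposed products are served from a second, explicitly stored packing
of M′ (five contiguous individuals per byte) built once at start-up;
there is no on-the-fly tile transpose. This doubles genotype memory in
exchange for a symmetric access pattern in both products.

## Lookup-table multiplication

For each column λ of Λ and each 5-SNP block, the 243 possible dot
products m′λ are tabulated once; the product row i then accumulates
`table_b[key[i, b]]` over blocks. All tables of a column are materialized
as one (243 × n_blocks) array so the gather vectorizes. For Z Λ the
tables store the centered values m′λ − 2·p′λ, which both saves a pass
over the output and avoids accumulating the large uncentered partial
sums. For Z′Λ̃ the centering term 2·p(1′Λ̃) varies per output row, so it
is applied as a rank-one update after the uncentered lookup product.

Missing-value policies:

* `mean` (default): a missing call contributes z = 0, i.e. it is imputed
  to its column mean 2p_j. Implemented as a sparse correction adding
  2·p_j·λ_j (row i) or 2·p_j·λ̃_i (row j) per missing pair after the
  centered product. A SNP with every call missing therefore yields an
  exactly zero row in Z′Λ̃.
* `zero`: the literal packed value stands, z = −2p_j at missing entries.
  Uncentered products are identical under both policies.

Mean imputation is the default because it is the standard convention for
centered genotype matrices in single-step evaluations; the zero-dosage
reading is retained as a flag since compressed-storage implementations
differ and the choice is observable only through the correction term.

Chunked execution partitions the reduction axis (SNP blocks for M Λ,
individual blocks for M′Λ̃) into contiguous chunks; partial sums are
combined once at the end in fixed chunk order, so any chunk count
reproduces the single-chunk result up to floating-point reassociation
(bounded at 1e-12 in the tests). All accumulation is in float64.

The 2-bit direct path (`packed_bed_times`) extracts dosages from the raw
codes with shifts and masks in SNP groups and multiplies immediately,
sharing the centering/correction logic. It exists both as an independent
execution path and because converting to 5codes is not always warranted
for one-shot products.

The genomic relationship matrix is G = Z Z′ / m with
m = 2 Σ p_j(1 − p_j) and mean-imputed missing values, computed in column
strips as Z(Z′E) through the two packed kernels. m = 0 (a panel with no
polymorphism) is rejected as degenerate. Other scalings of G exist in
the literature; this one matches the constant used in the solver's SNP
block, keeping the two consistent.

## Pedigree algebra

A⁻¹ is assembled directly by Henderson's rules. With inbreeding, animal
i's Mendelian-sampling variance is d_i = 0.5 − 0.25(F_s + F_d) (both
parents known), 0.75 − 0.25 F_s (one), or 1 (none), and α_i = 1/d_i
contributes α_i at (i,i), −α_i/2 between i and each known parent, and
α_i/4 between known parents. Without inbreeding the classical α values
2, 4/3, 1 apply; both conventions are exposed because both are in
routine use, and the non-inbred variant is exact only on
inbreeding-free pedigrees. Inbreeding coefficients come from the
recursive tabular relationship matrix, F = diag(A) − 1 — O(n²) memory
and therefore a desk-scale tool, which is all the sparse assembly needs
(it consumes only F, not A). Unknown parents are treated as unrelated
base-population founders. Pedigrees are validated for cycles (Kahn's
algorithm); input not in chronological order is re-ordered topologically
with a warning.

A⁻¹ is partitioned by genotyped status into A^nn, A^ng, A^gn, A^gg.
Products with A_gg⁻¹ use the identity
A_gg⁻¹ v = A^gg v − A^gn (A^nn)⁻¹ A^ng v; the sparse LU factorization of
A^nn is computed on first use and cached. A_gg and its inverse are never
formed.

## The single-step system

Records follow y = X b + W_n u_n + W_g u_g + e with u_g = a_g + Z g.
The precision of (u_n, u_g, g) is the 3×3 block matrix Σ⁻¹ (scaled by
1/σ²_u) with rows

```
[ A^nn                A^ng                               0                      ]
[ A^gn   A^gg + (1/w − 1) A_gg⁻¹          −(1/w) A_gg⁻¹ Z                       ]
[ 0            −(1/w) Z′ A_gg⁻¹     (1/w) Z′ A_gg⁻¹ Z + m/(1−w) I              ]
```

where w ∈ (0, 1) is the residual polygenic proportion (default 0.20) and
m = 2 Σ p_j(1 − p_j). Z is centered with observed allele frequencies by
default. The mixed model equations are Henderson's standard assembly for
(b, u_n, u_g, g), multiplied through by σ²_e so the coefficient matrix
is T′T + σ²_e·blockdiag(0, Σ⁻¹) with T = [X | W_n | W_g | 0] — this
keeps the data part integer-valued and puts the variance ratio in one
place. The operator is evaluated entirely matrix-free; a dense
assembly (by probing the operator with unit vectors) exists for
desk-scale verification only.

### PCG

Jacobi-preconditioned conjugate gradient with stopping rule
‖r‖²/‖rhs‖² < tol, default tol = 1e-13 and x₀ = 0. The preconditioner
uses the exact diagonal of T′T plus σ²_e/σ²_u times the diagonals of the
sparse A blocks and the m/(1−w) SNP term; the dense diagonals of the
A_gg⁻¹-involving blocks are omitted — they would cost a full pass over
A_gg⁻¹ and affect only the convergence rate, never the fixed point.
Zero diagonal entries (possible for effects with no data support) are
floored at 1. Non-finite or non-positive curvature raises a divergence
error carrying the iteration index. The fixed-effect design is a
one-hot level coding (full rank by construction here); a rank-deficient
X would still yield a consistent system solvable by CG, with the usual
estimability caveats left to the user.

## Synthetic data

The generator inverts the model above so every component is testable
without external data. Defaults define the reference study: 80 founders
plus 4 generations of 40 matings × 2 offspring (400 animals), 1000 SNPs
with founder MAF uniform on [0.01, 0.5], half the animals genotyped, 1%
missing calls, w = 0.20, σ²_u = σ²_e = 1, one record per animal with a
single fixed mean, and trait matrices of width k = 10.

Founder haplotypes are Bernoulli(q_j); descendants inherit one uniformly
chosen allele per parent per SNP (gene dropping), so pedigree and
genomic relationships are mutually consistent — required for the
parameter-recovery checks. Polygenic effects are drawn through a
Cholesky factor of the tabular A (O(n³), capped at 2000 animals);
SNP effects are N(0, (1−w)σ²_u/m) with m over the founder frequencies,
so Var(Z g) calibrates to (1−w)σ²_u. All randomness flows through
per-stage generators spawned from one integer seed, making regeneration
bit-identical.

What the generator does **not** emulate: linkage and LD structure (SNPs
segregate independently), chip ascertainment, imputation artefacts,
selection and non-random mating, and heterogeneous residual variance.
Passing tests therefore demonstrate algorithmic and numerical
correctness under the stated sampling model, not robustness to the LD
or data-editing features of real panels.

## Problem sizes and tolerances

The test suite and the reproduction script run the multiplication checks
on randomized instances up to 200 × 200 × 10 (relative error bound
1e-10 against the dense reference; observed errors are at machine-
precision level), pedigree identities on up to 500 animals (1e-8
absolute), operator-vs-dense-assembly checks at 1e-8 relative, and the
full solver equivalence on the 400-animal default study (1e-5 relative
per effect block at tol 1e-13). These sizes keep a full dense oracle
tractable while exercising every packed code path, including pad blocks
and missing data.

## Known limitations

* Single trait, homogeneous residual variance; no multivariate
  extension.
* The tabular-A routines (inbreeding, polygenic simulation, oracles) are
  quadratic/cubic and intended for desk scale; the sparse assembly and
  the solver itself scale to large pedigrees.
* Parallel chunking fixes the reduction order for reproducibility but
  the implementation is single-threaded NumPy; the chunk contract is the
  interface a threaded backend would honour.
* ssGTABLUP, APY and Woodbury-based variants are out of scope.
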