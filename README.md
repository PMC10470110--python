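# pentagen

Compressed genotype matrix algebra for genomic prediction: the base-3
**5codes** lookup-table multiplication of a 2-bit-packed SNP matrix by a
narrow floating-point matrix, with allele-frequency centering and
missing-value correction, applied inside a **matrix-free preconditioned
conjugate gradient (PCG)** solver for the single-step SNP BLUP
(ssSNPBLUP) mixed model equations.

## The problem

Genetic evaluations in animal breeding estimate breeding values — the
additive genetic merit an animal transmits to its offspring — from
phenotypic records, a pedigree, and SNP genotypes of a (usually partial)
subset of the population. Single-step models combine all three, and their
mixed model equations are solved iteratively: every PCG iteration must
multiply the centered genotype matrix

```
Z = M − 2·1 p′,       M ∈ {0,1,2}^(n_g × n_s)
```

and its transpose by a matrix Λ of small width (~10 columns). With
millions of genotyped animals, M is stored compressed (2 bits per call in
the PLINK 1 binary format), and this product is the computational
bottleneck. `pentagen` implements the lookup-table strategy that removes
it: since a block of five SNP dosages takes only 3⁵ = 243 values, it fits
in one byte (80% of the 2-bit footprint), and for each 5-row tile of a Λ
column the 243 possible dot products are tabulated once, so the product
reduces to table gathers:

```
Z Λ = M Λ − 2·1 (p′Λ),   Z′Λ̃ = M′Λ̃ − 2·p (1′Λ̃),
table[key(m)] = m′λ  (or z′λ = m′λ − 2 p′λ, centering folded in).
```

The solver side assembles nothing large: the ssSNPBLUP precision matrix
Σ⁻¹ over (u_n, u_g, g) uses the sparse blocks of the pedigree
relationship inverse A⁻¹ (Henderson's rules), applies
A_gg⁻¹ = A^gg − A^gn (A^nn)⁻¹ A^ng through a cached factorization of
A^nn, and reaches Z only through the packed kernels. Henderson's mixed
model equations for (b, u_n, u_g, g) are then solved by Jacobi-
preconditioned CG to a squared relative residual below 10⁻¹³.

## Worked example

Simulate a 400-animal, 4-generation population (1000 SNPs, half the
animals genotyped, residual polygenic proportion w = 0.20) and solve the
single-step system:

```python
import numpy as np
from pentagen import SimulationConfig, simulate_study, build_ssmodel, solve_ssSNPBLUP

study = simulate_study(SimulationConfig(seed=1))
model, ainv = build_ssmodel(study.pedigree, study.genotypes, study.y,
                            study.record_animal, study.fixed_codes, w=0.20)
res = solve_ssSNPBLUP(model, ainv)
print(f"PCG converged in {res.iterations} iterations "
      f"(final squared relative residual {res.residual_history[-1]:.2e})")
uhat = np.empty(study.pedigree.n_animals)
uhat[ainv.nong_idx] = res.u_n
uhat[ainv.geno_idx] = res.u_g
print(f"accuracy corr(u_hat, u_true) = {np.corrcoef(uhat, study.true_u)[0,1]:.3f}")
print(f"fixed-effect (mean) estimate = {res.b[0]:.3f}")
```

which prints

```
PCG converged in 63 iterations (final squared relative residual 9.72e-14)
accuracy corr(u_hat, u_true) = 0.745
fixed-effect (mean) estimate = 0.723
```

63 iterations reach the 10⁻¹³ stopping rule; the correlation of 0.745
between estimated and true breeding values is the accuracy attainable at
this data size (a single record per animal, heritability 0.5), and the
estimated population mean sits near the simulated fixed effect.

The same pipeline is available from the shell:

```sh
pentagen simulate --config sim.toml --out-prefix sim
pentagen freq  --bfile sim --out freq.txt
pentagen mm    --bfile sim --lambda sim.lambda.txt --center freq.txt --engine 5codes --out zl.tsv
pentagen grm   --bfile sim --out grm.tsv
pentagen solve --bfile sim --pedigree sim.ped.txt --pheno sim.pheno.txt --w 0.2 --out solution.tsv
```

## Scope

CPU only, univariate single-trait models, homogeneous residual variance.
PLINK 1 binary is the only genotype format; multiallelic sites, dosage
formats and PLINK 2 are out of scope.
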