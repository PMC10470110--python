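"""Seeded simulation of pedigrees, genotypes, phenotypes and trait matrices.

The generator inverts the single-step model so that every other module can
be exercised without external data:

* a multi-generation pedigree is grown by random mating within the
  previous generation (founders have unknown parents, so the order is
  topological by construction);
* founder haplotypes are drawn per SNP at a frequency uniform on the
  configured MAF range, and descendants receive alleles by Mendelian gene
  dropping — so pedigree and genomic relationships are mutually
  consistent, which single-step parameter-recovery checks require;
* SNP effects g ~ N(0, (1-w) sigma_u^2 / m) with m = 2 sum q_j (1-q_j)
  over the founder frequencies, residual polygenic effects a ~ N(0,
  w sigma_u^2 A) via a Cholesky factor of the tabular A (O(n^3): capped
  at 2000 animals), breeding values u = a + Z g with Z centered at the
  founder frequencies, and records y = X b + W u + e with
  e ~ N(0, sigma_e^2);
* trait matrices are i.i.d. standard normal with width 10 by default.

All randomness flows through NumPy generators keyed off one integer seed
(one spawned stream per stage), so regeneration is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._errors import DimensionError, ParameterError
from .blup import PedigreeFrame, tabular_relationship_matrix
from .plink_io import AlleleFrequencyVector, GenotypeMatrix

_POLYGENIC_CAP = 2000

_STREAMS = {"pedigree": 0, "genotypes": 1, "phenotypes": 2, "traits": 3}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stage],))))


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Defaults give a 4-generation population of 400 animals (80 founders,
    40 matings x 2 offspring per generation), 1000 SNPs with founder MAF
    uniform on [0.01, 0.5], half the animals genotyped, 1% missing calls,
    and the single-step variance split w = 0.20 with unit variances.  The
    trait-matrix width defaults to 10.
    """

    n_founders: int = 80
    n_generations: int = 4
    offspring_per_mating: int = 2
    n_snps: int = 1000
    maf_range: tuple[float, float] = (0.01, 0.5)
    genotyped_fraction: float = 0.5
    missing_rate: float = 0.01
    w: float = 0.20
    sigma2_u: float = 1.0
    sigma2_e: float = 1.0
    n_fixed_levels: int = 1
    k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 2:
            raise ParameterError("need at least two founders")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ParameterError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not 0.0 < self.genotyped_fraction <= 1.0:
            raise ParameterError("genotyped_fraction must lie in (0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ParameterError("missing_rate must lie in [0, 1)")
        if not 0.0 < self.w < 1.0:
            raise ParameterError("w must lie strictly in (0, 1)")


@dataclass
class GenotypeSimulation:
    """Gene-dropped genotypes: the observed subset plus the full truth."""

    genotypes: GenotypeMatrix  # genotyped subset, missing calls injected
    freqs: AlleleFrequencyVector  # founder (true) frequencies
    full_dosages: np.ndarray  # (n_animals, n_snps), no missingness


@dataclass
class SimulatedStudy:
    """Everything a single-step analysis and its oracle checks need."""

    config: SimulationConfig
    pedigree: PedigreeFrame
    genotypes: GenotypeMatrix
    freqs: AlleleFrequencyVector
    full_dosages: np.ndarray = field(repr=False)
    true_g: np.ndarray
    true_u: np.ndarray
    true_b: np.ndarray
    y: np.ndarray
    record_animal: np.ndarray
    fixed_codes: np.ndarray
    lam: np.ndarray


def simulate_pedigree(config: SimulationConfig) -> PedigreeFrame:
    """Grow the pedigree generation by generation with random mating.

    Sexes alternate by birth order; each generation draws sires and dams
    (with replacement) from the previous generation only.  The returned
    frame carries the genotyped mask (a seeded subset of all animals).
    """
    rng = _rng(config.seed, "pedigree")
    sire, dam = [-1] * config.n_founders, [-1] * config.n_founders
    prev = np.arange(config.n_founders)
    n_matings = config.n_founders // 2
    for _ in range(config.n_generations):
        males = prev[prev % 2 == 0]
        females = prev[prev % 2 == 1]
        start = len(sire)
        for _ in range(n_matings):
            s = int(rng.choice(males))
            d = int(rng.choice(females))
            for _ in range(config.offspring_per_mating):
                sire.append(s)
                dam.append(d)
        prev = np.arange(start, len(sire))
    n = len(sire)
    n_geno = max(1, round(config.genotyped_fraction * n))
    genotyped = np.zeros(n, dtype=bool)
    genotyped[np.sort(rng.choice(n, size=n_geno, replace=False))] = True
    return PedigreeFrame(
        sire=np.asarray(sire), dam=np.asarray(dam), genotyped=genotyped,
        ids=[str(i + 1) for i in range(n)],
    )


def simulate_genotypes(ped: PedigreeFrame, config: SimulationConfig) -> GenotypeSimulation:
    """Founder sampling plus Mendelian gene dropping down the pedigree.

    Founder alleles are Bernoulli(q_j) with q_j ~ Uniform(maf_range); each
    offspring inherits one uniformly chosen allele per parent per SNP (no
    linkage).  Missing calls are injected at ``missing_rate`` into the
    genotyped subset only.
    """
    rng = _rng(config.seed, "genotypes")
    n, n_s = ped.n_animals, config.n_snps
    q = rng.uniform(config.maf_range[0], config.maf_range[1], size=n_s)
    haps = np.zeros((n, 2, n_s), dtype=np.int8)
    for i in ped.order:
        s, d = ped.sire[i], ped.dam[i]
        for slot, parent in ((0, s), (1, d)):
            if parent < 0:
                haps[i, slot] = rng.random(n_s) < q
            else:
                pick = rng.integers(0, 2, size=n_s)
                haps[i, slot] = haps[parent, pick, np.arange(n_s)]
    full = haps.sum(axis=1, dtype=np.int8)

    geno_idx = np.flatnonzero(ped.genotyped)
    dosages = full[geno_idx].copy()
    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        missing = np.argwhere(mask)
        dosages[mask] = 0
    else:
        missing = np.empty((0, 2), dtype=np.int64)
    gm = GenotypeMatrix(
        dosages=dosages,
        missing=missing,
        individual_ids=[str(i + 1) for i in geno_idx],
        snp_ids=[f"snp{j + 1}" for j in range(n_s)],
    )
    return GenotypeSimulation(genotypes=gm, freqs=AlleleFrequencyVector(p=q), full_dosages=full)


def simulate_phenotypes(
    ped: PedigreeFrame, geno: GenotypeSimulation, config: SimulationConfig
) -> SimulatedStudy:
    """Draw effects under the single-step model and assemble one record per animal.

    g ~ N(0, (1-w) sigma_u^2 / m); a ~ N(0, w sigma_u^2 A) through the
    Cholesky factor of the tabular A; u = a + (D - 2q') g over the true
    (complete) dosages D; y = X b + W u + e.  Fixed effects are a single
    mean (level effects drawn N(1, 1) when more levels are configured).
    """
    rng = _rng(config.seed, "phenotypes")
    n = ped.n_animals
    if n > _POLYGENIC_CAP:
        raise ParameterError(
            f"polygenic simulation uses a dense Cholesky of A (O(n^3)); capped at {_POLYGENIC_CAP} animals"
        )
    q = geno.freqs.p
    m = float(2.0 * np.sum(q * (1.0 - q)))
    true_g = rng.normal(0.0, np.sqrt((1.0 - config.w) * config.sigma2_u / m), size=config.n_snps)

    A = tabular_relationship_matrix(ped)
    L = np.linalg.cholesky(A + 1e-10 * np.eye(n))
    a = np.sqrt(config.w * config.sigma2_u) * (L @ rng.standard_normal(n))

    Z_full = geno.full_dosages.astype(np.float64) - 2.0 * q[None, :]
    true_u = a + Z_full @ true_g

    fixed_codes = rng.integers(0, config.n_fixed_levels, size=n)
    true_b = np.ones(config.n_fixed_levels) + (
        rng.standard_normal(config.n_fixed_levels) if config.n_fixed_levels > 1 else 0.0
    )
    e = rng.normal(0.0, np.sqrt(config.sigma2_e), size=n)
    record_animal = np.arange(n)
    y = true_b[fixed_codes] + true_u + e

    lam = simulate_trait_matrix(config.n_snps, config.k, config.seed)
    return SimulatedStudy(
        config=config,
        pedigree=ped,
        genotypes=geno.genotypes,
        freqs=geno.freqs,
        full_dosages=geno.full_dosages,
        true_g=true_g,
        true_u=true_u,
        true_b=np.atleast_1d(true_b),
        y=y,
        record_animal=record_animal,
        fixed_codes=fixed_codes,
        lam=lam,
    )


def simulate_trait_matrix(n_rows: int, k: int = 10, seed: int = 0) -> np.ndarray:
    """An (n_rows, k) matrix of i.i.d. standard-normal 'trait' columns."""
    if k < 1:
        raise DimensionError("trait matrix width k must be >= 1")
    return _rng(seed, "traits").standard_normal((n_rows, k))


def simulate_study(config: SimulationConfig | None = None, **overrides) -> SimulatedStudy:
    """One-call pipeline: pedigree -> genotypes -> phenotypes/trait matrix."""
    if config is None:
        config = SimulationConfig()
    if overrides:
        config = replace(config, **overrides)
    ped = simulate_pedigree(config)
    geno = simulate_genotypes(ped, config)
    return simulate_phenotypes(ped, geno, config)
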