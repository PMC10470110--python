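"""Genotype matrix products: lookup-table, 2-bit direct, and dense reference.

The products of interest are M @ lam, M' @ lamT and their column-centered
versions Z @ lam = M @ lam - 2*1*(p' lam) and Z' @ lamT = M' @ lamT -
2*p*(1' lamT), where M is the n_g x n_s dosage matrix, p the vector of
allele frequencies of the counted allele, and lam a narrow floating-point
matrix (typically ~10 columns).

Three execution paths share one mathematical contract:

* ``m_times``/``z_times``/``mt_times``/``zt_times`` — the 5codes lookup
  path: per lambda column, one 243-entry table per 5-SNP block, gathered
  per packed row.  For Z @ lam the centering is folded into the tables.
* ``packed_bed_times`` — operates directly on the 2-bit PLINK codes in
  4-SNP groups, extracting dosages with bitmasks and multiplying
  immediately (code 1 is missing).
* ``reference_dense_multiply`` — the literal dense evaluation, serving as
  the oracle for the packed paths.

Missing-value policies: ``'mean'`` (default) treats a missing call as
imputed to its column mean, i.e. its centered value z is 0, implemented as
a sparse +2*p_j correction after the product; ``'zero'`` leaves the raw
zero dosage in place (z = -2*p_j).  Uncentered products are unaffected
(missing is packed as dosage 0 either way).

Chunked execution splits the reduction axis into contiguous chunks whose
partial results are summed once at the end in fixed order, so any chunk
count reproduces the single-chunk result up to reassociation error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._errors import DegeneratePanelError, DimensionError, OrientationError
from .fivecodes import (
    BLOCK,
    BY_INDIVIDUAL,
    BY_SNP,
    FiveCodesMatrix,
    block_tables,
)
from .plink_io import (
    CODE_TO_DOSAGE_A2,
    MISSING_CODE,
    AlleleFrequencyVector,
    GenotypeMatrix,
    PackedBed,
    _SHIFTS,
)

MEAN_IMPUTE = "mean"
ZERO_DOSAGE = "zero"


@dataclass
class ProductResult:
    """Result of a genotype-matrix product; ``values`` is (rows, k) float64."""

    values: np.ndarray
    centered: bool = False
    missing_policy: str | None = None


def as_trait_matrix(lam) -> np.ndarray:
    """Validate/coerce a trait matrix: finite float64, 2-D (vectors become columns)."""
    lam = np.asarray(lam, dtype=np.float64)
    if lam.ndim == 1:
        lam = lam[:, None]
    if lam.ndim != 2:
        raise DimensionError("trait matrix must be 1- or 2-dimensional")
    if not np.all(np.isfinite(lam)):
        raise DimensionError("trait matrix entries must be finite")
    return lam


def _freqs(p) -> np.ndarray:
    if isinstance(p, AlleleFrequencyVector):
        return p.p
    return np.asarray(p, dtype=np.float64).ravel()


def _chunk_bounds(n: int, n_chunks: int):
    n_chunks = max(1, min(int(n_chunks), n)) if n else 1
    edges = np.linspace(0, n, n_chunks + 1).astype(int)
    return [(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:]) if b > a]

def _gather_product(
    keys: np.ndarray,
    lam: np.ndarray,
    p: np.ndarray | None,
    centered: bool,
    n_chunks: int,
) -> np.ndarray:
    """Core lookup kernel: sum of per-block table gathers over packed rows."""
    n_rows, n_blocks = keys.shape
    k = lam.shape[1]
    out = np.zeros((n_rows, k))
    block_cols = np.arange(n_blocks)
    for c in range(k):
        tables = block_tables(lam[:, c], p, centered)  # (243, n_blocks)
        partials = []
        for lo, hi in _chunk_bounds(n_blocks, n_chunks):
            partials.append(tables[keys[:, lo:hi], block_cols[lo:hi]].sum(axis=1))
        if partials:
            acc = partials[0]
            for part in partials[1:]:  # single reduction, fixed chunk order
                acc = acc + part
            out[:, c] = acc
    return out


def m_times(fc: FiveCodesMatrix, lam, n_chunks: int = 1) -> ProductResult:
    """Uncentered product M @ lam via the 5codes lookup tables."""
    if fc.orientation != BY_SNP:
        raise OrientationError("m_times requires a by-snp packed matrix")
    lam = as_trait_matrix(lam)
    if lam.shape[0] != fc.n_snps:
        raise DimensionError(f"lam has {lam.shape[0]} rows, expected n_snps={fc.n_snps}")
    return ProductResult(values=_gather_product(fc.keys, lam, None, False, n_chunks))


def mt_times(fcT: FiveCodesMatrix, lamT, n_chunks: int = 1) -> ProductResult:
    """Transposed uncentered product M' @ lamT from the by-individual packing."""
    if fcT.orientation != BY_INDIVIDUAL:
        raise OrientationError("mt_times requires a by-individual packed matrix (M')")
    lamT = as_trait_matrix(lamT)
    if lamT.shape[0] != fcT.n_individuals:
        raise DimensionError(
            f"lamT has {lamT.shape[0]} rows, expected n_individuals={fcT.n_individuals}"
        )
    return ProductResult(values=_gather_product(fcT.keys, lamT, None, False, n_chunks))


def _apply_missing_correction_rows(out, missing, p, lam):
    """Add back 2*p_j*lam[j, :] to row i for every missing (i, j) (Z @ lam side)."""
    if missing.size:
        mi, mj = missing[:, 0], missing[:, 1]
        np.add.at(out, mi, 2.0 * p[mj, None] * lam[mj, :])


def _apply_missing_correction_cols(out, missing, p, lamT):
    """Add back 2*p_j*lamT[i, :] to row j for every missing (i, j) (Z' @ lamT side)."""
    if missing.size:
        mi, mj = missing[:, 0], missing[:, 1]
        np.add.at(out, mj, 2.0 * p[mj, None] * lamT[mi, :])


def z_times(
    fc: FiveCodesMatrix,
    p,
    lam,
    missing_policy: str = MEAN_IMPUTE,
    n_chunks: int = 1,
) -> ProductResult:
    """Centered product Z @ lam using centered lookup tables.

    The -2*p'lam term lives inside the tables; the missing correction is a
    sparse post-step over the recorded (individual, snp) pairs.
    """
    if fc.orientation != BY_SNP:
        raise OrientationError("z_times requires a by-snp packed matrix")
    lam = as_trait_matrix(lam)
    p = _freqs(p)
    if p.size != fc.n_snps:
        raise DimensionError(f"p has length {p.size}, expected n_snps={fc.n_snps}")
    if lam.shape[0] != fc.n_snps:
        raise DimensionError(f"lam has {lam.shape[0]} rows, expected n_snps={fc.n_snps}")
    out = _gather_product(fc.keys, lam, p, True, n_chunks)
    if missing_policy == MEAN_IMPUTE:
        _apply_missing_correction_rows(out, fc.missing, p, lam)
    elif missing_policy != ZERO_DOSAGE:
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    return ProductResult(values=out, centered=True, missing_policy=missing_policy)


def zt_times(
    fcT: FiveCodesMatrix,
    p,
    lamT,
    missing_policy: str = MEAN_IMPUTE,
    n_chunks: int = 1,
) -> ProductResult:
    """Transposed centered product Z' @ lamT = M' @ lamT - 2*p*(1' lamT).

    Here the centering term varies per output row (one p_j per SNP), so it
    is applied as a rank-one subtraction after the lookup product rather
    than inside the tables.
    """
    if fcT.orientation != BY_INDIVIDUAL:
        raise OrientationError("zt_times requires a by-individual packed matrix (M')")
    lamT = as_trait_matrix(lamT)
    p = _freqs(p)
    if p.size != fcT.n_snps:
        raise DimensionError(f"p has length {p.size}, expected n_snps={fcT.n_snps}")
    if lamT.shape[0] != fcT.n_individuals:
        raise DimensionError(
            f"lamT has {lamT.shape[0]} rows, expected n_individuals={fcT.n_individuals}"
        )
    out = _gather_product(fcT.keys, lamT, None, False, n_chunks)
    out -= 2.0 * np.outer(p, lamT.sum(axis=0))
    if missing_policy == MEAN_IMPUTE:
        _apply_missing_correction_cols(out, fcT.missing, p, lamT)
    elif missing_policy != ZERO_DOSAGE:
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    return ProductResult(values=out, centered=True, missing_policy=missing_policy)


def packed_bed_times(
    pb: PackedBed,
    lam,
    transposed: bool = False,
    p=None,
    centered: bool = False,
    missing_policy: str = MEAN_IMPUTE,
    snp_chunk: int = 512,
) -> ProductResult:
    """Product straight from the 2-bit PLINK codes, 4 SNP calls per byte.

    Dosages are extracted with bitmasks group-wise and multiplied
    immediately in double precision; code 1 is treated as missing.  Same
    mathematical contract as the 5codes path.
    """
    if missing_policy not in (MEAN_IMPUTE, ZERO_DOSAGE):
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    lam = as_trait_matrix(lam)
    n_g, n_s = pb.n_individuals, pb.n_snps
    expected_rows = n_g if transposed else n_s
    if lam.shape[0] != expected_rows:
        raise DimensionError(f"lam has {lam.shape[0]} rows, expected {expected_rows}")
    if centered:
        p = _freqs(p)
        if p.size != n_s:
            raise DimensionError(f"p has length {p.size}, expected n_snps={n_s}")

    k = lam.shape[1]
    out = np.zeros((n_s, k)) if transposed else np.zeros((n_g, k))
    miss_pairs = []
    for lo in range(0, n_s, snp_chunk):
        hi = min(lo + snp_chunk, n_s)
        chunk = pb.data[lo:hi]
        codes = ((chunk[:, :, None] >> _SHIFTS) & np.uint8(0b11)).reshape(hi - lo, -1)[:, :n_g]
        dos = CODE_TO_DOSAGE_A2[codes].astype(np.float64)
        if centered:
            local = np.argwhere(codes == MISSING_CODE)
            if local.size:
                local[:, 0] += lo
                miss_pairs.append(local[:, ::-1])  # -> (individual, snp)
        if transposed:
            out[lo:hi] = dos @ lam
        else:
            out += dos.T @ lam[lo:hi]
    if centered:
        missing = (
            np.concatenate(miss_pairs, axis=0) if miss_pairs else np.empty((0, 2), dtype=np.int64)
        )
        if transposed:
            out -= 2.0 * np.outer(p, lam.sum(axis=0))
            if missing_policy == MEAN_IMPUTE:
                _apply_missing_correction_cols(out, missing, p, lam)
        else:
            out -= 2.0 * (p @ lam)[None, :]
            if missing_policy == MEAN_IMPUTE:
                _apply_missing_correction_rows(out, missing, p, lam)
    return ProductResult(values=out, centered=centered, missing_policy=missing_policy if centered else None)


def reference_dense_multiply(
    g: GenotypeMatrix,
    p,
    lam,
    mode: str = "M",
    missing_policy: str = MEAN_IMPUTE,
) -> ProductResult:
    """Literal dense evaluation of M@lam / Z@lam / M'@lamT / Z'@lamT.

    Desk-scale oracle for every packed path: the dosage matrix is inflated
    to float64 and multiplied with NumPy.
    """
    if mode not in ("M", "Z", "Mt", "Zt"):
        raise ValueError(f"unknown mode {mode!r}")
    lam = as_trait_matrix(lam)
    d = g.dosages.astype(np.float64)  # missing already zero
    if mode in ("Z", "Zt"):
        p = _freqs(p)
        if p.size != g.n_snps:
            raise DimensionError("p length must equal n_snps")
        zd = d - 2.0 * p[None, :]
        if missing_policy == MEAN_IMPUTE:
            mask = g.missing_mask()
            zd[mask] = 0.0
        elif missing_policy != ZERO_DOSAGE:
            raise ValueError(f"unknown missing policy {missing_policy!r}")
        mat = zd
        centered = True
    else:
        mat = d
        centered = False
    if mode in ("Mt", "Zt"):
        mat = mat.T
    if lam.shape[0] != mat.shape[1]:
        raise DimensionError(f"lam has {lam.shape[0]} rows, expected {mat.shape[1]}")
    return ProductResult(values=mat @ lam, centered=centered,
                         missing_policy=missing_policy if centered else None)


def heterozygosity_scale(p) -> float:
    """Scaling constant m = 2 * sum_j p_j (1 - p_j) of the marker panel."""
    p = _freqs(p)
    return float(2.0 * np.sum(p * (1.0 - p)))


def compute_grm(
    fc: FiveCodesMatrix,
    fcT: FiveCodesMatrix,
    p,
    block: int = 64,
) -> np.ndarray:
    """Genomic relationship matrix G = Z Z' / m, m = 2 sum p_j(1-p_j).

    Built in column strips through the packed kernels: each strip of G is
    Z @ (Z' @ E) for an indicator block E, with missing calls mean-imputed.
    """
    p = _freqs(p)
    m = heterozygosity_scale(p)
    if m <= 0.0:
        raise DegeneratePanelError("no polymorphic SNPs: m = 2*sum p(1-p) is zero")
    n_g = fc.n_individuals
    G = np.empty((n_g, n_g))
    eye = np.eye(n_g)
    for lo in range(0, n_g, block):
        hi = min(lo + block, n_g)
        zt = zt_times(fcT, p, eye[:, lo:hi]).values  # Z' E, (n_s, b)
        G[:, lo:hi] = z_times(fc, p, zt).values / m
    return G
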