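"""Base-3 "5codes" packing of genotype dosages and its lookup tables.

A biallelic dosage takes one of three states, so a block of five contiguous
SNPs has 3^5 = 243 possible realisations and fits into one byte, using 80%
of the memory of 2-bit packing.  The key of a block is

    key = m_1*3^0 + m_2*3^1 + m_3*3^2 + m_4*3^3 + m_5*3^4,

i.e. the first SNP of the block is the 3^0 digit.  Multiplication of the
packed matrix by a floating-point vector is then a table lookup: for each
5-SNP tile of the vector, the 243 possible dot products are precomputed
once and gathered per row.  The table can absorb the allele-frequency
centering term (-2 p'lambda), which turns the lookup product into the
centered product directly.

Missing values are not representable in the key space; they are packed as
dosage 0 and tracked in a separate sparse index that the multiplication
engine uses for post-hoc corrections.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._errors import CorruptFileError, DimensionError, DomainError, UnsupportedFormatError
from .plink_io import GenotypeMatrix

N_KEYS = 243
BLOCK = 5
POW3 = 3 ** np.arange(BLOCK, dtype=np.int64)

# ALL_CODES[k] == decode_key(k); shape (243, 5)
ALL_CODES = np.stack(
    [(np.arange(N_KEYS, dtype=np.int64) // POW3[t]) % 3 for t in range(BLOCK)], axis=1
).astype(np.float64)
_ALL_CODES_INT = ALL_CODES.astype(np.int8)

BY_SNP = "by-snp"
BY_INDIVIDUAL = "by-individual"

_5C_MAGIC = b"5COD"
_5C_VERSION = 1


def encode_key(m) -> int:
    """Base-3 key of a 5-vector of dosages; bijection {0,1,2}^5 -> [0, 242]."""
    m = np.asarray(m, dtype=np.int64)
    if m.shape != (BLOCK,):
        raise DomainError(f"expected a 5-vector, got shape {m.shape}")
    if np.any((m < 0) | (m > 2)):
        raise DomainError("dosages must lie in {0, 1, 2}")
    return int(m @ POW3)


def decode_key(key: int) -> np.ndarray:
    """Inverse of :func:`encode_key`; returns the 5-vector of dosages."""
    key = int(key)
    if not 0 <= key < N_KEYS:
        raise DomainError(f"key {key} outside [0, {N_KEYS - 1}]")
    return _ALL_CODES_INT[key].copy()


@dataclass
class FiveCodesMatrix:
    """Genotype matrix packed one byte per five SNPs.

    ``orientation == 'by-snp'`` packs M row-wise: ``keys`` has shape
    ``(n_individuals, ceil(n_snps/5))`` and entry (i, b) encodes SNPs
    5b..5b+4 of individual i.  ``orientation == 'by-individual'`` packs the
    transpose M': ``keys`` has shape ``(n_snps, ceil(n_individuals/5))``.
    ``missing`` always lists (individual, snp) pairs in M coordinates.
    Trailing pad slots encode dosage 0.
    """

    n_individuals: int
    n_snps: int
    keys: np.ndarray
    missing: np.ndarray
    orientation: str = BY_SNP
    freqs: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.keys = np.ascontiguousarray(self.keys, dtype=np.uint8)
        self.missing = np.asarray(self.missing, dtype=np.int64).reshape(-1, 2)
        if self.orientation not in (BY_SNP, BY_INDIVIDUAL):
            raise DomainError(f"unknown orientation {self.orientation!r}")
        rows, packed_len = (
            (self.n_individuals, self.n_snps)
            if self.orientation == BY_SNP
            else (self.n_snps, self.n_individuals)
        )
        expected = (rows, -(-packed_len // BLOCK))
        if self.keys.shape != expected:
            raise DimensionError(f"keys shape {self.keys.shape}, expected {expected}")
        if self.keys.size and self.keys.max() >= N_KEYS:
            raise DomainError("key value >= 243")

    @property
    def nbytes(self) -> int:
        return self.keys.size

    @property
    def n_blocks(self) -> int:
        return self.keys.shape[1]

    def decode(self) -> np.ndarray:
        """Unpack to the dense dosage matrix (n_individuals, n_snps)."""
        dense = _ALL_CODES_INT[self.keys].reshape(self.keys.shape[0], -1)
        if self.orientation == BY_SNP:
            return np.ascontiguousarray(dense[:, : self.n_snps])
        return np.ascontiguousarray(dense[:, : self.n_individuals].T)


def _pack_rows(d: np.ndarray) -> np.ndarray:
    """Pack each row of a dosage matrix into base-3 keys, padding with 0."""
    rows, cols = d.shape
    n_blocks = -(-cols // BLOCK) if cols else 0
    padded = np.zeros((rows, n_blocks * BLOCK), dtype=np.int64)
    padded[:, :cols] = d
    return (padded.reshape(rows, n_blocks, BLOCK) @ POW3).astype(np.uint8)


def encode_matrix(g: GenotypeMatrix, orientation: str = BY_SNP) -> FiveCodesMatrix:
    """Pack a dosage matrix into 5codes format (missing set carried through)."""
    if np.any((g.dosages < 0) | (g.dosages > 2)):
        raise DomainError("dosages must lie in {0, 1, 2}")
    d = g.dosages if orientation == BY_SNP else g.dosages.T
    return FiveCodesMatrix(
        n_individuals=g.n_individuals,
        n_snps=g.n_snps,
        keys=_pack_rows(np.asarray(d, dtype=np.int64)),
        missing=g.missing,
        orientation=orientation,
    )


def transpose_packed(g: GenotypeMatrix) -> FiveCodesMatrix:
    """Pack M' so that five contiguous individuals share a byte.

    The transposed product M' @ lam is served from this explicitly stored
    packing (the whole matrix is transposed once at start-up; there is no
    on-the-fly tile transpose).
    """
    return encode_matrix(g, orientation=BY_INDIVIDUAL)


@dataclass
class LookupTable:
    """All 243 dot products of one 5-SNP tile of lambda, optionally centered."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if self.values.size != N_KEYS:
            raise DimensionError("a lookup table has exactly 243 entries")


def build_lookup_table(lambda5, p5=None, centered: bool = False) -> LookupTable:
    """Table of x = m'lambda5 (or z'lambda5 = m'lambda5 - 2 p5'lambda5) over all m.

    The centered variant folds the allele-frequency term into the table so
    that the gather step yields the centered product directly, which also
    reduces floating-point accumulation error.
    """
    lam = np.asarray(lambda5, dtype=np.float64).ravel()
    if lam.size != BLOCK:
        raise DimensionError("lambda5 must have length 5")
    values = ALL_CODES @ lam
    if centered:
        if p5 is None:
            raise DimensionError("centered table requires the frequency 5-vector p5")
        p = np.asarray(p5, dtype=np.float64).ravel()
        if p.size != BLOCK:
            raise DimensionError("p5 must have length 5")
        values = values - 2.0 * (p @ lam)
    return LookupTable(values=values)


def block_tables(lam_col: np.ndarray, p: np.ndarray | None, centered: bool) -> np.ndarray:
    """Stack of per-block tables, shape (243, n_blocks), for one lambda column.

    ``lam_col`` (length L) is zero-padded to a multiple of 5; pads carry
    frequency 0 so centered pad contributions are exactly zero.
    """
    lam_col = np.asarray(lam_col, dtype=np.float64).ravel()
    n_blocks = -(-lam_col.size // BLOCK)
    lam_pad = np.zeros(n_blocks * BLOCK)
    lam_pad[: lam_col.size] = lam_col
    tiles = lam_pad.reshape(n_blocks, BLOCK)
    tables = ALL_CODES @ tiles.T  # (243, n_blocks)
    if centered:
        p_pad = np.zeros(n_blocks * BLOCK)
        p_pad[: lam_col.size] = np.asarray(p, dtype=np.float64).ravel()
        tables = tables - 2.0 * (p_pad.reshape(n_blocks, BLOCK) * tiles).sum(axis=1)
    return tables


# ---------------------------------------------------------------------------
# On-disk container (little-endian): magic "5COD", u8 version, u8 orientation
# (0 = by-snp, 1 = by-individual), u64 n_individuals, u64 n_snps, key bytes
# row-major, u64 missing count, then (u64 individual, u64 snp) pairs.
# ---------------------------------------------------------------------------

_HEADER = struct.Struct("<4sBBQQ")


def write_5codes(fc: FiveCodesMatrix, path) -> Path:
    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(
            _HEADER.pack(
                _5C_MAGIC,
                _5C_VERSION,
                0 if fc.orientation == BY_SNP else 1,
                fc.n_individuals,
                fc.n_snps,
            )
        )
        fh.write(fc.keys.tobytes())
        fh.write(struct.pack("<Q", fc.missing.shape[0]))
        fh.write(fc.missing.astype("<u8").tobytes())
    return path


def read_5codes(path) -> FiveCodesMatrix:
    raw = Path(path).read_bytes()
    if len(raw) < _HEADER.size:
        raise CorruptFileError(f"{path}: truncated header")
    magic, version, orient, n_g, n_s = _HEADER.unpack_from(raw)
    if magic != _5C_MAGIC or version != _5C_VERSION:
        raise UnsupportedFormatError(f"{path}: not a 5codes v{_5C_VERSION} container")
    orientation = BY_SNP if orient == 0 else BY_INDIVIDUAL
    rows, packed_len = (n_g, n_s) if orientation == BY_SNP else (n_s, n_g)
    n_blocks = -(-packed_len // BLOCK)
    off = _HEADER.size
    nk = rows * n_blocks
    if len(raw) < off + nk + 8:
        raise CorruptFileError(f"{path}: truncated key payload")
    keys = np.frombuffer(raw, dtype=np.uint8, count=nk, offset=off).reshape(rows, n_blocks)
    off += nk
    (n_missing,) = struct.unpack_from("<Q", raw, off)
    off += 8
    missing = np.frombuffer(raw, dtype="<u8", count=2 * n_missing, offset=off)
    return FiveCodesMatrix(
        n_individuals=n_g,
        n_snps=n_s,
        keys=keys.copy(),
        missing=missing.astype(np.int64).reshape(-1, 2),
        orientation=orientation,
    )
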