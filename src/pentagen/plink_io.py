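"""PLINK 1 binary genotype I/O and dosage / allele-frequency derivation.

The .bed/.bim/.fam trio stores biallelic genotypes SNP-major, four
individuals per byte.  Each 2-bit code is one of

====  =============================
code  meaning
====  =============================
0     homozygous for allele A1
1     missing call
2     heterozygous
3     homozygous for allele A2
====  =============================

with the first individual of each byte in the two least-significant bits.
Dosages count the A2 allele by default (code 3 -> 2); a flag flips the
orientation.  Missing calls are represented as dosage 0 plus an explicit
sparse index of (individual, snp) positions, which downstream code uses for
post-hoc corrections of centered products.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import CorruptFileError, DimensionError, UnsupportedFormatError

log = logging.getLogger("pentagen")

BED_MAGIC = b"\x6c\x1b"
SNP_MAJOR_MODE = 0x01
MISSING_CODE = 1

_SHIFTS = np.array([0, 2, 4, 6], dtype=np.uint8)
# 2-bit code -> A2-allele dosage (missing coded as zero)
CODE_TO_DOSAGE_A2 = np.array([0, 0, 1, 2], dtype=np.int8)
CODE_TO_DOSAGE_A1 = np.array([2, 0, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE_A2 = np.array([0, 2, 3], dtype=np.uint8)


def _bytes_per_snp(n_individuals: int) -> int:
    return (n_individuals + 3) // 4


@dataclass
class PackedBed:
    """SNP-major 2-bit genotype matrix, bit-exact as stored on disk.

    ``data`` has shape ``(n_snps, ceil(n_individuals/4))``; pad bit-pairs in
    the last byte of every SNP block are zero.
    """

    n_individuals: int
    n_snps: int
    data: np.ndarray
    snp_ids: list[str]
    individual_ids: list[str]
    bim: pd.DataFrame | None = field(default=None, repr=False)
    fam: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.ascontiguousarray(self.data, dtype=np.uint8)
        expected = (self.n_snps, _bytes_per_snp(self.n_individuals))
        if self.data.shape != expected:
            raise DimensionError(
                f"packed payload has shape {self.data.shape}, expected {expected}"
            )
        if len(self.snp_ids) != self.n_snps or len(self.individual_ids) != self.n_individuals:
            raise DimensionError("id list lengths do not match matrix dimensions")
        rem = self.n_individuals % 4
        if rem and self.n_snps:
            keep = np.uint8((1 << (2 * rem)) - 1)
            if np.any(self.data[:, -1] & ~keep):
                raise CorruptFileError("pad bit-pairs in last byte per SNP are not zero")

    @property
    def nbytes(self) -> int:
        return self.data.size

    def codes(self) -> np.ndarray:
        """Unpack to a ``(n_individuals, n_snps)`` array of raw 2-bit codes."""
        c = (self.data[:, :, None] >> _SHIFTS) & np.uint8(0b11)
        c = c.reshape(self.n_snps, -1)[:, : self.n_individuals]
        return np.ascontiguousarray(c.T)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PackedBed):
            return NotImplemented
        return (
            self.n_individuals == other.n_individuals
            and self.n_snps == other.n_snps
            and np.array_equal(self.data, other.data)
            and list(self.snp_ids) == list(other.snp_ids)
            and list(self.individual_ids) == list(other.individual_ids)
        )


def pack_codes(codes: np.ndarray) -> np.ndarray:
    """Pack an ``(n_individuals, n_snps)`` code array into SNP-major bytes."""
    codes = np.asarray(codes, dtype=np.uint8)
    n_g, n_s = codes.shape
    bps = _bytes_per_snp(n_g)
    padded = np.zeros((n_s, bps * 4), dtype=np.uint8)
    padded[:, :n_g] = codes.T
    lanes = padded.reshape(n_s, bps, 4)
    return (lanes << _SHIFTS).sum(axis=2, dtype=np.uint8)


@dataclass
class GenotypeMatrix:
    """Integer dosage matrix ``(n_individuals, n_snps)`` with entries in {0,1,2}.

    Missing calls are dosage 0 with their position listed in ``missing``
    (an ``(n_missing, 2)`` array of ``(individual, snp)`` index pairs).
    """

    dosages: np.ndarray
    missing: np.ndarray
    individual_ids: list[str] | None = None
    snp_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.dosages = np.ascontiguousarray(self.dosages, dtype=np.int8)
        self.missing = np.asarray(self.missing, dtype=np.int64).reshape(-1, 2)
        if self.missing.size:
            if np.any(self.dosages[self.missing[:, 0], self.missing[:, 1]] != 0):
                raise DimensionError("dosage at a missing position must be zero")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def missing_mask(self) -> np.ndarray:
        mask = np.zeros(self.dosages.shape, dtype=bool)
        if self.missing.size:
            mask[self.missing[:, 0], self.missing[:, 1]] = True
        return mask


@dataclass
class AlleleFrequencyVector:
    """Per-SNP frequency of the counted allele, entries in [0, 1]."""

    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=np.float64).ravel()
        if self.p.size and (self.p.min() < 0.0 or self.p.max() > 1.0):
            raise DimensionError("allele frequencies must lie in [0, 1]")

    def __len__(self) -> int:
        return self.p.size


def _resolve_paths(bed_path, bim_path, fam_path):
    bed = Path(bed_path)
    if bed.suffix != ".bed":
        bed = bed.with_suffix(".bed")
    bim = Path(bim_path) if bim_path is not None else bed.with_suffix(".bim")
    fam = Path(fam_path) if fam_path is not None else bed.with_suffix(".fam")
    return bed, bim, fam


def read_bed(bed_path, bim_path=None, fam_path=None) -> PackedBed:
    """Read a PLINK 1 binary trio; ``bed_path`` may be a prefix or the .bed file.

    Only SNP-major files (mode byte 0x01) are supported.  Raw 2-bit codes are
    preserved bit-exactly; pad bit-pairs are required to be zero.
    """
    bed, bim, fam = _resolve_paths(bed_path, bim_path, fam_path)
    bim_df = pd.read_csv(bim, sep=r"\s+", header=None, dtype=str)
    fam_df = pd.read_csv(fam, sep=r"\s+", header=None, dtype=str)
    n_s, n_g = len(bim_df), len(fam_df)

    raw = bed.read_bytes()
    if len(raw) < 3 or raw[:2] != BED_MAGIC:
        raise UnsupportedFormatError(f"{bed}: not a PLINK 1 .bed file (bad magic bytes)")
    if raw[2] != SNP_MAJOR_MODE:
        raise UnsupportedFormatError(
            f"{bed}: mode byte 0x{raw[2]:02x}; only SNP-major (0x01) files are supported"
        )
    bps = _bytes_per_snp(n_g)
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != n_s * bps:
        raise CorruptFileError(
            f"{bed}: payload is {payload.size} bytes, expected {n_s * bps} "
            f"for {n_g} individuals x {n_s} SNPs"
        )
    return PackedBed(
        n_individuals=n_g,
        n_snps=n_s,
        data=payload.reshape(n_s, bps),
        snp_ids=bim_df[1].tolist(),
        individual_ids=fam_df[1].tolist(),
        bim=bim_df,
        fam=fam_df,
    )


def write_bed(packed: PackedBed, bed_path, bim_path=None, fam_path=None) -> tuple[Path, Path, Path]:
    """Write a PLINK 1 binary trio; returns the three paths written."""
    bed, bim, fam = _resolve_paths(bed_path, bim_path, fam_path)
    with open(bed, "wb") as fh:
        fh.write(BED_MAGIC)
        fh.write(bytes([SNP_MAJOR_MODE]))
        fh.write(packed.data.tobytes())
    if packed.bim is not None:
        bim_df = packed.bim
    else:
        bim_df = pd.DataFrame(
            {
                0: ["1"] * packed.n_snps,
                1: packed.snp_ids,
                2: ["0"] * packed.n_snps,
                3: [str(i + 1) for i in range(packed.n_snps)],
                4: ["A"] * packed.n_snps,
                5: ["B"] * packed.n_snps,
            }
        )
    if packed.fam is not None:
        fam_df = packed.fam
    else:
        fam_df = pd.DataFrame(
            {
                0: packed.individual_ids,
                1: packed.individual_ids,
                2: ["0"] * packed.n_individuals,
                3: ["0"] * packed.n_individuals,
                4: ["0"] * packed.n_individuals,
                5: ["-9"] * packed.n_individuals,
            }
        )
    bim_df.to_csv(bim, sep="\t", header=False, index=False)
    fam_df.to_csv(fam, sep="\t", header=False, index=False)
    return bed, bim, fam


def unpack_genotypes(packed: PackedBed, count_allele: str = "a2") -> GenotypeMatrix:
    """Convert raw 2-bit codes to 0/1/2 dosages plus a missing index.

    ``count_allele='a2'`` counts the allele whose homozygote is code 3
    (default); ``'a1'`` flips the orientation.  Missing calls (code 1) become
    dosage 0 and are recorded in the missing set.
    """
    if count_allele not in ("a1", "a2"):
        raise ValueError("count_allele must be 'a1' or 'a2'")
    codes = packed.codes()
    table = CODE_TO_DOSAGE_A2 if count_allele == "a2" else CODE_TO_DOSAGE_A1
    dosages = table[codes]
    missing = np.argwhere(codes == MISSING_CODE)
    return GenotypeMatrix(
        dosages=dosages,
        missing=missing,
        individual_ids=list(packed.individual_ids),
        snp_ids=list(packed.snp_ids),
    )


def pack_genotypes(g: GenotypeMatrix) -> PackedBed:
    """Repack dosages (A2 orientation) and missing index into 2-bit codes."""
    codes = _DOSAGE_TO_CODE_A2[g.dosages]
    if g.missing.size:
        codes[g.missing[:, 0], g.missing[:, 1]] = MISSING_CODE
    n_g, n_s = g.dosages.shape
    return PackedBed(
        n_individuals=n_g,
        n_snps=n_s,
        data=pack_codes(codes),
        snp_ids=list(g.snp_ids) if g.snp_ids is not None else [f"snp{j}" for j in range(n_s)],
        individual_ids=(
            list(g.individual_ids) if g.individual_ids is not None else [f"ind{i}" for i in range(n_g)]
        ),
    )


def compute_allele_frequencies(g: GenotypeMatrix) -> AlleleFrequencyVector:
    """Observed allele frequencies p_j over non-missing calls.

    p_j = (sum of non-missing dosages) / (2 x number of non-missing calls).
    A SNP with every call missing gets p_j = 0 and a logged warning; such
    SNPs are retained, never dropped.
    """
    miss = g.missing_mask()
    n_called = (~miss).sum(axis=0)
    totals = g.dosages.astype(np.float64).sum(axis=0)  # missing already zero
    p = np.zeros(g.n_snps, dtype=np.float64)
    ok = n_called > 0
    p[ok] = totals[ok] / (2.0 * n_called[ok])
    if not ok.all():
        log.warning(
            "%d SNP(s) have no non-missing calls; their allele frequency is set to 0",
            int((~ok).sum()),
        )
    return AlleleFrequencyVector(p=p)
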