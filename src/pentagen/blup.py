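"""Pedigree relationship algebra and the matrix-free ssSNPBLUP PCG solver.

Pedigree side
-------------
The numerator relationship matrix A has a sparse inverse that Henderson's
rules assemble directly from the animal/sire/dam triples: animal i with
Mendelian-sampling variance d_i contributes alpha_i = 1/d_i at (i, i),
-alpha_i/2 between i and each known parent, and alpha_i/4 between known
parents, where d_i = 0.5 - 0.25*(F_s + F_d) with both parents known
(0.75 - 0.25*F_s with one, 1 with none; F is the inbreeding coefficient).
With ``use_inbreeding`` off the classical non-inbred alphas 2, 4/3, 1 are
used instead.  A itself is only ever formed densely at desk scale via the
recursive tabular method, which also yields F = diag(A) - 1.

A^-1 is partitioned by the genotyped mask into blocks A^nn, A^ng, A^gn,
A^gg.  Products with the inverse of the genotyped submatrix A_gg never
form it: A_gg^-1 v = A^gg v - A^gn (A^nn)^-1 A^ng v, with the sparse
factorization of A^nn computed once and reused.

Model side
----------
The single-step SNP BLUP observation model is y = X b + W_n u_n + W_g u_g
+ e with u_g = a_g + Z g (SNP effects g, residual polygenic effects a_g).
The joint precision of (u_n, u_g, g) is the 3x3 block matrix Sigma^-1
(scaled by 1/sigma_u^2) whose blocks involve A^nn, A^ng, A^gg,
(1/w - 1) A_gg^-1, -(1/w) A_gg^-1 Z and (1/w) Z' A_gg^-1 Z +
m/(1-w) I, where w is the residual polygenic proportion and
m = 2 sum_j p_j (1 - p_j).  The mixed model equations are assembled in
Henderson's standard form, scaled through by sigma_e^2:

    (T'T + sigma_e^2 * blockdiag(0, Sigma^-1)) theta = T'y,
    T = [X | W_n | W_g | 0],  theta = (b, u_n, u_g, g).

Every coefficient-matrix product is evaluated matrix-free: sparse products
for the A blocks, triangular solves for (A^nn)^-1, and the compressed
genotype kernels of :mod:`pentagen.matmul` for Z and Z'.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from ._errors import (
    DimensionError,
    DivergenceError,
    FactorizationError,
    ParameterError,
    PedigreeError,
)
from .fivecodes import FiveCodesMatrix, encode_matrix, transpose_packed
from .matmul import heterozygosity_scale, z_times, zt_times
from .plink_io import GenotypeMatrix, compute_allele_frequencies

log = logging.getLogger("pentagen")


# ---------------------------------------------------------------------------
# Pedigree container
# ---------------------------------------------------------------------------

@dataclass
class PedigreeFrame:
    """Animal/sire/dam triples with a genotyped mask and topological order.

    ``sire``/``dam`` hold 0-based parent indices, -1 for unknown.  ``order``
    is a permutation in which every parent precedes its offspring.
    """

    sire: np.ndarray
    dam: np.ndarray
    genotyped: np.ndarray
    ids: list[str] | None = None
    order: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        self.genotyped = np.asarray(self.genotyped, dtype=bool)
        n = self.sire.size
        if self.dam.size != n or self.genotyped.size != n:
            raise DimensionError("sire, dam and genotyped mask must have equal length")
        for parents in (self.sire, self.dam):
            if parents.size and (parents.min() < -1 or parents.max() >= n):
                raise PedigreeError("parent index out of range")
        if np.any((self.sire == np.arange(n)) & (self.sire >= 0)) or np.any(
            (self.dam == np.arange(n)) & (self.dam >= 0)
        ):
            raise PedigreeError("animal cannot be its own parent")
        if self.order is None:
            self.order = self._topological_order()
        else:
            self.order = np.asarray(self.order, dtype=np.int64)

    @property
    def n_animals(self) -> int:
        return self.sire.size

    def _topological_order(self) -> np.ndarray:
        """Kahn's algorithm; raises on cycles, warns if input order is not topological."""
        n = self.n_animals
        children: list[list[int]] = [[] for _ in range(n)]
        indeg = np.zeros(n, dtype=np.int64)
        for i in range(n):
            for par in (self.sire[i], self.dam[i]):
                if par >= 0:
                    children[par].append(i)
                    indeg[i] += 1
        ready = sorted(np.flatnonzero(indeg == 0).tolist())
        order = []
        while ready:
            i = ready.pop(0)
            order.append(i)
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    ready.append(c)
        if len(order) != n:
            raise PedigreeError("pedigree contains a cycle")
        idx = np.arange(n)
        if np.any(self.sire > idx) or np.any(self.dam > idx):
            log.warning("pedigree not in chronological order; using topological order")
        return np.asarray(order, dtype=np.int64)

    @classmethod
    def from_table(cls, animal, sire, dam, genotyped=None, ids_are_labels=True) -> "PedigreeFrame":
        """Build from raw id triples; 0 (or '0') denotes an unknown parent."""
        animal = [str(a) for a in animal]
        index = {a: i for i, a in enumerate(animal)}
        if len(index) != len(animal):
            raise PedigreeError("duplicate animal ids")

        def resolve(parent):
            out = np.empty(len(animal), dtype=np.int64)
            for i, p in enumerate(parent):
                p = str(p)
                if p == "0":
                    out[i] = -1
                elif p in index:
                    out[i] = index[p]
                else:
                    raise PedigreeError(f"parent {p!r} is not listed as an animal")
            return out

        if genotyped is None:
            genotyped = np.zeros(len(animal), dtype=bool)
        return cls(
            sire=resolve(sire), dam=resolve(dam),
            genotyped=np.asarray(genotyped, dtype=bool), ids=animal,
        )


def tabular_relationship_matrix(ped: PedigreeFrame) -> np.ndarray:
    """Dense A by the recursive tabular method (O(n^2) memory; desk scale)."""
    n = ped.n_animals
    A = np.zeros((n, n))
    for i in ped.order:
        s, d = ped.sire[i], ped.dam[i]
        row = np.zeros(n)
        if s >= 0:
            row += 0.5 * A[s]
        if d >= 0:
            row += 0.5 * A[d]
        A[i, :] = row
        A[:, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return A


def inbreeding_coefficients(ped: PedigreeFrame) -> np.ndarray:
    """F_i = 0.5 * A(sire_i, dam_i), i.e. diag(A) - 1 from the tabular method."""
    return np.diag(tabular_relationship_matrix(ped)) - 1.0


# ---------------------------------------------------------------------------
# Sparse inverse of A, partitioned by genotyped status
# ---------------------------------------------------------------------------

@dataclass
class SparseAinverse:
    """Blocks A^nn, A^ng, A^gn, A^gg of A^-1 plus inbreeding coefficients."""

    ann: sp.csc_matrix
    ang: sp.csr_matrix
    agn: sp.csr_matrix
    agg: sp.csr_matrix
    inbreeding: np.ndarray
    nong_idx: np.ndarray
    geno_idx: np.ndarray
    _ann_factor: object = field(default=None, repr=False, compare=False)

    @property
    def n_non(self) -> int:
        return self.nong_idx.size

    @property
    def n_gen(self) -> int:
        return self.geno_idx.size

    def full(self) -> sp.csr_matrix:
        """Reassemble A^-1 in original animal order (testing convenience)."""
        n = self.n_non + self.n_gen
        perm = np.concatenate([self.nong_idx, self.geno_idx])
        block = sp.bmat([[self.ann, self.ang], [self.agn, self.agg]], format="csr")
        P = sp.csr_matrix((np.ones(n), (perm, np.arange(n))), shape=(n, n))
        return P @ block @ P.T

    def ann_solve(self, v: np.ndarray) -> np.ndarray:
        """Solve A^nn x = v with the cached sparse factorization."""
        if self._ann_factor is None:
            try:
                self._ann_factor = splu(self.ann.tocsc())
            except RuntimeError as exc:  # singular
                raise FactorizationError(f"A^nn factorization failed: {exc}") from exc
        return self._ann_factor.solve(v)


def build_a_inverse(ped: PedigreeFrame, use_inbreeding: bool = True) -> SparseAinverse:
    """Assemble A^-1 by Henderson's rules and split it by the genotyped mask."""
    n = ped.n_animals
    s, d = ped.sire, ped.dam
    has_s, has_d = s >= 0, d >= 0
    n_known = has_s.astype(int) + has_d.astype(int)

    if use_inbreeding:
        F = inbreeding_coefficients(ped)
        Fs = np.where(has_s, F[np.where(has_s, s, 0)], 0.0)
        Fd = np.where(has_d, F[np.where(has_d, d, 0)], 0.0)
        mendelian = np.select(
            [n_known == 2, n_known == 1],
            [0.5 - 0.25 * (Fs + Fd), 0.75 - 0.25 * (Fs + Fd)],
            default=1.0,
        )
        alpha = 1.0 / mendelian
    else:
        F = np.zeros(n)
        alpha = np.select([n_known == 2, n_known == 1], [2.0, 4.0 / 3.0], default=1.0)

    rows, cols, vals = [np.arange(n)], [np.arange(n)], [alpha]
    for par, has in ((s, has_s), (d, has_d)):
        i = np.flatnonzero(has)
        rows += [i, par[i]]
        cols += [par[i], i]
        vals += [-alpha[i] / 2.0, -alpha[i] / 2.0]
        rows.append(par[i])
        cols.append(par[i])
        vals.append(alpha[i] / 4.0)
    both = np.flatnonzero(has_s & has_d)
    rows += [s[both], d[both]]
    cols += [d[both], s[both]]
    vals += [alpha[both] / 4.0, alpha[both] / 4.0]

    ainv = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    ).tocsr()

    nong = np.flatnonzero(~ped.genotyped)
    geno = np.flatnonzero(ped.genotyped)
    return SparseAinverse(
        ann=ainv[nong][:, nong].tocsc(),
        ang=ainv[nong][:, geno].tocsr(),
        agn=ainv[geno][:, nong].tocsr(),
        agg=ainv[geno][:, geno].tocsr(),
        inbreeding=F,
        nong_idx=nong,
        geno_idx=geno,
    )


def agg_inverse_times(ainv: SparseAinverse, v: np.ndarray) -> np.ndarray:
    """Apply A_gg^-1 = A^gg - A^gn (A^nn)^-1 A^ng without forming A_gg.

    Accepts a vector or a (n_gen, k) matrix over the genotyped animals.
    """
    v = np.asarray(v, dtype=np.float64)
    if v.shape[0] != ainv.n_gen:
        raise DimensionError(f"v has leading dimension {v.shape[0]}, expected {ainv.n_gen}")
    out = ainv.agg @ v
    if ainv.n_non:
        out = out - ainv.agn @ ainv.ann_solve(ainv.ang @ v)
    return out


# ---------------------------------------------------------------------------
# ssSNPBLUP model
# ---------------------------------------------------------------------------

@dataclass
class SSModel:
    """All operands of the ssSNPBLUP system.

    Unknown layout: theta = (b, u_n, u_g, g) of lengths (n_fixed, n_non,
    n_gen, n_snps).  W_n/W_g rows align with the records in y; genotype
    kernels (fc, fcT, p) are over the genotyped animals in ``geno_idx``
    order of the accompanying :class:`SparseAinverse`.
    """

    y: np.ndarray
    X: sp.csr_matrix
    W_n: sp.csr_matrix
    W_g: sp.csr_matrix
    fc: FiveCodesMatrix
    fcT: FiveCodesMatrix
    p: np.ndarray
    m: float
    w: float
    sigma2_u: float
    sigma2_e: float

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64).ravel()
        if not 0.0 < self.w < 1.0:
            raise ParameterError(f"w must lie strictly in (0, 1), got {self.w}")
        if self.sigma2_u <= 0 or self.sigma2_e <= 0:
            raise ParameterError("variance components must be positive")
        if self.m <= 0:
            raise ParameterError("scaling constant m must be positive")
        n_rec = self.y.size
        for name, mat in (("X", self.X), ("W_n", self.W_n), ("W_g", self.W_g)):
            if mat.shape[0] != n_rec:
                raise DimensionError(f"{name} has {mat.shape[0]} rows, expected {n_rec}")
        w_ones = np.asarray(self.W_n.sum(axis=1)).ravel() + np.asarray(self.W_g.sum(axis=1)).ravel()
        if n_rec and not np.array_equal(w_ones, np.ones(n_rec)):
            raise DimensionError("each record must map to exactly one animal")
        if self.fc.n_snps != self.p.size:
            raise DimensionError("allele frequency length must equal n_snps")

    @property
    def n_fixed(self) -> int:
        return self.X.shape[1]

    @property
    def n_non(self) -> int:
        return self.W_n.shape[1]

    @property
    def n_gen(self) -> int:
        return self.W_g.shape[1]

    @property
    def n_snps(self) -> int:
        return self.fc.n_snps

    @property
    def n_unknowns(self) -> int:
        return self.n_fixed + self.n_non + self.n_gen + self.n_snps

    def split(self, theta: np.ndarray):
        """Split a stacked unknown vector into (b, u_n, u_g, g)."""
        o1 = self.n_fixed
        o2 = o1 + self.n_non
        o3 = o2 + self.n_gen
        return theta[:o1], theta[o1:o2], theta[o2:o3], theta[o3:]


def build_ssmodel(
    ped: PedigreeFrame,
    genotypes: GenotypeMatrix,
    y: np.ndarray,
    record_animal: np.ndarray,
    fixed_codes: np.ndarray,
    w: float = 0.20,
    sigma2_u: float = 1.0,
    sigma2_e: float = 1.0,
    p=None,
) -> tuple[SSModel, SparseAinverse]:
    """Assemble an SSModel and its A^-1 blocks from raw components.

    ``genotypes`` rows must follow the genotyped animals in ascending
    pedigree-index order; ``record_animal`` maps each record to a 0-based
    animal index; ``fixed_codes`` are integer fixed-effect levels.  The
    default centering frequencies are the observed ones.
    """
    ainv = build_a_inverse(ped)
    if genotypes.n_individuals != ainv.n_gen:
        raise DimensionError("genotype matrix rows must equal number of genotyped animals")
    if p is None:
        p = compute_allele_frequencies(genotypes).p
    else:
        p = np.asarray(p, dtype=np.float64).ravel()
    fc = encode_matrix(genotypes)
    fcT = transpose_packed(genotypes)

    y = np.asarray(y, dtype=np.float64).ravel()
    record_animal = np.asarray(record_animal, dtype=np.int64).ravel()
    fixed_codes = np.asarray(fixed_codes, dtype=np.int64).ravel()
    n_rec = y.size
    levels, level_idx = np.unique(fixed_codes, return_inverse=True)
    X = sp.csr_matrix(
        (np.ones(n_rec), (np.arange(n_rec), level_idx)), shape=(n_rec, levels.size)
    )

    pos_non = -np.ones(ped.n_animals, dtype=np.int64)
    pos_non[ainv.nong_idx] = np.arange(ainv.n_non)
    pos_gen = -np.ones(ped.n_animals, dtype=np.int64)
    pos_gen[ainv.geno_idx] = np.arange(ainv.n_gen)

    is_gen = ped.genotyped[record_animal]
    rec = np.arange(n_rec)
    W_n = sp.csr_matrix(
        (np.ones((~is_gen).sum()), (rec[~is_gen], pos_non[record_animal[~is_gen]])),
        shape=(n_rec, ainv.n_non),
    )
    W_g = sp.csr_matrix(
        (np.ones(is_gen.sum()), (rec[is_gen], pos_gen[record_animal[is_gen]])),
        shape=(n_rec, ainv.n_gen),
    )
    model = SSModel(
        y=y, X=X, W_n=W_n, W_g=W_g, fc=fc, fcT=fcT, p=p,
        m=heterozygosity_scale(p), w=w, sigma2_u=sigma2_u, sigma2_e=sigma2_e,
    )
    return model, ainv


def sigma_inverse_times(model: SSModel, ainv: SparseAinverse, v) -> np.ndarray:
    """Matrix-free product of the joint precision Sigma^-1 with (v_n, v_g, v_snp).

    Block rows (all scaled by 1/sigma_u^2):

        n:   A^nn v_n + A^ng v_g
        g:   A^gn v_n + A^gg v_g + (1/w - 1) A_gg^-1 v_g - (1/w) A_gg^-1 Z v_snp
        snp: -(1/w) Z' A_gg^-1 v_g + (1/w) Z' A_gg^-1 Z v_snp + m/(1-w) v_snp
    """
    if isinstance(v, (tuple, list)):
        v = np.concatenate([np.asarray(part, dtype=np.float64).ravel() for part in v])
    v = np.asarray(v, dtype=np.float64).ravel()
    n_non, n_gen, n_snp = model.n_non, model.n_gen, model.n_snps
    if v.size != n_non + n_gen + n_snp:
        raise DimensionError("v must stack (v_n, v_g, v_snp)")
    v_n, v_g, v_s = v[:n_non], v[n_non : n_non + n_gen], v[n_non + n_gen :]
    w = model.w

    out_n = ainv.ann @ v_n + ainv.ang @ v_g
    out_g = ainv.agn @ v_n + ainv.agg @ v_g

    u1 = agg_inverse_times(ainv, v_g)
    zv = z_times(model.fc, model.p, v_s[:, None]).values.ravel()
    u2 = agg_inverse_times(ainv, zv)
    out_g = out_g + (1.0 / w - 1.0) * u1 - (1.0 / w) * u2

    t = (u2 - u1) / w
    out_s = zt_times(model.fcT, model.p, t[:, None]).values.ravel()
    out_s = out_s + model.m / (1.0 - w) * v_s

    return np.concatenate([out_n, out_g, out_s]) / model.sigma2_u


def mme_operator_times(model: SSModel, ainv: SparseAinverse, theta) -> np.ndarray:
    """Coefficient-matrix product of the sigma_e^2-scaled MME.

    C theta = T'T theta + sigma_e^2 * blockdiag(0, Sigma^-1) theta_random,
    T = [X | W_n | W_g | 0].
    """
    theta = np.asarray(theta, dtype=np.float64).ravel()
    if theta.size != model.n_unknowns:
        raise DimensionError(f"theta has length {theta.size}, expected {model.n_unknowns}")
    b, u_n, u_g, g = model.split(theta)
    t_theta = model.X @ b + model.W_n @ u_n + model.W_g @ u_g
    out = np.concatenate(
        [model.X.T @ t_theta, model.W_n.T @ t_theta, model.W_g.T @ t_theta, np.zeros(model.n_snps)]
    )
    random = sigma_inverse_times(model, ainv, np.concatenate([u_n, u_g, g]))
    out[model.n_fixed :] += model.sigma2_e * random
    return out


def assemble_dense_mme(model: SSModel, ainv: SparseAinverse) -> tuple[np.ndarray, np.ndarray]:
    """Densify the MME by probing the operator with unit vectors; returns (C, rhs).

    Intended for desk-scale verification against a direct solve of the
    identical system.
    """
    n = model.n_unknowns
    C = np.empty((n, n))
    e = np.zeros(n)
    for j in range(n):
        e[j] = 1.0
        C[:, j] = mme_operator_times(model, ainv, e)
        e[j] = 0.0
    rhs = np.concatenate(
        [model.X.T @ model.y, model.W_n.T @ model.y, model.W_g.T @ model.y, np.zeros(model.n_snps)]
    )
    return C, rhs


# ---------------------------------------------------------------------------
# Preconditioned conjugate gradient
# ---------------------------------------------------------------------------

@dataclass
class SolveResult:
    """PCG solution split into effect blocks, with convergence diagnostics."""

    b: np.ndarray
    u_n: np.ndarray
    u_g: np.ndarray
    g: np.ndarray
    x: np.ndarray
    iterations: int
    residual_history: np.ndarray
    converged: bool


def pcg_solve(
    operator,
    rhs: np.ndarray,
    preconditioner: np.ndarray,
    tol: float = 1e-13,
    max_iter: int = 10000,
):
    """Jacobi-style PCG; stops when ||r||^2 / ||rhs||^2 < tol.

    ``operator`` maps a vector to the coefficient-matrix product;
    ``preconditioner`` is the positive diagonal.  Returns
    ``(x, iterations, residual_history, converged)``; the history records
    the squared relative residual per iteration.
    """
    rhs = np.asarray(rhs, dtype=np.float64).ravel()
    d = np.asarray(preconditioner, dtype=np.float64).ravel()
    if d.size != rhs.size:
        raise DimensionError("preconditioner length must match rhs")
    if np.any(d <= 0):
        raise ParameterError("preconditioner diagonal must be positive")
    x = np.zeros_like(rhs)
    b_norm2 = float(rhs @ rhs)
    if b_norm2 == 0.0:
        return x, 0, np.zeros(0), True
    r = rhs.copy()
    z = r / d
    s = z.copy()
    rz = float(r @ z)
    history = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        q = operator(s)
        sq = float(s @ q)
        if not np.isfinite(sq) or sq <= 0.0:
            raise DivergenceError(f"non-positive or non-finite curvature at iteration {it}", it)
        alpha = rz / sq
        x += alpha * s
        r -= alpha * q
        rel = float(r @ r) / b_norm2
        history.append(rel)
        if not np.isfinite(rel):
            raise DivergenceError(f"non-finite residual at iteration {it}", it)
        if rel < tol:
            converged = True
            break
        z = r / d
        rz_new = float(r @ z)
        s = z + (rz_new / rz) * s
        rz = rz_new
    return x, it, np.asarray(history), converged


def _mme_preconditioner(model: SSModel, ainv: SparseAinverse) -> np.ndarray:
    """Diagonal of T'T plus the cheap diagonal of sigma_e^2 * Sigma^-1.

    The exact diagonals of the sparse A blocks and the m/(1-w) SNP term are
    included; the dense diagonal of (1/w) Z' A_gg^-1 Z (and the A_gg^-1
    correction in the g block) is omitted — this only affects the
    convergence rate, never the solution.
    """
    lam_e = model.sigma2_e / model.sigma2_u
    d_t = np.concatenate(
        [
            np.asarray(model.X.multiply(model.X).sum(axis=0)).ravel(),
            np.asarray(model.W_n.multiply(model.W_n).sum(axis=0)).ravel(),
            np.asarray(model.W_g.multiply(model.W_g).sum(axis=0)).ravel(),
            np.zeros(model.n_snps),
        ]
    )
    d_sigma = np.concatenate(
        [
            np.zeros(model.n_fixed),
            lam_e * ainv.ann.diagonal(),
            lam_e * ainv.agg.diagonal(),
            np.full(model.n_snps, lam_e * model.m / (1.0 - model.w)),
        ]
    )
    d = d_t + d_sigma
    return np.where(d > 0, d, 1.0)


def solve_ssSNPBLUP(
    model: SSModel,
    ainv: SparseAinverse,
    tol: float = 1e-13,
    max_iter: int = 10000,
) -> SolveResult:
    """Solve the ssSNPBLUP MME matrix-free with PCG.

    Returns block-labelled estimates; ``u_g`` is the total breeding value
    of the genotyped animals (u_g = a_g + Z g), estimated directly as an
    unknown of the system.
    """
    rhs = np.concatenate(
        [model.X.T @ model.y, model.W_n.T @ model.y, model.W_g.T @ model.y, np.zeros(model.n_snps)]
    )
    x, iterations, history, converged = pcg_solve(
        lambda v: mme_operator_times(model, ainv, v),
        rhs,
        _mme_preconditioner(model, ainv),
        tol=tol,
        max_iter=max_iter,
    )
    if not converged and history.size:
        log.warning("PCG stopped at max_iter=%d with residual %.3e", max_iter, history[-1])
    b, u_n, u_g, g = model.split(x)
    return SolveResult(
        b=b, u_n=u_n, u_g=u_g, g=g, x=x,
        iterations=iterations, residual_history=history, converged=converged,
    )
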