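"""Independent brute-force oracles used by the test suite.

Everything here is computed by literal dense linear algebra from first
principles (tabular relationship matrix, explicit matrix inverses, dense
centered genotype matrices) so that it shares no code path with the packed
kernels, the Henderson assembly, or the matrix-free operators it checks.
"""

import numpy as np

from pentagen.blup import PedigreeFrame, tabular_relationship_matrix
from pentagen.plink_io import GenotypeMatrix


def random_pedigree(n, rng, p_unknown=0.2, p_genotyped=0.5):
    """A random acyclic pedigree: parents drawn from earlier animals.

    Produces overlapping generations, parent-offspring and sib matings, so
    nonzero inbreeding arises naturally.
    """
    sire = np.full(n, -1, dtype=np.int64)
    dam = np.full(n, -1, dtype=np.int64)
    for i in range(2, n):
        if rng.random() > p_unknown:
            sire[i] = rng.integers(0, i)
        if rng.random() > p_unknown:
            d = rng.integers(0, i)
            dam[i] = d if d != sire[i] else -1
    genotyped = rng.random(n) < p_genotyped
    if not genotyped.any():
        genotyped[n - 1] = True
    return PedigreeFrame(sire=sire, dam=dam, genotyped=genotyped)


def random_genotypes(rng, n_g, n_s, missing_rate=0.0):
    """Random dosage matrix with a sparse missing set (dosage zeroed)."""
    d = rng.integers(0, 3, size=(n_g, n_s)).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random((n_g, n_s)) < missing_rate
        missing = np.argwhere(mask)
        d[mask] = 0
    else:
        missing = np.empty((0, 2), dtype=np.int64)
    return GenotypeMatrix(dosages=d, missing=missing)


def dense_centered(g: GenotypeMatrix, p, missing_policy="mean"):
    """Dense Z = M - 2*1p' with the missing policy applied explicitly."""
    z = g.dosages.astype(np.float64) - 2.0 * np.asarray(p)[None, :]
    if missing_policy == "mean":
        z[g.missing_mask()] = 0.0
    return z


def dense_sigma_inverse(ped: PedigreeFrame, geno: GenotypeMatrix, p, w, sigma2_u):
    """Dense assembly of the joint precision of (u_n, u_g, g).

    A^-1 blocks come from numpy's inverse of the tabular A (not Henderson's
    rules); A_gg^-1 from the dense inverse of the genotyped submatrix of A.
    """
    A = tabular_relationship_matrix(ped)
    Ainv = np.linalg.inv(A)
    nong = np.flatnonzero(~ped.genotyped)
    geno_idx = np.flatnonzero(ped.genotyped)
    Ann = Ainv[np.ix_(nong, nong)]
    Ang = Ainv[np.ix_(nong, geno_idx)]
    Agn = Ainv[np.ix_(geno_idx, nong)]
    Agg_blk = Ainv[np.ix_(geno_idx, geno_idx)]
    Agg_inv = np.linalg.inv(A[np.ix_(geno_idx, geno_idx)])
    Z = dense_centered(geno, p)
    m = 2.0 * np.sum(np.asarray(p) * (1.0 - np.asarray(p)))
    n_s = Z.shape[1]
    top = np.hstack([Ann, Ang, np.zeros((nong.size, n_s))])
    mid = np.hstack([Agn, Agg_blk + (1.0 / w - 1.0) * Agg_inv, -(1.0 / w) * Agg_inv @ Z])
    bot = np.hstack(
        [
            np.zeros((n_s, nong.size)),
            -(1.0 / w) * Z.T @ Agg_inv,
            (1.0 / w) * Z.T @ Agg_inv @ Z + m / (1.0 - w) * np.eye(n_s),
        ]
    )
    return np.vstack([top, mid, bot]) / sigma2_u


def dense_mme(ped, geno, p, y, X, W_n, W_g, w, sigma2_u, sigma2_e):
    """Dense MME coefficient matrix and right-hand side, scaled by sigma_e^2."""
    Xd = np.asarray(X.todense(), dtype=float)
    Wnd = np.asarray(W_n.todense(), dtype=float)
    Wgd = np.asarray(W_g.todense(), dtype=float)
    n_s = geno.n_snps
    T = np.hstack([Xd, Wnd, Wgd, np.zeros((len(y), n_s))])
    sigma_inv = dense_sigma_inverse(ped, geno, p, w, sigma2_u)
    C = T.T @ T
    nf = Xd.shape[1]
    C[nf:, nf:] += sigma2_e * sigma_inv
    return C, T.T @ np.asarray(y, dtype=float)
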