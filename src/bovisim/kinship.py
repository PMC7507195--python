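"""Relationship matrices for single-step evaluation.

* ``build_A_inverse`` — sparse inverse of the pedigree numerator
  relationship matrix via Henderson's rules with inbreeding, the
  inbreeding coefficients coming from the Meuwissen & Luo (1992)
  algorithm.
* ``build_A22`` / ``A_block`` — dense blocks of A computed indirectly
  through the factorisation A = T D T' (Colleau 2002), never forming the
  full matrix.
* ``build_G`` — VanRaden (2008) method-1 genomic relationship matrix.
* ``tune_G`` — two-scalar mean-matching adjustment that puts G on the
  pedigree base-population scale (Christensen et al. style; the common
  software default).
* ``build_H_inverse`` — A-inverse plus the genotyped-block correction
  ``(alpha G + beta A22)^-1 - A22^-1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from numba import njit
from scipy.linalg import cho_factor, cho_solve
from scipy.sparse.linalg import spsolve_triangular

logger = logging.getLogger(__name__)

__all__ = [
    "PedigreeRelationship", "GenomicRelationship", "HInverse",
    "build_A_inverse", "build_A22", "A_block", "build_G", "tune_G",
    "build_H_inverse", "h_submatrix",
]


# --------------------------------------------------------------------------
# inbreeding (Meuwissen & Luo 1992)
# --------------------------------------------------------------------------

@njit(cache=True)
def _inbreeding_ml(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """F coefficients for a pedigree sorted parents-before-offspring.

    ``sire``/``dam`` are 0-based parent row indices, -1 for unknown.
    """
    n = len(sire)
    F = np.zeros(n)
    L = np.zeros(n)
    D = np.zeros(n)
    active = np.zeros(n, dtype=np.uint8)
    for i in range(n):
        s, d = sire[i], dam[i]
        fs = F[s] if s >= 0 else -1.0
        fd = F[d] if d >= 0 else -1.0
        D[i] = 0.5 - 0.25 * (fs + fd)
        if s < 0 or d < 0:
            F[i] = 0.0
            continue
        fi = -1.0
        L[i] = 1.0
        active[i] = 1
        for j in range(i, -1, -1):
            if active[j] == 0:
                continue
            active[j] = 0
            lj = L[j]
            L[j] = 0.0
            sj, dj = sire[j], dam[j]
            if sj >= 0:
                L[sj] += 0.5 * lj
                active[sj] = 1
            if dj >= 0:
                L[dj] += 0.5 * lj
                active[dj] = 1
            fi += lj * lj * D[j]
        F[i] = fi
    return F


@dataclass
class PedigreeRelationship:
    """Sparse A-inverse plus the pieces of the factorisation A = T D T'."""

    A_inverse: sp.csr_matrix
    inbreeding: np.ndarray           # F per individual
    mendelian_d: np.ndarray          # Mendelian-sampling variances d_i
    sire: np.ndarray                 # 0-based rows, -1 unknown
    dam: np.ndarray
    _I_minus_P: sp.csr_matrix = field(repr=False, default=None)

    @property
    def n(self) -> int:
        return self.A_inverse.shape[0]

    # solve_mme interface
    def matvec(self, v: np.ndarray) -> np.ndarray:
        return self.A_inverse @ v

    def diagonal(self) -> np.ndarray:
        return self.A_inverse.diagonal()

    def to_dense(self) -> np.ndarray:
        return self.A_inverse.toarray()

    def A_times(self, V: np.ndarray) -> np.ndarray:
        """A @ V through two triangular solves (Colleau's indirect method)."""
        IP = self._I_minus_P
        x = spsolve_triangular(IP.T.tocsr(), np.asarray(V, dtype=np.float64),
                               lower=False, unit_diagonal=True)
        x *= self.mendelian_d[:, None] if x.ndim == 2 else self.mendelian_d
        return spsolve_triangular(IP, x, lower=True, unit_diagonal=True)


def _parents_to_rows(pedigree: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    ids = pedigree["id"].to_numpy()
    if list(ids) != list(range(1, len(ids) + 1)):
        raise ValueError("pedigree ids must be 1..n in row order")
    sire = pedigree["sire"].to_numpy(dtype=np.int64) - 1
    dam = pedigree["dam"].to_numpy(dtype=np.int64) - 1
    for par in (sire, dam):
        bad = par >= np.arange(len(par))
        if np.any(bad & (par >= 0)):
            raise ValueError("individual listed before (or as) its own ancestor")
    return sire, dam


def build_A_inverse(pedigree: pd.DataFrame) -> PedigreeRelationship:
    """Henderson's rules with inbreeding for a parents-first pedigree."""
    sire, dam = _parents_to_rows(pedigree)
    n = len(sire)
    F = _inbreeding_ml(sire, dam)
    fs = np.where(sire >= 0, F[np.maximum(sire, 0)], -1.0)
    fd = np.where(dam >= 0, F[np.maximum(dam, 0)], -1.0)
    d = 0.5 - 0.25 * (fs + fd)
    alpha = 1.0 / d

    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i); cols.append(j); vals.append(v)

    for i in range(n):
        a = alpha[i]
        s, dm = sire[i], dam[i]
        add(i, i, a)
        for p in (s, dm):
            if p >= 0:
                add(p, p, 0.25 * a)
                add(i, p, -0.5 * a)
                add(p, i, -0.5 * a)
        if s >= 0 and dm >= 0:
            add(s, dm, 0.25 * a)
            add(dm, s, 0.25 * a)
    Ainv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()

    P = sp.coo_matrix(
        (np.r_[np.full((sire >= 0).sum(), 0.5), np.full((dam >= 0).sum(), 0.5)],
         (np.r_[np.flatnonzero(sire >= 0), np.flatnonzero(dam >= 0)],
          np.r_[sire[sire >= 0], dam[dam >= 0]])),
        shape=(n, n))
    I_minus_P = (sp.identity(n, format="csr") - P.tocsr()).tocsr()
    return PedigreeRelationship(Ainv, F, d, sire, dam, I_minus_P)


def A_block(rel: PedigreeRelationship, rows: np.ndarray, cols: np.ndarray,
            chunk: int = 2000) -> np.ndarray:
    """Dense A[rows, cols] without forming A (indirect method)."""
    rows = np.asarray(rows, dtype=np.int64)
    cols = np.asarray(cols, dtype=np.int64)
    out = np.empty((len(rows), len(cols)))
    for lo in range(0, len(cols), chunk):
        sub = cols[lo:lo + chunk]
        E = np.zeros((rel.n, len(sub)))
        E[sub, np.arange(len(sub))] = 1.0
        out[:, lo:lo + chunk] = rel.A_times(E)[rows]
    return out


def build_A22(rel: PedigreeRelationship, genotyped_rows: np.ndarray) -> np.ndarray:
    """Pedigree relationship block among genotyped animals."""
    g = np.asarray(genotyped_rows, dtype=np.int64)
    if np.any(g < 0) or np.any(g >= rel.n):
        raise ValueError("unknown genotyped ids")
    A22 = A_block(rel, g, g)
    return 0.5 * (A22 + A22.T)


# --------------------------------------------------------------------------
# genomic relationship
# --------------------------------------------------------------------------

@dataclass
class GenomicRelationship:
    G: np.ndarray
    allele_freqs: np.ndarray
    n_excluded_monomorphic: int = 0
    tuning: tuple | None = None       # (a, b) once tuned
    alpha: float | None = None
    beta: float | None = None


def build_G(genotype_matrix: np.ndarray, allele_freqs: np.ndarray | None = None,
            weights: np.ndarray | None = None) -> GenomicRelationship:
    """VanRaden method-1 GRM: G = M D M' / (2 sum p(1-p)).

    ``genotype_matrix`` holds 0/1/2 allele counts (animals x loci).
    Monomorphic loci (frequency 0 or 1) are excluded with a logged count.
    ``weights`` is the optional per-SNP diagonal D used by weighted
    single-step GWAS (defaults to 1).
    """
    X = np.asarray(genotype_matrix, dtype=np.float64)
    if X.min() < 0 or X.max() > 2:
        raise ValueError("genotypes must be coded 0/1/2")
    p = X.mean(axis=0) / 2.0 if allele_freqs is None else np.asarray(allele_freqs, float)
    poly = (p > 0.0) & (p < 1.0)
    n_excl = int((~poly).sum())
    if n_excl:
        logger.info("build_G: excluded %d monomorphic loci", n_excl)
    if not np.any(poly):
        raise ValueError("no polymorphic loci")
    Xp, pp = X[:, poly], p[poly]
    M = Xp - 2.0 * pp
    denom = 2.0 * float(np.sum(pp * (1.0 - pp)))
    if weights is not None:
        w = np.asarray(weights, float)[poly]
        G = (M * w) @ M.T / denom
    else:
        G = M @ M.T / denom
    return GenomicRelationship(0.5 * (G + G.T), p, n_excl)


def tune_G(grm: GenomicRelationship | np.ndarray, A22: np.ndarray):
    """Rescale G so its mean diagonal/off-diagonal match those of A22.

    Solves ``a + b * mean(diag G) = mean(diag A22)`` and
    ``a + b * mean(offdiag G) = mean(offdiag A22)`` and returns
    ``(G_tuned, a, b)``.
    """
    G = grm.G if isinstance(grm, GenomicRelationship) else np.asarray(grm)
    if G.shape != A22.shape:
        raise ValueError("G and A22 must be conformable")
    n = G.shape[0]
    dG, dA = np.mean(np.diag(G)), np.mean(np.diag(A22))
    if n > 1:
        oG = (G.sum() - np.trace(G)) / (n * (n - 1))
        oA = (A22.sum() - np.trace(A22)) / (n * (n - 1))
    else:
        oG, oA = 0.0, 0.0
    if abs(dG - oG) < 1e-12:
        raise ValueError("degenerate tuning system: G has constant entries")
    b = (dA - oA) / (dG - oG)
    a = dA - b * dG
    Gt = a + b * G
    if isinstance(grm, GenomicRelationship):
        grm.tuning = (a, b)
    return Gt, a, b


# --------------------------------------------------------------------------
# H-inverse
# --------------------------------------------------------------------------

def _inv_pd(M: np.ndarray, what: str, suggest_beta: bool = False) -> np.ndarray:
    hint = "; consider beta > 0 in the blend" if suggest_beta else ""
    try:
        c = cho_factor(M, lower=True)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(f"{what} is singular/not positive definite{hint}") from e
    piv = np.abs(np.diag(c[0]))
    # LAPACK accepts numerically zero pivots; treat those as singular too
    if piv.min() <= np.sqrt(np.finfo(float).eps) * piv.max():
        raise np.linalg.LinAlgError(f"{what} is singular/not positive definite{hint}")
    return cho_solve(c, np.eye(M.shape[0]))


@dataclass
class HInverse:
    """A-inverse plus the genotyped-block correction of single-step BLUP."""

    rel: PedigreeRelationship
    genotyped_rows: np.ndarray
    correction: np.ndarray            # (aG+bA22)^-1 - A22^-1 on the block
    Gb: np.ndarray                    # alpha*G_tuned + beta*A22 (kept for H blocks)
    A22: np.ndarray
    alpha: float
    beta: float

    @property
    def n(self) -> int:
        return self.rel.n

    def matvec(self, v: np.ndarray) -> np.ndarray:
        out = self.rel.A_inverse @ v
        g = self.genotyped_rows
        out[g] += self.correction @ v[g]
        return out

    def diagonal(self) -> np.ndarray:
        d = self.rel.A_inverse.diagonal().copy()
        d[self.genotyped_rows] += np.diag(self.correction)
        return d

    def to_dense(self) -> np.ndarray:
        H = self.rel.A_inverse.toarray()
        g = self.genotyped_rows
        H[np.ix_(g, g)] += self.correction
        return H


def build_H_inverse(rel: PedigreeRelationship, A22: np.ndarray,
                    G_tuned: np.ndarray, alpha: float, beta: float,
                    genotyped_rows: np.ndarray, ridge: float = 0.0) -> HInverse:
    """Assemble H-inverse; ``alpha``/``beta`` blend G with A22.

    Evaluation uses (0.95, 0.05) and GWAS (1, 0), the software defaults
    reproduced here. ``ridge`` is an optional diagonal added to the blend
    for near-singular GWAS-mode systems (logged when non-zero).
    """
    g = np.asarray(genotyped_rows, dtype=np.int64)
    if len(g) != A22.shape[0] or A22.shape != G_tuned.shape:
        raise ValueError("genotyped index map inconsistent with matrix blocks")
    Gb = alpha * G_tuned + beta * A22
    if ridge > 0:
        logger.info("build_H_inverse: adding ridge %.2e to the blended G", ridge)
        Gb = Gb + ridge * np.eye(len(g))
    Gb_inv = _inv_pd(Gb, "alpha*G + beta*A22", suggest_beta=(beta == 0.0))
    A22_inv = _inv_pd(A22, "A22")
    corr = Gb_inv - A22_inv
    corr = 0.5 * (corr + corr.T)
    return HInverse(rel, g, corr, Gb, A22, alpha, beta)


def h_submatrix(hinv: HInverse, rows: np.ndarray) -> np.ndarray:
    """Dense H[rows, rows] from the single-step identity.

    H_SS = A_SS + A_Sg A22^-1 (Gb - A22) A22^-1 A_gS, valid for any
    subset S (including animals in the genotyped block itself).
    """
    S = np.asarray(rows, dtype=np.int64)
    g = hinv.genotyped_rows
    A_Sg = A_block(hinv.rel, S, g)
    A_SS = A_block(hinv.rel, S, S)
    A22_inv = _inv_pd(hinv.A22, "A22")
    B = A_Sg @ A22_inv
    H = A_SS + B @ (hinv.Gb - hinv.A22) @ B.T
    return 0.5 * (H + H.T)
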