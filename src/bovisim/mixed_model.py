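"""Single-trait animal model: y = 1 mu + Z u + e.

``u ~ N(0, K sigma2_u)`` with K the combined relationship H (genomic
evaluation / GWAS) or the pedigree relationship A (conventional EBV);
``e ~ N(0, I sigma2_e)``. The mixed-model equations

    [ 1'1   1'Z              ] [mu]   [1'y]
    [ Z'1   Z'Z + K^-1 lambda] [u ] = [Z'y]

with lambda = sigma2_e / sigma2_u are solved by preconditioned conjugate
gradients (diagonal preconditioner); a dense direct solve is available
for small systems and cross-checks.

Variance components are estimated by exact REML on the phenotyped
block: records marginally follow y = 1 mu + g + e with
var(g) = K_phi sigma2_u, so a single eigendecomposition of K_phi turns
the restricted likelihood into a cheap one-dimensional profile over h2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.sparse.linalg import LinearOperator, cg

from .kinship import HInverse, PedigreeRelationship, A_block, h_submatrix

logger = logging.getLogger(__name__)

__all__ = ["ModelSpec", "Solution", "VarComps", "solve_mme",
           "estimate_varcomps", "predict_ebv", "reml_loglik_direct"]


@dataclass
class ModelSpec:
    y: np.ndarray                    # phenotype records
    record_rows: np.ndarray          # 0-based pedigree row per record
    relationship: HInverse | PedigreeRelationship
    sigma2_u: float
    sigma2_e: float

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64)
        self.record_rows = np.asarray(self.record_rows, dtype=np.int64)
        if len(self.y) != len(self.record_rows):
            raise ValueError("one pedigree member per record required")
        n = self.relationship.n
        if np.any(self.record_rows < 0) or np.any(self.record_rows >= n):
            raise ValueError("record maps outside the pedigree")
        if self.sigma2_u <= 0 or self.sigma2_e <= 0:
            raise ValueError("variance components must be positive")

    @property
    def lam(self) -> float:
        return self.sigma2_e / self.sigma2_u


@dataclass
class Solution:
    mu_hat: float
    u_hat: np.ndarray                # one prediction per pedigree member
    solver: str
    iterations: int
    residual_norm: float
    converged: bool


def _record_counts_and_sums(spec: ModelSpec) -> tuple[np.ndarray, np.ndarray]:
    n = spec.relationship.n
    counts = np.bincount(spec.record_rows, minlength=n).astype(np.float64)
    sums = np.bincount(spec.record_rows, weights=spec.y, minlength=n)
    return counts, sums


def solve_mme(spec: ModelSpec, tol: float = 1e-10, maxiter: int = 20_000,
              method: str = "pcg") -> Solution:
    """Solve the mixed-model equations for (mu, u)."""
    K = spec.relationship
    n = K.n
    lam = spec.lam
    counts, zy = _record_counts_and_sums(spec)
    n_rec = float(len(spec.y))
    rhs = np.r_[spec.y.sum(), zy]

    if method == "direct":
        C = np.zeros((n + 1, n + 1))
        C[0, 0] = n_rec
        C[0, 1:] = counts
        C[1:, 0] = counts
        C[1:, 1:] = np.diag(counts) + lam * K.to_dense()
        sol = np.linalg.solve(C, rhs)
        res = float(np.linalg.norm(C @ sol - rhs) / np.linalg.norm(rhs))
        return Solution(float(sol[0]), sol[1:], "direct", 1, res, True)

    def matvec(x: np.ndarray) -> np.ndarray:
        mu, u = x[0], x[1:]
        top = n_rec * mu + counts @ u
        bottom = counts * mu + counts * u + lam * K.matvec(u)
        return np.r_[top, bottom]

    op = LinearOperator((n + 1, n + 1), matvec=matvec, dtype=np.float64)
    pre = np.r_[n_rec, counts + lam * K.diagonal()]
    pre[pre <= 0] = 1.0
    M = LinearOperator((n + 1, n + 1), matvec=lambda x: x / pre, dtype=np.float64)
    it = 0

    def count_iter(_):
        nonlocal it
        it += 1

    sol, info = cg(op, rhs, rtol=tol, atol=0.0, maxiter=maxiter, M=M,
                   callback=count_iter)
    res = float(np.linalg.norm(matvec(sol) - rhs) / np.linalg.norm(rhs))
    if info != 0:
        logger.warning("solve_mme: PCG stopped at %d iterations, residual %.3e",
                       it, res)
    return Solution(float(sol[0]), sol[1:], "pcg", it, res, info == 0)


def predict_ebv(spec: ModelSpec, **kw) -> Solution:
    """Pedigree-only BLUP: the relationship must be a PedigreeRelationship."""
    if not isinstance(spec.relationship, PedigreeRelationship):
        raise TypeError("predict_ebv requires the pedigree relationship (A-inverse)")
    return solve_mme(spec, **kw)


# --------------------------------------------------------------------------
# REML
# --------------------------------------------------------------------------

@dataclass
class VarComps:
    sigma2_u: float
    sigma2_e: float
    h2: float
    loglik: float
    converged: bool


def _phenotyped_K(relationship, record_rows: np.ndarray) -> np.ndarray:
    if isinstance(relationship, HInverse):
        return h_submatrix(relationship, record_rows)
    if isinstance(relationship, PedigreeRelationship):
        K = A_block(relationship, record_rows, record_rows)
        return 0.5 * (K + K.T)
    return np.asarray(relationship)  # an explicit dense K_phi


def _reml_m2ll_profiled(h2: float, s: np.ndarray, yt: np.ndarray,
                        xt: np.ndarray) -> tuple[float, float]:
    """-2 REML log-likelihood (up to constant) and the profiled sigma2_u."""
    delta = (1.0 - h2) / h2
    w = s + delta
    xwx = np.sum(xt * xt / w)
    beta = np.sum(xt * yt / w) / xwx
    r = yt - xt * beta
    q = float(np.sum(r * r / w))
    npar = len(yt) - 1
    sigma2_u = q / npar
    m2ll = npar * np.log(sigma2_u) + float(np.sum(np.log(w))) + np.log(xwx)
    return m2ll, sigma2_u


def estimate_varcomps(y: np.ndarray, record_rows: np.ndarray,
                      relationship, h2_bounds: tuple = (1e-6, 1.0 - 1e-6),
                      xtol: float = 1e-8,
                      eig: tuple[np.ndarray, np.ndarray] | None = None) -> VarComps:
    """Exact single-component REML on the phenotyped block.

    ``relationship`` is an :class:`HInverse`, a
    :class:`PedigreeRelationship`, or an explicit dense relationship over
    the records. Total variance is not constrained; the estimates
    partition var(y) into additive and residual parts. ``eig`` may carry
    a precomputed ``(eigenvalues, eigenvectors)`` of the record-block
    relationship to amortise the factorisation over repeated calls.
    """
    y = np.asarray(y, dtype=np.float64)
    if len(y) < 2:
        raise ValueError("need at least two records")
    if eig is None:
        K = _phenotyped_K(relationship, np.asarray(record_rows, dtype=np.int64))
        s, U = np.linalg.eigh(K)
    else:
        s, U = eig
    s = np.clip(s, 0.0, None)
    yt = U.T @ y
    xt = U.T @ np.ones_like(y)

    res = minimize_scalar(lambda h: _reml_m2ll_profiled(h, s, yt, xt)[0],
                          bounds=h2_bounds, method="bounded",
                          options={"xatol": xtol})
    h2 = float(res.x)
    m2ll, sigma2_u = _reml_m2ll_profiled(h2, s, yt, xt)
    sigma2_e = sigma2_u * (1.0 - h2) / h2
    return VarComps(float(sigma2_u), float(sigma2_e), h2, -0.5 * m2ll,
                    bool(res.success))


def reml_loglik_direct(y: np.ndarray, K: np.ndarray, sigma2_u: float,
                       sigma2_e: float) -> float:
    """Direct REML log-likelihood (slogdet form), for cross-checks.

    -2 l = log|V| + log|X'V^-1 X| + y'Py with V = K s2u + I s2e and
    X = 1. Constant terms are dropped, matching the profiled form used
    by :func:`estimate_varcomps` up to the same constant.
    """
    n = len(y)
    V = sigma2_u * np.asarray(K) + sigma2_e * np.eye(n)
    sign, logdetV = np.linalg.slogdet(V)
    Vi = np.linalg.inv(V)
    X = np.ones((n, 1))
    XVX = X.T @ Vi @ X
    beta = np.linalg.solve(XVX, X.T @ Vi @ y)
    r = y - (X @ beta).ravel()
    quad = float(r @ Vi @ r)
    return -0.5 * (logdetV + float(np.linalg.slogdet(XVX)[1]) + quad)
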