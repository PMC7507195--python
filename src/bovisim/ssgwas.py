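"""Weighted single-step GWAS: SNP back-solution, weight refinement,
window variance scans, and QTL detection power.

SNP effects are back-solved from the GEBVs of genotyped animals as

    beta_hat = D W' (W D W')^-1 u_g

(Wang et al. 2012), where W holds genotypes centred by twice the allele
frequency and D is the diagonal of per-SNP variance weights (initially
I). Weights are refined as d_i = beta_i^2 * 2 p_i (1 - p_i), rescaled
so trace(D) stays equal to the SNP count, and the GEBV/back-solve cycle
is run for exactly two iterations. The fraction of genetic variance per
region is the variance of the window genetic score (20 adjacent SNPs,
non-overlapping) across genotyped animals relative to the variance of
the total score W beta_hat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

logger = logging.getLogger(__name__)

__all__ = ["SnpEffectSet", "WindowScan", "QtlCallSet",
           "backsolve_snp_effects", "refine_weights",
           "window_variance_scan", "define_true_qtl", "compute_power"]

DEFAULT_WINDOW_SIZE = 20
DEFAULT_THRESHOLD = 1.0     # percent of genetic variance


@dataclass
class SnpEffectSet:
    beta_hat: np.ndarray
    weights: np.ndarray              # diagonal of D, trace = n_snps
    allele_freqs: np.ndarray
    iteration: int

    def __post_init__(self) -> None:
        if np.any(self.weights <= 0):
            raise ValueError("weights must be positive")
        if self.iteration not in (1, 2):
            raise ValueError("the procedure runs exactly two iterations")


@dataclass
class WindowScan:
    """Non-overlapping windows tiling each chromosome's loci in map order.

    ``lo_cM``/``hi_cM`` are detection boundaries: midpoints between the
    flanking loci of adjacent windows, extended to the chromosome ends,
    so that every map position belongs to exactly one window.
    """

    chrom: np.ndarray
    first_locus: np.ndarray          # column index into the scanned matrix
    last_locus: np.ndarray           # inclusive
    lo_cM: np.ndarray
    hi_cM: np.ndarray
    pct_variance: np.ndarray
    total_score_variance: float
    window_size: int = DEFAULT_WINDOW_SIZE

    def __post_init__(self) -> None:
        if np.any(self.pct_variance < 0):
            raise ValueError("variance percentages must be non-negative")

    @property
    def n_windows(self) -> int:
        return len(self.chrom)

    def window_of(self, chrom: int, pos_cM: float) -> int:
        """Index of the window containing a map position (-1 if none)."""
        hit = np.flatnonzero((self.chrom == chrom) &
                             (self.lo_cM <= pos_cM) & (pos_cM < self.hi_cM))
        return int(hit[0]) if len(hit) else -1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": self.chrom + 1,
            "first_locus": self.first_locus,
            "last_locus": self.last_locus,
            "lo_cM": self.lo_cM,
            "hi_cM": self.hi_cM,
            "pct_variance": self.pct_variance,
        })


@dataclass
class QtlCallSet:
    true_qtl_windows: np.ndarray     # window index per trueQTL
    detected: np.ndarray             # bool per trueQTL
    power: float                     # NaN when trueQTL is empty

    @property
    def n_det(self) -> int:
        return int(self.detected.sum())


def backsolve_snp_effects(u_g: np.ndarray, W: np.ndarray,
                          weights: np.ndarray | None = None,
                          allele_freqs: np.ndarray | None = None,
                          iteration: int = 1,
                          ridge: float = 1e-8,
                          gram: np.ndarray | None = None) -> SnpEffectSet:
    """beta_hat = D W' (W D W')^-1 u_g; D = I recovers the GBLUP back-solution.

    ``gram`` optionally replaces the raw W D W' with an equivalent
    invertible matrix. When W is centred with frequencies computed from
    the same genotypes, W D W' is exactly singular (its columns sum to
    zero, so the all-ones vector is a null vector); the single-step GWAS
    pipeline then passes ``2 sum p(1-p)`` times the tuned/blended G used
    in H, which is the same matrix up to the tuning adjustment and is
    positive definite — the convention of the postGS-style back-solvers.
    """
    u_g = np.asarray(u_g, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    if W.shape[0] != len(u_g):
        raise ValueError("rows of W must match the genotyped GEBV vector")
    m = W.shape[1]
    d = np.ones(m) if weights is None else np.asarray(weights, dtype=np.float64)
    if len(d) != m:
        raise ValueError("one weight per SNP required")
    S = (W * d) @ W.T if gram is None else np.asarray(gram, dtype=np.float64).copy()
    try:
        c = cho_factor(S, lower=True)
    except np.linalg.LinAlgError:
        logger.info("backsolve: WDW' singular, adding ridge %.1e", ridge)
        S[np.diag_indices_from(S)] += ridge
        c = cho_factor(S, lower=True)
    t = cho_solve(c, u_g)
    beta = d * (W.T @ t)
    if allele_freqs is None:
        allele_freqs = np.full(m, np.nan)
    return SnpEffectSet(beta, d, np.asarray(allele_freqs, float), iteration)


def refine_weights(snp_effects: SnpEffectSet) -> np.ndarray:
    """Next-iteration D: d_i = beta_i^2 * 2 p_i (1-p_i), trace-normalised."""
    p = snp_effects.allele_freqs
    if np.any(np.isnan(p)):
        raise ValueError("allele frequencies required for weight refinement")
    d = snp_effects.beta_hat ** 2 * 2.0 * p * (1.0 - p)
    total = d.sum()
    if total <= 0:
        raise ValueError("degenerate refinement: all SNP weights are zero")
    return d * (len(d) / total)


def window_variance_scan(snp_effects: SnpEffectSet, W: np.ndarray,
                         chrom: np.ndarray, pos_cM: np.ndarray,
                         chrom_length: float,
                         window_size: int = DEFAULT_WINDOW_SIZE) -> WindowScan:
    """Percent of genetic variance per window of adjacent loci.

    Loci must be ordered by (chromosome, position); windows never span
    chromosomes, and a trailing window shorter than ``window_size`` is
    kept as its own window (logged).
    """
    beta = snp_effects.beta_hat
    W = np.asarray(W, dtype=np.float64)
    chrom = np.asarray(chrom)
    pos_cM = np.asarray(pos_cM, dtype=float)
    if not (W.shape[1] == len(beta) == len(chrom) == len(pos_cM)):
        raise ValueError("W columns, effects and map arrays must align")
    order = np.lexsort((pos_cM, chrom))
    if not np.array_equal(order, np.arange(len(order))):
        raise ValueError("loci must be sorted by chromosome then position")
    total_score = W @ beta
    total_var = float(total_score.var())
    rows = {"chrom": [], "first": [], "last": [], "lo": [], "hi": [], "var": []}
    n_short = 0
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        starts = np.arange(0, len(idx), window_size)
        bounds = []
        for s in starts:
            members = idx[s:s + window_size]
            if len(members) < window_size:
                n_short += 1
            score = W[:, members] @ beta[members]
            rows["chrom"].append(int(c))
            rows["first"].append(int(members[0]))
            rows["last"].append(int(members[-1]))
            rows["var"].append(float(score.var()))
            bounds.append((pos_cM[members[0]], pos_cM[members[-1]]))
        # detection boundaries: midpoints between adjacent windows
        for k, (first_p, last_p) in enumerate(bounds):
            lo = 0.0 if k == 0 else 0.5 * (bounds[k - 1][1] + first_p)
            hi = chrom_length if k == len(bounds) - 1 else 0.5 * (last_p + bounds[k + 1][0])
            rows["lo"].append(lo)
            rows["hi"].append(hi)
    if n_short:
        logger.info("window_variance_scan: %d trailing windows shorter than %d",
                    n_short, window_size)
    var = np.array(rows["var"])
    pct = 100.0 * var / total_var if total_var > 0 else np.zeros_like(var)
    return WindowScan(np.array(rows["chrom"]), np.array(rows["first"]),
                      np.array(rows["last"]), np.array(rows["lo"]),
                      np.array(rows["hi"]), pct, total_var, window_size)


def define_true_qtl(scen0_scan: WindowScan, qtl_chrom: np.ndarray,
                    qtl_pos_cM: np.ndarray,
                    threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Indices of simulated QTL detectable in the idealised scan.

    A QTL is a trueQTL when the window containing its map position in
    the SCEN0 scan (QTL genotyped) explains more than ``threshold``
    percent of the genetic variance. An empty result is reported (the
    caller records power as missing for that replicate).
    """
    qtl_chrom = np.asarray(qtl_chrom)
    qtl_pos_cM = np.asarray(qtl_pos_cM, dtype=float)
    out = []
    for k, (c, p) in enumerate(zip(qtl_chrom, qtl_pos_cM)):
        w = scen0_scan.window_of(int(c), float(p))
        if w >= 0 and scen0_scan.pct_variance[w] > threshold:
            out.append(k)
    if not out:
        logger.warning("define_true_qtl: no QTL passes the %.2f%% threshold",
                       threshold)
    return np.array(out, dtype=int)


def compute_power(scan: WindowScan, qtl_chrom: np.ndarray,
                  qtl_pos_cM: np.ndarray, true_qtl: np.ndarray,
                  threshold: float = DEFAULT_THRESHOLD) -> QtlCallSet:
    """Fraction of trueQTL whose containing window exceeds the threshold."""
    true_qtl = np.asarray(true_qtl, dtype=int)
    if len(true_qtl) == 0:
        return QtlCallSet(np.array([], int), np.array([], bool), float("nan"))
    wins = np.array([scan.window_of(int(qtl_chrom[k]), float(qtl_pos_cM[k]))
                     for k in true_qtl])
    det = np.array([w >= 0 and scan.pct_variance[w] > threshold for w in wins])
    return QtlCallSet(wins, det, float(det.mean()))
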