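"""Genome layout: chromosomes, genetic positions, and locus roles.

Loci live on a linear genetic map (cM). Before panel selection a locus is
a *candidate* SNP or QTL; after selection against the minor-allele-
frequency filter the map holds only the selected panels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GenomeMap", "ROLE_SNP", "ROLE_QTL", "make_candidate_map"]

ROLE_SNP = 0
ROLE_QTL = 1


@dataclass
class GenomeMap:
    """Per-locus records sorted by (chromosome, position).

    Attributes
    ----------
    chrom : int array, 0-based chromosome index per locus
    pos_cM : float array, genetic position within chromosome in centimorgans
    role : int array, ``ROLE_SNP`` or ``ROLE_QTL``
    chrom_length : map length of every chromosome in cM
    n_chromosomes : number of chromosomes
    """

    chrom: np.ndarray
    pos_cM: np.ndarray
    role: np.ndarray
    chrom_length: float
    n_chromosomes: int

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=np.int32)
        self.pos_cM = np.asarray(self.pos_cM, dtype=np.float64)
        self.role = np.asarray(self.role, dtype=np.int8)
        if not (len(self.chrom) == len(self.pos_cM) == len(self.role)):
            raise ValueError("chrom/pos/role length mismatch")
        if np.any(self.pos_cM < 0) or np.any(self.pos_cM > self.chrom_length):
            raise ValueError("positions must lie within [0, chrom_length]")
        order = np.lexsort((self.pos_cM, self.chrom))
        if not np.array_equal(order, np.arange(len(order))):
            raise ValueError("loci must be sorted by chromosome then position")

    # ---------------------------------------------------------------- views
    @property
    def n_loci(self) -> int:
        return len(self.chrom)

    @property
    def snp_mask(self) -> np.ndarray:
        return self.role == ROLE_SNP

    @property
    def qtl_mask(self) -> np.ndarray:
        return self.role == ROLE_QTL

    @property
    def snp_indices(self) -> np.ndarray:
        return np.flatnonzero(self.snp_mask)

    @property
    def qtl_indices(self) -> np.ndarray:
        return np.flatnonzero(self.qtl_mask)

    def chrom_slices(self) -> list[slice]:
        """Contiguous locus slice per chromosome (loci are sorted)."""
        out = []
        for c in range(self.n_chromosomes):
            idx = np.flatnonzero(self.chrom == c)
            out.append(slice(int(idx[0]), int(idx[-1]) + 1) if len(idx) else slice(0, 0))
        return out

    def subset(self, indices: np.ndarray) -> "GenomeMap":
        indices = np.sort(np.asarray(indices))
        return GenomeMap(self.chrom[indices], self.pos_cM[indices],
                         self.role[indices], self.chrom_length, self.n_chromosomes)

    # ------------------------------------------------------------ serialization
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": self.chrom + 1,       # 1-based on disk
            "pos_cM": self.pos_cM,
            "role": np.where(self.role == ROLE_QTL, "QTL", "SNP"),
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame, chrom_length: float,
                   n_chromosomes: int) -> "GenomeMap":
        role = np.where(df["role"].to_numpy() == "QTL", ROLE_QTL, ROLE_SNP)
        return cls(df["chrom"].to_numpy() - 1, df["pos_cM"].to_numpy(),
                   role, chrom_length, n_chromosomes)


def make_candidate_map(config, rng: np.random.Generator) -> GenomeMap:
    """Scatter candidate SNP and QTL loci uniformly over every chromosome."""
    chroms, poss, roles = [], [], []
    for c in range(config.n_chromosomes):
        n_s = config.snps_per_chrom_candidate
        n_q = config.qtl_per_chrom_candidate
        pos = rng.uniform(0.0, config.chrom_length, n_s + n_q)
        role = np.r_[np.full(n_s, ROLE_SNP, dtype=np.int8),
                     np.full(n_q, ROLE_QTL, dtype=np.int8)]
        order = np.argsort(pos, kind="stable")
        chroms.append(np.full(n_s + n_q, c, dtype=np.int32))
        poss.append(pos[order])
        roles.append(role[order])
    return GenomeMap(np.concatenate(chroms), np.concatenate(poss),
                     np.concatenate(roles), config.chrom_length,
                     config.n_chromosomes)
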