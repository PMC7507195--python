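"""Population container: pedigree, haplotypes, breeding values, phenotypes.

The pedigree is a pandas DataFrame with one row per retained animal, in
birth order (parents always precede offspring). Ids are positive
integers assigned in row order, so ``row = id - 1``. Unknown parents are
coded 0. Haplotypes are a ``uint8`` array of shape ``(n, 2, n_loci)``
aligned with the pedigree rows over the loci of the attached
:class:`~bovisim.genome.GenomeMap`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeMap

__all__ = ["Population", "HistoricalPopulation", "PEDIGREE_COLUMNS"]

PEDIGREE_COLUMNS = [
    "id", "sire", "dam", "sex", "gen",
    "is_breeding", "is_bull", "is_test", "is_progeny",
    "progeny_rank", "tbv", "phenotype",
]


@dataclass
class HistoricalPopulation:
    """Final generation of the historical phase (no pedigree recorded)."""

    haplotypes: np.ndarray      # (n, 2, n_loci) uint8
    sex: np.ndarray             # 'M'/'F' per individual
    genome: GenomeMap

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0]

    def allele_frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=(0, 1))


@dataclass
class Population:
    pedigree: pd.DataFrame
    haplotypes: np.ndarray
    genome: GenomeMap
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ped = self.pedigree
        if list(ped["id"]) != list(range(1, len(ped) + 1)):
            raise ValueError("ids must be 1..n in pedigree row order")
        ids = ped["id"].to_numpy()
        for col in ("sire", "dam"):
            par = ped[col].to_numpy()
            known = par > 0
            if np.any(par[known] >= ids[known]):
                raise ValueError("parents must precede offspring in the pedigree")
        if self.haplotypes.shape[0] != len(ped):
            raise ValueError("haplotype rows must match pedigree rows")
        if self.haplotypes.shape[2] != self.genome.n_loci:
            raise ValueError("haplotype loci must match the genome map")

    # ---------------------------------------------------------------- access
    @property
    def n_individuals(self) -> int:
        return len(self.pedigree)

    def rows_of(self, ids: np.ndarray) -> np.ndarray:
        return np.asarray(ids, dtype=np.int64) - 1

    def ids_where(self, mask: pd.Series | np.ndarray) -> np.ndarray:
        return self.pedigree.loc[np.asarray(mask), "id"].to_numpy()

    @property
    def bull_ids(self) -> np.ndarray:
        return self.ids_where(self.pedigree["is_bull"].to_numpy())

    @property
    def test_ids(self) -> np.ndarray:
        return self.ids_where(self.pedigree["is_test"].to_numpy())

    def progeny_ids(self, per_bull: int | None = None) -> np.ndarray:
        """Phenotyped progenies; optionally the nested first-k-per-bull subset."""
        ped = self.pedigree
        mask = ped["is_progeny"].to_numpy()
        if per_bull is not None:
            mask = mask & (ped["progeny_rank"].to_numpy() < per_bull)
        return self.ids_where(mask)

    def genotypes(self, ids: np.ndarray, loci: np.ndarray | None = None) -> np.ndarray:
        """Allele-count matrix (len(ids), n_loci_selected) as float64."""
        rows = self.rows_of(ids)
        hap = self.haplotypes[rows]
        if loci is not None:
            hap = hap[:, :, loci]
        return hap.sum(axis=1, dtype=np.int64).astype(np.float64)

    def allele_frequencies(self, ids: np.ndarray | None = None,
                           loci: np.ndarray | None = None) -> np.ndarray:
        if ids is None:
            hap = self.haplotypes
        else:
            hap = self.haplotypes[self.rows_of(ids)]
        if loci is not None:
            hap = hap[:, :, loci]
        return hap.mean(axis=(0, 1))
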