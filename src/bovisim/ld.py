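"""Linkage-disequilibrium decay summaries (r-squared vs genetic distance)."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genome import GenomeMap

logger = logging.getLogger(__name__)

__all__ = ["LdDecaySummary", "compute_ld_decay"]


@dataclass
class LdDecaySummary:
    bin_edges: np.ndarray          # cM, len nbins+1, increasing
    mean_r2: np.ndarray            # per bin; NaN where no pairs fell
    n_pairs: np.ndarray            # pairs per bin
    n_skipped_monomorphic: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bins must be ordered and non-overlapping")
        r = self.mean_r2[~np.isnan(self.mean_r2)]
        if np.any((r < -1e-12) | (r > 1 + 1e-12)):
            raise ValueError("r2 must lie in [0, 1]")


def compute_ld_decay(genotypes: np.ndarray, genome_map: GenomeMap,
                     bins: np.ndarray | None = None,
                     max_pairs: int = 50_000,
                     rng: np.random.Generator | None = None) -> LdDecaySummary:
    """Mean r^2 of sampled within-chromosome locus pairs, binned by distance.

    Parameters
    ----------
    genotypes : (n_individuals, n_loci) allele-count matrix over the map's loci.
    bins : distance bin edges in cM (default 0..10 in 1-cM steps).
    max_pairs : pairs sampled uniformly among within-chromosome pairs whose
        distance falls inside the bin range (pair sampling, not exhaustive).
    """
    if bins is None:
        bins = np.arange(0.0, 11.0, 1.0)
    bins = np.asarray(bins, dtype=float)
    rng = rng or np.random.default_rng()
    X = np.asarray(genotypes, dtype=np.float64)
    if X.shape[1] != genome_map.n_loci:
        raise ValueError("genotype columns must match the genome map")
    sd = X.std(axis=0)
    sums = np.zeros(len(bins) - 1)
    counts = np.zeros(len(bins) - 1, dtype=np.int64)
    skipped = 0
    max_dist = bins[-1]
    chrom = genome_map.chrom
    pos = genome_map.pos_cM
    n_loci = genome_map.n_loci
    drawn = 0
    attempts = 0
    Xc = X - X.mean(axis=0)
    while drawn < max_pairs and attempts < 50 * max_pairs:
        take = min(4 * (max_pairs - drawn), 200_000)
        attempts += take
        i = rng.integers(0, n_loci, take)
        j = rng.integers(0, n_loci, take)
        ok = (chrom[i] == chrom[j]) & (i != j)
        d = np.abs(pos[i] - pos[j])
        ok &= (d >= bins[0]) & (d <= max_dist)
        i, j, d = i[ok], j[ok], d[ok]
        poly = (sd[i] > 0) & (sd[j] > 0)
        skipped += int((~poly).sum())
        i, j, d = i[poly], j[poly], d[poly]
        if len(i) == 0:
            continue
        if drawn + len(i) > max_pairs:
            cut = max_pairs - drawn
            i, j, d = i[:cut], j[:cut], d[:cut]
        r = (Xc[:, i] * Xc[:, j]).sum(axis=0) / (len(X) * sd[i] * sd[j])
        r2 = r ** 2
        which = np.clip(np.digitize(d, bins) - 1, 0, len(bins) - 2)
        np.add.at(sums, which, r2)
        np.add.at(counts, which, 1)
        drawn += len(i)
    if skipped:
        logger.info("compute_ld_decay: skipped %d monomorphic pairs", skipped)
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return LdDecaySummary(bins, mean_r2, counts, skipped)
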