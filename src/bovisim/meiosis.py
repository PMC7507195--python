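"""Meiosis: gamete formation with Haldane recombination and mutation.

Crossover counts per chromosome are Poisson with mean equal to the map
length in Morgans (no interference); crossover positions are uniform on
the chromosome; the starting parental strand is a fair coin per
chromosome. After recombination each locus mutates (allele flip) with the
per-locus per-meiosis mutation rate.
"""

from __future__ import annotations

import numpy as np

from .genome import GenomeMap

__all__ = ["drop_gametes", "drop_gamete"]


def _recombine_batch(h0: np.ndarray, h1: np.ndarray, genome: GenomeMap,
                     rng: np.random.Generator) -> np.ndarray:
    """Recombine B parental haplotype pairs into B gametes (no mutation).

    h0, h1 : uint8 arrays (B, n_loci) — the two strands of each parent.
    """
    B, m = h0.shape
    gam = np.empty((B, m), dtype=np.uint8)
    for sl in genome.chrom_slices():
        if sl.stop == sl.start:
            continue
        pos_m = genome.pos_cM[sl] / 100.0          # Morgans
        length = genome.chrom_length / 100.0
        k = rng.poisson(length, B)
        start = rng.integers(0, 2, B)
        kmax = int(k.max()) if B else 0
        if kmax > 0:
            x = rng.random((B, kmax)) * length
            x[np.arange(kmax)[None, :] >= k[:, None]] = np.inf
            # number of crossovers at or before each locus position
            counts = (x[:, :, None] <= pos_m[None, None, :]).sum(axis=1)
            strand = (start[:, None] + counts) & 1
        else:
            strand = np.broadcast_to((start & 1)[:, None], (B, sl.stop - sl.start))
        gam[:, sl] = np.where(strand == 0, h0[:, sl], h1[:, sl])
    return gam


def _mutate_batch(gam: np.ndarray, mutation_rate: float,
                  rng: np.random.Generator) -> None:
    """Flip alleles in place at the per-locus mutation rate."""
    if mutation_rate <= 0:
        return
    n_mut = rng.binomial(gam.size, mutation_rate)
    if n_mut == 0:
        return
    flat = rng.integers(0, gam.size, n_mut)
    gam.reshape(-1)[flat] ^= 1


def drop_gametes(parent_haps: np.ndarray, genome: GenomeMap,
                 rng: np.random.Generator, mutation_rate: float = 0.0) -> np.ndarray:
    """Produce one gamete from each of B parents.

    Parameters
    ----------
    parent_haps : uint8 array (B, 2, n_loci)
        Both strands of each contributing parent (already gathered; a
        parent may appear multiple times to yield several gametes).
    """
    gam = _recombine_batch(parent_haps[:, 0, :], parent_haps[:, 1, :], genome, rng)
    _mutate_batch(gam, mutation_rate, rng)
    return gam


def drop_gamete(parent_haplotypes: np.ndarray, genome_map: GenomeMap,
                rng: np.random.Generator, mutation_rate: float = 0.0) -> np.ndarray:
    """Single-parent convenience wrapper around :func:`drop_gametes`."""
    ph = np.asarray(parent_haplotypes, dtype=np.uint8)
    if ph.ndim != 2 or ph.shape[0] != 2 or ph.shape[1] != genome_map.n_loci:
        raise ValueError("parent_haplotypes must have shape (2, n_loci)")
    return drop_gametes(ph[None, :, :], genome_map, rng, mutation_rate)[0]
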