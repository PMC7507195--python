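"""Trait architecture: gamma-distributed QTL effects, TBVs and phenotypes.

Allele-substitution effect magnitudes are drawn from a gamma
distribution (shape 0.4 by default) with random sign, then rescaled by a
single common factor so that the realized additive variance of the QTL
score among the G0 founders equals ``sigma2_u = h2 * Vp`` (under
linkage equilibrium and Hardy-Weinberg proportions this reduces to the
familiar ``sum_k 2 p_k (1 - p_k) a_k^2`` scaling). True
breeding values are sums of frequency-centred allele counts times
effects; phenotypes add independent Gaussian noise with variance
``sigma2_e`` and are assigned only to the designated phenotyped
progenies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SimulationConfig
from .population import Population

__all__ = ["TraitArchitecture", "draw_qtl_effects", "compute_tbv_and_phenotypes"]


@dataclass
class TraitArchitecture:
    qtl_locus_indices: np.ndarray     # indices into the population genome map
    qtl_effects: np.ndarray           # signed allele-substitution effects
    qtl_ref_freq: np.ndarray          # G0 allele-1 frequencies (centering reference)
    sigma2_u: float
    sigma2_e: float
    h2: float

    def __post_init__(self) -> None:
        if abs(self.sigma2_u / (self.sigma2_u + self.sigma2_e) - self.h2) > 1e-8:
            raise ValueError("h2 must equal sigma2_u / (sigma2_u + sigma2_e)")


def draw_qtl_effects(g0: Population, config: SimulationConfig,
                     rng: np.random.Generator) -> TraitArchitecture:
    """Sample and scale QTL effects against the G0 allele frequencies."""
    qtl = g0.genome.qtl_indices
    if len(qtl) == 0:
        raise ValueError("QTL panel is empty")
    p = g0.allele_frequencies(loci=qtl)
    raw = rng.gamma(config.gamma_shape, 1.0, len(qtl))
    sign = np.where(rng.random(len(qtl)) < 0.5, 1.0, -1.0)
    a = raw * sign
    # scale to the *simulated* genetic variance: the empirical variance of
    # the QTL score among the G0 founders (captures drift-induced LD and
    # non-equilibrium genotype proportions, unlike sum 2p(1-p)a^2)
    X = g0.genotypes(g0.pedigree["id"].to_numpy(), loci=qtl)
    base_var = float(((X - 2.0 * p) @ a).var())
    if base_var <= 0:
        raise ValueError("zero total QTL variance before scaling")
    sigma2_u = config.h2 * config.phenotypic_variance
    sigma2_e = config.phenotypic_variance - sigma2_u
    a *= np.sqrt(sigma2_u / base_var)
    return TraitArchitecture(qtl, a, p, sigma2_u, sigma2_e, config.h2)


def compute_tbv_and_phenotypes(population: Population, trait: TraitArchitecture,
                               rng: np.random.Generator) -> Population:
    """Fill the tbv column for all animals and phenotypes for progenies.

    TBVs are centred with the G0 reference allele frequencies so that
    E[TBV] is approximately zero in the base generation.
    """
    qtl = trait.qtl_locus_indices
    if qtl.max(initial=-1) >= population.genome.n_loci:
        raise ValueError("QTL genotypes missing from the population genome")
    X = population.genotypes(population.pedigree["id"].to_numpy(), loci=qtl)
    tbv = (X - 2.0 * trait.qtl_ref_freq) @ trait.qtl_effects
    ped = population.pedigree
    ped["tbv"] = tbv
    prog = ped["is_progeny"].to_numpy()
    noise = rng.normal(0.0, np.sqrt(trait.sigma2_e), int(prog.sum()))
    phen = np.full(len(ped), np.nan)
    phen[prog] = tbv[prog] + noise
    ped["phenotype"] = phen
    population.meta["sigma2_u"] = trait.sigma2_u
    population.meta["sigma2_e"] = trait.sigma2_e
    population.meta["h2"] = trait.h2
    return population
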