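"""Shared test utilities: tiny pedigrees, tabular-method oracle, mini config."""

from __future__ import annotations

import numpy as np
import pandas as pd

from bovisim.config import SimulationConfig
from bovisim.population import PEDIGREE_COLUMNS


def ped_frame(sire, dam, **overrides) -> pd.DataFrame:
    """Minimal valid pedigree frame (ids 1..n, defaults everywhere else)."""
    n = len(sire)
    base = {
        "id": np.arange(1, n + 1, dtype=np.int64),
        "sire": np.asarray(sire, dtype=np.int64),
        "dam": np.asarray(dam, dtype=np.int64),
        "sex": np.full(n, "M"), "gen": np.zeros(n, dtype=int),
        "is_breeding": np.full(n, True), "is_bull": np.full(n, False),
        "is_test": np.full(n, False), "is_progeny": np.full(n, False),
        "progeny_rank": np.full(n, -1), "tbv": np.full(n, np.nan),
        "phenotype": np.full(n, np.nan),
    }
    base.update(overrides)
    return pd.DataFrame(base, columns=PEDIGREE_COLUMNS)


def tabular_A(sire, dam) -> np.ndarray:
    """Tabular-method numerator relationship matrix (independent oracle)."""
    sire = np.asarray(sire, dtype=int)
    dam = np.asarray(dam, dtype=int)
    n = len(sire)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i] - 1, dam[i] - 1
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
        for j in range(i):
            v = 0.0
            if s >= 0:
                v += 0.5 * A[j, s]
            if d >= 0:
                v += 0.5 * A[j, d]
            A[i, j] = A[j, i] = v
    return A


def random_pedigree(rng: np.random.Generator, n: int = 12, n_founders: int = 4):
    """Random valid pedigree (parents precede offspring, possibly unknown)."""
    sire = [0] * n
    dam = [0] * n
    for i in range(n_founders, n):
        if rng.random() < 0.85:
            sire[i] = int(rng.integers(1, i + 1))
        if rng.random() < 0.85:
            dam[i] = int(rng.integers(1, i + 1))
    return np.array(sire), np.array(dam)


def mini_config(**overrides) -> SimulationConfig:
    """Tiny full-structure configuration for fast end-to-end tests."""
    base = dict(
        Ne_target=15, nQTL=8, h2=0.5,
        n_chromosomes=2, chrom_length=100.0,
        snps_per_chrom_candidate=260, qtl_per_chrom_candidate=40,
        n_snps_selected=300,
        hist_n0=80, hist_const_gens=40, hist_bottleneck_gens=10,
        hist_expand_gens=3, hist_final_size=240,
        n_sires=5, n_dams=50, n_bulls_per_gen=5, n_test_per_gen=5,
        progeny_per_bull=4, progeny_tiers=(4, 2, 1), n_replicates=2,
    )
    base.update(overrides)
    return SimulationConfig(**base)
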