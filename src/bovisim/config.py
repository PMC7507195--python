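"""Simulation configuration and built-in profiles.

A :class:`SimulationConfig` fully determines one replicate of the study
design: the historical demography that builds linkage disequilibrium, the
genome/marker layout, the trait architecture, and the recent pedigreed
population with its progeny-testing structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

__all__ = ["SimulationConfig", "profile", "PROFILES"]


@dataclass
class SimulationConfig:
    # demographic target
    Ne_target: int = 20
    # trait architecture
    nQTL: int = 50
    h2: float = 0.50
    phenotypic_variance: float = 1.0
    gamma_shape: float = 0.4
    # genome
    n_chromosomes: int = 30
    chrom_length: float = 100.0          # cM
    snps_per_chrom_candidate: int = 3000
    qtl_per_chrom_candidate: int = 50
    n_snps_selected: int = 50_000
    maf_min: float = 0.05
    mutation_rate: float = 2.5e-5        # per locus per meiosis
    # historical population (mutation-drift equilibrium -> bottleneck -> expansion)
    hist_n0: int = 1000
    hist_const_gens: int = 1000
    hist_bottleneck_gens: int = 30
    hist_expand_gens: int = 3
    hist_final_size: int = 10_000
    # recent population
    n_sires: int = 50
    n_dams: int = 3000
    n_generations: int = 12
    bull_gen_first: int = 5
    bull_gen_last: int = 10
    n_bulls_per_gen: int = 50
    n_test_per_gen: int = 50
    progeny_per_bull: int = 30           # max simulated; tiers subset this
    progeny_tiers: tuple = (30, 15, 5)
    # replication
    n_replicates: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.maf_min < 0.5:
            raise ValueError("maf_min must lie in (0, 0.5)")
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("h2 must lie in (0, 1)")
        if self.n_snps_selected > self.n_chromosomes * self.snps_per_chrom_candidate:
            raise ValueError("n_snps_selected exceeds the SNP candidate pool")
        if self.nQTL > self.n_chromosomes * self.qtl_per_chrom_candidate:
            raise ValueError("nQTL exceeds the QTL candidate pool")
        if self.Ne_target > self.hist_n0:
            raise ValueError("Ne_target cannot exceed the historical base size")
        counts = (
            self.Ne_target, self.nQTL, self.n_chromosomes,
            self.snps_per_chrom_candidate, self.qtl_per_chrom_candidate,
            self.n_snps_selected, self.hist_n0, self.hist_const_gens,
            self.hist_bottleneck_gens, self.hist_expand_gens,
            self.hist_final_size, self.n_sires, self.n_dams,
            self.n_generations, self.n_bulls_per_gen, self.n_test_per_gen,
            self.progeny_per_bull, self.n_replicates,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        if self.chrom_length <= 0 or self.phenotypic_variance <= 0:
            raise ValueError("lengths and variances must be positive")
        self.progeny_tiers = tuple(int(t) for t in self.progeny_tiers)
        if max(self.progeny_tiers) > self.progeny_per_bull:
            raise ValueError("progeny tier exceeds progeny_per_bull")
        if self.n_bulls_per_gen > self.n_sires:
            # tagged bulls are drawn from the breeding sires of each generation
            raise ValueError("n_bulls_per_gen cannot exceed n_sires")

    # ------------------------------------------------------------------ io
    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["progeny_tiers"] = list(self.progeny_tiers)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        known = {f for f in cls.__dataclass_fields__}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def replace(self, **kw: Any) -> "SimulationConfig":
        d = self.to_dict()
        d.update(kw)
        return SimulationConfig.from_dict(d)


def _paper_profile(**overrides: Any) -> SimulationConfig:
    return SimulationConfig(**overrides)


def _desk_profile(**overrides: Any) -> SimulationConfig:
    """Scaled-down profile: same structure, desk-scale sizes.

    5 chromosomes x 100 cM, 5,000 SNPs, 10 sires x 200 dams, 60 tagged
    bulls, progeny tiers 10/5/2 (600/300/120 phenotyped progenies),
    20 test bulls, 3 replicates.
    """
    base = dict(
        n_chromosomes=5,
        snps_per_chrom_candidate=1800,
        qtl_per_chrom_candidate=240,
        n_snps_selected=5000,
        hist_n0=200,
        hist_const_gens=200,
        hist_final_size=600,
        n_sires=10,
        n_dams=200,
        n_bulls_per_gen=10,
        n_test_per_gen=10,
        progeny_per_bull=10,
        progeny_tiers=(10, 5, 2),
        n_replicates=3,
    )
    base.update(overrides)
    return SimulationConfig(**base)


PROFILES = {"paper": _paper_profile, "desk": _desk_profile}


def profile(name: str, **overrides: Any) -> SimulationConfig:
    """Return a built-in configuration profile, optionally overridden."""
    try:
        factory = PROFILES[name]
    except KeyError:
        raise ValueError(f"unknown profile {name!r}; choose from {sorted(PROFILES)}")
    return factory(**overrides)
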