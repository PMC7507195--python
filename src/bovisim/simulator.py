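"""Forward-in-time simulation of the historical and recent populations.

The historical phase builds mutation-drift equilibrium and linkage
disequilibrium: a constant-size base population, a gradual (linear)
bottleneck down to the target effective size, and a three-generation
expansion, with random union of gametes and an exactly balanced sex
ratio throughout. The recent phase is a pedigreed cattle population of
12 discrete generations bred from 50 sires x 3,000 dams (scaled profiles
keep the same structure), with progeny-tested bulls in G5-G10, their
phenotyped progenies in G6-G11, and test bulls in G11-G12.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .genome import GenomeMap, make_candidate_map
from .meiosis import drop_gametes
from .population import HistoricalPopulation, Population, PEDIGREE_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "historical_trajectory", "simulate_historical", "found_recent",
    "select_segregating_panels", "simulate_recent", "simulate_replicate",
]


def historical_trajectory(config: SimulationConfig) -> np.ndarray:
    """Population size per historical generation (index 0 = base)."""
    const = np.full(config.hist_const_gens + 1, config.hist_n0)
    decline = np.linspace(config.hist_n0, config.Ne_target,
                          config.hist_bottleneck_gens + 1)[1:]
    expand = np.linspace(config.Ne_target, config.hist_final_size,
                         config.hist_expand_gens + 1)[1:]
    return np.rint(np.r_[const, decline, expand]).astype(int)


def _balanced_sexes(n: int, rng: np.random.Generator) -> np.ndarray:
    """Exactly floor(n/2) males among n individuals, in random order."""
    sex = np.array(["M"] * (n // 2) + ["F"] * (n - n // 2))
    rng.shuffle(sex)
    return sex


def _next_generation(haps: np.ndarray, sex: np.ndarray, n_out: int,
                     genome: GenomeMap, mu: float,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Random union of gametes: one sire and one dam draw per offspring."""
    males = np.flatnonzero(sex == "M")
    females = np.flatnonzero(sex == "F")
    if len(males) == 0 or len(females) == 0:
        raise ValueError("both sexes must be present to breed")
    sires = rng.choice(males, n_out)
    dams = rng.choice(females, n_out)
    gam_s = drop_gametes(haps[sires], genome, rng, mu)
    gam_d = drop_gametes(haps[dams], genome, rng, mu)
    out = np.stack([gam_s, gam_d], axis=1)
    return out, _balanced_sexes(n_out, rng)


def simulate_historical(config: SimulationConfig,
                        rng: np.random.Generator) -> HistoricalPopulation:
    """Run the historical demography and return its final generation.

    Base-generation haplotypes start with allele frequency 0.5 at every
    candidate locus; recurrent mutation (allele flips) maintains
    segregating variation against drift.
    """
    if config.Ne_target > config.hist_n0:
        raise ValueError("Ne_target cannot exceed the historical base size")
    genome = make_candidate_map(config, rng)
    sizes = historical_trajectory(config)
    if np.any(sizes <= 0):
        raise ValueError("non-positive historical population size")
    n0 = sizes[0]
    haps = (rng.random((n0, 2, genome.n_loci)) < 0.5).astype(np.uint8)
    sex = _balanced_sexes(n0, rng)
    for n_next in sizes[1:]:
        haps, sex = _next_generation(haps, sex, int(n_next), genome,
                                     config.mutation_rate, rng)
    return HistoricalPopulation(haps, sex, genome)


def found_recent(historical: HistoricalPopulation, config: SimulationConfig,
                 rng: np.random.Generator) -> Population:
    """Sample the G0 founders (n_sires males, n_dams females) uniformly."""
    males = np.flatnonzero(historical.sex == "M")
    females = np.flatnonzero(historical.sex == "F")
    if len(males) < config.n_sires or len(females) < config.n_dams:
        raise ValueError(
            f"need {config.n_sires} males and {config.n_dams} females; "
            f"historical generation has {len(males)}/{len(females)}")
    pick_m = rng.choice(males, config.n_sires, replace=False)
    pick_f = rng.choice(females, config.n_dams, replace=False)
    rows = np.r_[pick_m, pick_f]
    n = len(rows)
    ped = pd.DataFrame({
        "id": np.arange(1, n + 1, dtype=np.int64),
        "sire": 0, "dam": 0,
        "sex": np.r_[np.full(config.n_sires, "M"), np.full(config.n_dams, "F")],
        "gen": 0,
        "is_breeding": True, "is_bull": False, "is_test": False,
        "is_progeny": False, "progeny_rank": -1,
        "tbv": np.nan, "phenotype": np.nan,
    }, columns=PEDIGREE_COLUMNS)
    return Population(ped, historical.haplotypes[rows].copy(), historical.genome)


def select_segregating_panels(g0: Population, config: SimulationConfig,
                              rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw the SNP and QTL panels among candidates with MAF > maf_min in G0.

    Returns locus indices (into the candidate map) of the SNP panel and
    the QTL panel. Raises if either candidate pool has too few
    segregating loci — panels are never silently shrunk.
    """
    freq = g0.allele_frequencies()
    maf = np.minimum(freq, 1.0 - freq)
    ok = maf > config.maf_min
    genome = g0.genome
    snp_pool = np.flatnonzero(ok & genome.snp_mask)
    qtl_pool = np.flatnonzero(ok & genome.qtl_mask)
    if len(snp_pool) < config.n_snps_selected:
        raise ValueError(
            f"insufficient segregating loci: {len(snp_pool)} SNP candidates "
            f"pass MAF > {config.maf_min}, need {config.n_snps_selected}")
    if len(qtl_pool) < config.nQTL:
        raise ValueError(
            f"insufficient segregating loci: {len(qtl_pool)} QTL candidates "
            f"pass MAF > {config.maf_min}, need {config.nQTL}")
    snp_panel = np.sort(rng.choice(snp_pool, config.n_snps_selected, replace=False))
    qtl_panel = np.sort(rng.choice(qtl_pool, config.nQTL, replace=False))
    return snp_panel, qtl_panel


def restrict_to_panels(g0: Population, snp_panel: np.ndarray,
                       qtl_panel: np.ndarray) -> Population:
    """Drop all non-panel loci; the result's genome holds SNP+QTL roles."""
    keep = np.sort(np.r_[snp_panel, qtl_panel])
    return Population(g0.pedigree.copy(), np.ascontiguousarray(g0.haplotypes[:, :, keep]),
                      g0.genome.subset(keep), dict(g0.meta))


def _allocate_dams(sire_ids: np.ndarray, dam_ids: np.ndarray,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Each sire gets an equal share of the shuffled dams (round-robin tail)."""
    dams = rng.permutation(dam_ids)
    sires = np.resize(np.repeat(sire_ids, len(dams) // len(sire_ids)), len(dams))
    return sires, dams


def simulate_recent(g0: Population, config: SimulationConfig,
                    rng: np.random.Generator) -> Population:
    """Breed 12 discrete generations G1-G12 on top of the G0 founders.

    Each dam is mated once per generation and produces a litter of two;
    replacements (n_sires males, n_dams females) are drawn uniformly from
    the litters with no selection on merit. Progeny-tested bulls are a
    separate uniform draw of males in each of G5-G10 (independent of the
    replacement draw, so they rarely coincide with the breeding sires);
    each tagged bull produces ``progeny_per_bull`` phenotyped progenies
    in the next generation via extra matings to randomly chosen dams of
    its own generation (dam reuse allowed); those progenies never breed.
    Test bulls are untested males sampled the same way in G11-G12.
    """
    if config.n_generations != 12:
        raise ValueError("the breeding design is defined for 12 recent generations")
    genome = g0.genome
    ped_frames = [g0.pedigree]
    hap_blocks = [g0.haplotypes]       # ids are sequential, so id-1 indexes the
    block_offsets = [0]                # concatenation of these blocks
    next_id = g0.n_individuals + 1

    def hap_of(ids: np.ndarray) -> np.ndarray:
        rows = np.asarray(ids, dtype=np.int64) - 1
        block = np.searchsorted(block_offsets, rows, side="right") - 1
        return np.stack([hap_blocks[b][r - block_offsets[b]]
                         for b, r in zip(block, rows)])

    def push(frame: pd.DataFrame, haps: np.ndarray) -> None:
        block_offsets.append(block_offsets[-1] + len(hap_blocks[-1]))
        ped_frames.append(frame)
        hap_blocks.append(haps)

    cur_sires = g0.pedigree.loc[g0.pedigree["sex"] == "M", "id"].to_numpy()
    cur_dams = g0.pedigree.loc[g0.pedigree["sex"] == "F", "id"].to_numpy()
    bulls_of_gen: dict[int, np.ndarray] = {}

    for g in range(1, config.n_generations + 1):
        prev_g = g - 1

        # --- regular litters: each dam once, litter size 2
        mate_sires, mate_dams = _allocate_dams(cur_sires, cur_dams, rng)
        sire_per_child = np.repeat(mate_sires, 2)
        dam_per_child = np.repeat(mate_dams, 2)
        n_children = len(sire_per_child)
        gam_s = drop_gametes(hap_of(sire_per_child), genome, rng, config.mutation_rate)
        gam_d = drop_gametes(hap_of(dam_per_child), genome, rng, config.mutation_rate)
        child_haps = np.stack([gam_s, gam_d], axis=1)
        child_sex = _balanced_sexes(n_children, rng)

        # --- replacement selection (random, no selection on merit)
        males = np.flatnonzero(child_sex == "M")
        females = np.flatnonzero(child_sex == "F")
        if len(males) < config.n_sires or len(females) < config.n_dams:
            raise ValueError("not enough progeny of each sex for replacement")
        sel_m = rng.choice(males, config.n_sires, replace=False)
        sel_f = rng.choice(females, config.n_dams, replace=False)
        keep = set(sel_m.tolist()) | set(sel_f.tolist())

        # --- progeny-tested bulls: a separate random draw of males of this
        # generation (they are genotyping candidates, not the breeding sires,
        # though overlap by chance is allowed)
        bull_rows: set[int] = set()
        if config.bull_gen_first <= g <= config.bull_gen_last:
            pick = rng.choice(males, config.n_bulls_per_gen, replace=False)
            bull_rows = set(pick.tolist())
            keep |= bull_rows

        # --- test bulls: random unphenotyped males of G11/G12
        test_rows: set[int] = set()
        if g in (config.n_generations - 1, config.n_generations):
            pick = rng.choice(males, config.n_test_per_gen, replace=False)
            test_rows = set(pick.tolist())
            keep |= test_rows
        if g == config.n_generations:
            # last generation: only test bulls are retained
            keep = set(test_rows)
            sel_m = np.array([], dtype=int)
            sel_f = np.array([], dtype=int)

        keep_rows = np.array(sorted(keep), dtype=int)
        ids = np.arange(next_id, next_id + len(keep_rows), dtype=np.int64)
        next_id += len(keep_rows)
        sel_set = set(sel_m.tolist()) | set(sel_f.tolist())
        reg_frame = pd.DataFrame({
            "id": ids,
            "sire": sire_per_child[keep_rows],
            "dam": dam_per_child[keep_rows],
            "sex": child_sex[keep_rows],
            "gen": g,
            "is_breeding": [r in sel_set for r in keep_rows],
            "is_bull": [r in bull_rows for r in keep_rows],
            "is_test": [r in test_rows for r in keep_rows],
            "is_progeny": False, "progeny_rank": -1,
            "tbv": np.nan, "phenotype": np.nan,
        }, columns=PEDIGREE_COLUMNS)
        push(reg_frame, child_haps[keep_rows])
        if bull_rows:
            bulls_of_gen[g] = reg_frame.loc[reg_frame["is_bull"], "id"].to_numpy()

        # --- extra matings: phenotyped progenies of the previous generation's bulls
        if prev_g in bulls_of_gen:
            bulls = bulls_of_gen[prev_g]
            n_extra = len(bulls) * config.progeny_per_bull
            ex_sires = np.repeat(bulls, config.progeny_per_bull)
            ex_dams = rng.choice(cur_dams, n_extra, replace=True)
            gam_s = drop_gametes(hap_of(ex_sires), genome, rng, config.mutation_rate)
            gam_d = drop_gametes(hap_of(ex_dams), genome, rng, config.mutation_rate)
            ex_haps = np.stack([gam_s, gam_d], axis=1)
            ex_sex = np.where(rng.random(n_extra) < 0.5, "M", "F")
            ex_ids = np.arange(next_id, next_id + n_extra, dtype=np.int64)
            next_id += n_extra
            ex_frame = pd.DataFrame({
                "id": ex_ids,
                "sire": ex_sires, "dam": ex_dams, "sex": ex_sex, "gen": g,
                "is_breeding": False, "is_bull": False, "is_test": False,
                "is_progeny": True,
                "progeny_rank": np.tile(np.arange(config.progeny_per_bull), len(bulls)),
                "tbv": np.nan, "phenotype": np.nan,
            }, columns=PEDIGREE_COLUMNS)
            push(ex_frame, ex_haps)

        # --- roll the breeding set forward
        if g < config.n_generations:
            br = reg_frame[reg_frame["is_breeding"]]
            cur_sires = br.loc[br["sex"] == "M", "id"].to_numpy()
            cur_dams = br.loc[br["sex"] == "F", "id"].to_numpy()

    pedigree = pd.concat(ped_frames, ignore_index=True)
    haplotypes = np.concatenate(hap_blocks, axis=0)
    pop = Population(pedigree, haplotypes, genome, dict(g0.meta))
    _validate_design(pop, config)
    return pop


def _validate_design(pop: Population, config: SimulationConfig) -> None:
    ped = pop.pedigree
    n_bulls = int(ped["is_bull"].sum())
    n_gens = config.bull_gen_last - config.bull_gen_first + 1
    if n_bulls != config.n_bulls_per_gen * n_gens:
        raise AssertionError(f"expected {config.n_bulls_per_gen * n_gens} bulls, got {n_bulls}")
    n_test = int(ped["is_test"].sum())
    if n_test != 2 * config.n_test_per_gen:
        raise AssertionError(f"expected {2 * config.n_test_per_gen} test bulls, got {n_test}")
    n_prog = int(ped["is_progeny"].sum())
    expect = n_bulls * config.progeny_per_bull
    if n_prog != expect:
        raise AssertionError(f"expected {expect} phenotyped progenies, got {n_prog}")
    # phenotyped progenies never appear as parents
    parents = set(ped.loc[ped["sire"] > 0, "sire"]) | set(ped.loc[ped["dam"] > 0, "dam"])
    prog = set(ped.loc[ped["is_progeny"], "id"])
    if parents & prog:
        raise AssertionError("phenotyped progenies must not be parents")


def simulate_replicate(config: SimulationConfig, rng: np.random.Generator):
    """One full replicate: historical phase -> G0 -> panels -> trait ->
    recent population with TBVs and phenotypes.

    Returns ``(population, trait)``; the population's genome map holds
    only the selected SNP and QTL panels and its meta carries the config.
    """
    from .trait import draw_qtl_effects, compute_tbv_and_phenotypes

    hist = simulate_historical(config, rng)
    g0 = found_recent(hist, config, rng)
    del hist
    snp_panel, qtl_panel = select_segregating_panels(g0, config, rng)
    g0p = restrict_to_panels(g0, snp_panel, qtl_panel)
    del g0
    trait = draw_qtl_effects(g0p, config, rng)
    pop = simulate_recent(g0p, config, rng)
    pop = compute_tbv_and_phenotypes(pop, trait, rng)
    pop.meta["config"] = config
    return pop, trait
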