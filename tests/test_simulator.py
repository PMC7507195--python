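"""Demography, breeding design, panels, trait architecture and LD."""

import numpy as np
import pandas as pd
import pytest

import bovisim as bv
from bovisim.genome import GenomeMap, ROLE_SNP, make_candidate_map
from bovisim.ld import compute_ld_decay
from bovisim.population import Population
from bovisim.simulator import (historical_trajectory, simulate_historical,
                               found_recent, select_segregating_panels,
                               restrict_to_panels)
from bovisim.trait import draw_qtl_effects, TraitArchitecture, compute_tbv_and_phenotypes
from helpers import mini_config, ped_frame


# ----------------------------------------------------------------- historical

def test_historical_trajectory_endpoints_and_shape():
    cfg = mini_config()
    sizes = historical_trajectory(cfg)
    assert sizes[0] == cfg.hist_n0
    assert sizes[cfg.hist_const_gens] == cfg.hist_n0
    assert sizes[cfg.hist_const_gens + cfg.hist_bottleneck_gens] == cfg.Ne_target
    assert sizes[-1] == cfg.hist_final_size
    assert len(sizes) == cfg.hist_const_gens + cfg.hist_bottleneck_gens + cfg.hist_expand_gens + 1


def test_historical_final_generation_has_balanced_sexes():
    cfg = mini_config()
    hist = simulate_historical(cfg, np.random.default_rng(0))
    assert hist.n_individuals == cfg.hist_final_size
    assert (hist.sex == "M").sum() == cfg.hist_final_size // 2
    assert (hist.sex == "F").sum() == cfg.hist_final_size - cfg.hist_final_size // 2


def test_historical_rejects_ne_above_base_size():
    with pytest.raises(ValueError):
        mini_config(Ne_target=5000)


def test_bottleneck_reduces_heterozygosity():
    # mini run 100 -> 10 -> 100: drift through the bottleneck must lose
    # diversity relative to the pre-bottleneck constant phase
    before, after = [], []
    for seed in range(20):
        cfg = mini_config(hist_n0=100, hist_const_gens=5, Ne_target=10,
                          hist_bottleneck_gens=5, hist_expand_gens=2,
                          hist_final_size=100, n_chromosomes=1,
                          snps_per_chrom_candidate=200, qtl_per_chrom_candidate=10,
                          n_snps_selected=100, nQTL=2)
        rng = np.random.default_rng(seed)
        constant = simulate_historical(
            cfg.replace(hist_bottleneck_gens=1, Ne_target=100, hist_expand_gens=1),
            rng)
        rng = np.random.default_rng(seed)
        squeezed = simulate_historical(cfg, rng)
        het = lambda h: float(np.mean(2 * h.allele_frequencies()
                                      * (1 - h.allele_frequencies())))
        before.append(het(constant))
        after.append(het(squeezed))
    assert np.mean(after) < np.mean(before)


def test_single_generation_drift_variance_matches_wright_fisher():
    # Var(delta p) ~ p(1-p)/(2N) for one generation of random union
    from bovisim.simulator import _next_generation
    N, m = 50, 400
    gm = make_candidate_map(mini_config(n_chromosomes=1,
                                        snps_per_chrom_candidate=m,
                                        qtl_per_chrom_candidate=1,
                                        n_snps_selected=100, nQTL=1),
                            np.random.default_rng(0))
    rng = np.random.default_rng(11)
    haps = (rng.random((N, 2, gm.n_loci)) < 0.5).astype(np.uint8)
    sex = np.array(["M", "F"] * (N // 2))
    p0 = haps.mean(axis=(0, 1))
    dp2 = []
    for _ in range(20):
        child, _sex = _next_generation(haps, sex, N, gm, 0.0, rng)
        p1 = child.mean(axis=(0, 1))
        dp2.append((p1 - p0) ** 2)
    expected = float(np.mean(p0 * (1 - p0)) / (2 * N))
    assert float(np.mean(dp2)) == pytest.approx(expected, rel=0.2)


# ----------------------------------------------------------------- G0 founders

def test_found_recent_counts_and_tags(mini_replicate):
    pop, _ = mini_replicate
    g0 = pop.pedigree[pop.pedigree["gen"] == 0]
    cfg = pop.meta["config"]
    assert len(g0) == cfg.n_sires + cfg.n_dams
    assert (g0["sire"] == 0).all() and (g0["dam"] == 0).all()
    assert (g0["sex"] == "M").sum() == cfg.n_sires


def test_found_recent_takes_all_males_when_pool_is_minimal():
    cfg = mini_config()
    hist = simulate_historical(cfg, np.random.default_rng(3))
    keep = np.r_[np.flatnonzero(hist.sex == "M")[: cfg.n_sires],
                 np.flatnonzero(hist.sex == "F")]
    hist.haplotypes = hist.haplotypes[keep]
    hist.sex = hist.sex[keep]
    marked = hist.haplotypes[: cfg.n_sires].copy()
    g0 = found_recent(hist, cfg, np.random.default_rng(4))
    males = g0.pedigree["sex"] == "M"
    got = g0.haplotypes[males.to_numpy()]
    assert np.array_equal(np.sort(got, axis=0), np.sort(marked, axis=0))


def test_found_recent_different_seeds_pick_different_females():
    cfg = mini_config()
    hist = simulate_historical(cfg, np.random.default_rng(5))
    a = found_recent(hist, cfg, np.random.default_rng(1))
    b = found_recent(hist, cfg, np.random.default_rng(2))
    fa = a.haplotypes[(a.pedigree["sex"] == "F").to_numpy()]
    fb = b.haplotypes[(b.pedigree["sex"] == "F").to_numpy()]
    assert not np.array_equal(fa, fb)


def test_found_recent_insufficient_candidates_raises():
    cfg = mini_config()
    hist = simulate_historical(cfg, np.random.default_rng(6))
    hist.sex = np.full(hist.n_individuals, "F")
    with pytest.raises(ValueError, match="males"):
        found_recent(hist, cfg, np.random.default_rng(0))


# ----------------------------------------------------------------- recent pop

def test_recent_population_design_counts(desk_replicate):
    pop, _ = desk_replicate
    cfg = pop.meta["config"]
    ped = pop.pedigree
    n_bull_gens = cfg.bull_gen_last - cfg.bull_gen_first + 1
    assert int(ped["is_bull"].sum()) == cfg.n_bulls_per_gen * n_bull_gens
    assert int(ped["is_test"].sum()) == 2 * cfg.n_test_per_gen
    assert int(ped["is_progeny"].sum()) == (cfg.n_bulls_per_gen * n_bull_gens
                                            * cfg.progeny_per_bull)
    # bulls live in G5-G10, their progenies in G6-G11, test bulls in G11-G12
    assert set(ped.loc[ped["is_bull"], "gen"]) == set(range(5, 11))
    assert set(ped.loc[ped["is_progeny"], "gen"]) == set(range(6, 12))
    assert set(ped.loc[ped["is_test"], "gen"]) == {11, 12}


def test_progeny_tiers_are_nested_subsets(desk_replicate):
    pop, _ = desk_replicate
    cfg = pop.meta["config"]
    full, mid, low = (set(pop.progeny_ids(per_bull=t)) for t in cfg.progeny_tiers)
    assert low < mid < full
    n_bulls = int(pop.pedigree["is_bull"].sum())
    assert len(mid) == n_bulls * cfg.progeny_tiers[1]


def test_pedigree_is_generation_consistent(mini_replicate):
    pop, _ = mini_replicate
    ped = pop.pedigree
    gen = ped.set_index("id")["gen"]
    for col in ("sire", "dam"):
        child_gen = ped.loc[ped[col] > 0, "gen"].to_numpy()
        parent_gen = gen.loc[ped.loc[ped[col] > 0, col]].to_numpy()
        assert np.all(parent_gen == child_gen - 1)


def test_phenotyped_progenies_never_breed(mini_replicate):
    pop, _ = mini_replicate
    ped = pop.pedigree
    parents = set(ped.loc[ped["sire"] > 0, "sire"]) | set(ped.loc[ped["dam"] > 0, "dam"])
    assert not parents & set(ped.loc[ped["is_progeny"], "id"])


def test_every_bull_sires_its_quota_of_phenotyped_progenies(mini_replicate):
    pop, _ = mini_replicate
    ped = pop.pedigree
    cfg = pop.meta["config"]
    by_sire = ped[ped["is_progeny"]].groupby("sire").size()
    bulls = ped.loc[ped["is_bull"], "id"]
    assert set(by_sire.index) == set(bulls)
    assert (by_sire == cfg.progeny_per_bull).all()
    # a bull's progenies are born in the generation after its own
    gen_of = ped.set_index("id")["gen"]
    prog = ped[ped["is_progeny"]]
    assert np.all(prog["gen"].to_numpy() == gen_of.loc[prog["sire"]].to_numpy() + 1)


# ----------------------------------------------------------------- panels

def _toy_g0(genotype_cols, roles, positions=None):
    """G0 population with explicit per-locus genotype columns (n x m)."""
    X = np.asarray(genotype_cols)
    n, m = X.shape
    pos = np.linspace(0, 100, m) if positions is None else np.asarray(positions)
    gm = GenomeMap(np.zeros(m, dtype=int), pos, np.asarray(roles), 100.0, 1)
    hap = np.zeros((n, 2, m), dtype=np.uint8)
    hap[:, 0, :] = (X >= 1)
    hap[:, 1, :] = (X == 2)
    ped = ped_frame([0] * n, [0] * n)
    return Population(ped, hap, gm)


def test_panel_selection_respects_maf_filter(desk_replicate):
    pop, _ = desk_replicate
    g0_ids = pop.ids_where((pop.pedigree["gen"] == 0).to_numpy())
    freq = pop.allele_frequencies(ids=g0_ids)
    maf = np.minimum(freq, 1 - freq)
    cfg = pop.meta["config"]
    assert len(pop.genome.snp_indices) == cfg.n_snps_selected
    assert len(pop.genome.qtl_indices) == cfg.nQTL
    assert (maf > cfg.maf_min).all()


def test_panel_selection_errors_when_nothing_segregates():
    cfg = mini_config(n_snps_selected=4, nQTL=1)
    X = np.zeros((6, 8), dtype=int)           # all monomorphic
    g0 = _toy_g0(X, [ROLE_SNP] * 8)
    with pytest.raises(ValueError, match="insufficient segregating"):
        select_segregating_panels(g0, cfg, np.random.default_rng(0))


def test_panel_selection_errors_at_unreachable_maf_threshold():
    cfg = mini_config(n_snps_selected=4, nQTL=1, maf_min=0.499)
    X = np.tile([0, 0, 0, 1, 1, 2], (8, 1)).T      # every column has MAF 1/3
    g0 = _toy_g0(X, [ROLE_SNP] * 8)
    with pytest.raises(ValueError, match="insufficient segregating"):
        select_segregating_panels(g0, cfg, np.random.default_rng(0))


# ----------------------------------------------------------------- trait

def test_variance_components_partition_phenotypic_variance(mini_replicate):
    _, trait = mini_replicate
    assert trait.sigma2_u + trait.sigma2_e == pytest.approx(1.0)
    assert trait.sigma2_u / (trait.sigma2_u + trait.sigma2_e) == pytest.approx(trait.h2)


def test_realized_g0_genetic_variance_equals_sigma2_u(desk_replicate):
    pop, trait = desk_replicate
    g0_tbv = pop.pedigree.loc[pop.pedigree["gen"] == 0, "tbv"].to_numpy()
    assert np.var(g0_tbv) == pytest.approx(trait.sigma2_u, rel=1e-6)


def test_single_qtl_effect_scaling_under_exact_hwe():
    # genotypes 0,1,1,2 give p=0.5 and empirical variance 2p(1-p)=0.5,
    # so |a| = sqrt(h2 / 0.5) regardless of the gamma draw
    from bovisim.genome import ROLE_QTL
    cfg = mini_config(h2=0.2, nQTL=1)
    g0 = _toy_g0(np.array([[0], [1], [1], [2]]), [ROLE_QTL])
    trait = draw_qtl_effects(g0, cfg, np.random.default_rng(0))
    assert abs(trait.qtl_effects[0]) == pytest.approx(np.sqrt(0.2 / 0.5))


def test_phenotype_equals_tbv_in_noiseless_limit(mini_replicate):
    pop, trait = mini_replicate
    noiseless = TraitArchitecture(trait.qtl_locus_indices, trait.qtl_effects,
                                  trait.qtl_ref_freq, trait.sigma2_u, 0.0, 1.0)
    pop2 = Population(pop.pedigree.copy(), pop.haplotypes, pop.genome, dict(pop.meta))
    pop2 = compute_tbv_and_phenotypes(pop2, noiseless, np.random.default_rng(0))
    ped = pop2.pedigree
    prog = ped["is_progeny"]
    assert np.allclose(ped.loc[prog, "phenotype"], ped.loc[prog, "tbv"])
    assert ped.loc[~prog, "phenotype"].isna().all()


def test_homozygous_reference_tbv_equals_centering_constant():
    from bovisim.genome import ROLE_QTL
    cfg = mini_config(h2=0.5, nQTL=2)
    X = np.array([[0, 0], [1, 1], [1, 1], [2, 2], [0, 2], [2, 0]])
    g0 = _toy_g0(X, [ROLE_QTL, ROLE_QTL])
    trait = draw_qtl_effects(g0, cfg, np.random.default_rng(1))
    pop = compute_tbv_and_phenotypes(g0, trait, np.random.default_rng(2))
    expected = -2.0 * float(np.sum(trait.qtl_effects * trait.qtl_ref_freq))
    assert pop.pedigree.loc[0, "tbv"] == pytest.approx(expected)


def test_phenotype_regression_on_tbv_recovers_heritability(desk_replicate):
    pop, trait = desk_replicate
    ped = pop.pedigree
    prog = ped["is_progeny"]
    y = ped.loc[prog, "phenotype"].to_numpy()
    tbv = ped.loc[prog, "tbv"].to_numpy()
    slope = np.cov(y, tbv)[0, 1] / np.var(tbv)
    r2 = np.corrcoef(y, tbv)[0, 1] ** 2
    assert slope == pytest.approx(1.0, abs=0.1)
    assert r2 == pytest.approx(np.var(tbv) / np.var(y), abs=0.05)


# ----------------------------------------------------------------- LD decay

def test_duplicated_locus_gives_r2_of_one():
    rng = np.random.default_rng(0)
    x = rng.integers(0, 3, 50).astype(float)
    X = np.c_[x, x]
    gm = GenomeMap(np.zeros(2, dtype=int), np.array([10.0, 10.0]),
                   np.array([ROLE_SNP, ROLE_SNP]), 100.0, 1)
    summ = compute_ld_decay(X, gm, bins=np.array([0.0, 1.0]), max_pairs=100,
                            rng=np.random.default_rng(1))
    assert summ.mean_r2[0] == pytest.approx(1.0)


def test_unlinked_loci_r2_matches_sampling_noise():
    # independent loci: E[r^2] ~ 1/n from finite-sample correlation noise
    rng = np.random.default_rng(2)
    n, m = 100, 300
    X = rng.binomial(2, 0.5, size=(n, m)).astype(float)
    gm = GenomeMap(np.zeros(m, dtype=int), np.sort(rng.uniform(0, 10, m)),
                   np.full(m, ROLE_SNP), 100.0, 1)
    summ = compute_ld_decay(X, gm, bins=np.array([0.0, 10.0]), max_pairs=20000,
                            rng=np.random.default_rng(3))
    assert summ.mean_r2[0] == pytest.approx(1.0 / n, rel=0.3)


def test_ld_summary_skips_monomorphic_pairs():
    X = np.c_[np.ones(40), np.random.default_rng(4).integers(0, 3, 40)].astype(float)
    gm = GenomeMap(np.zeros(2, dtype=int), np.array([1.0, 2.0]),
                   np.array([ROLE_SNP, ROLE_SNP]), 100.0, 1)
    summ = compute_ld_decay(X, gm, bins=np.array([0.0, 5.0]), max_pairs=50,
                            rng=np.random.default_rng(5))
    assert summ.n_skipped_monomorphic > 0
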