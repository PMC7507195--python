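"""SNP back-solution, weight refinement, window scans and power."""

import numpy as np
import pytest

from bovisim.ssgwas import (SnpEffectSet, backsolve_snp_effects, refine_weights,
                            window_variance_scan, define_true_qtl, compute_power)


def make_effects(beta, p=None, weights=None, iteration=1):
    beta = np.asarray(beta, dtype=float)
    p = np.full(len(beta), 0.5) if p is None else np.asarray(p, dtype=float)
    w = np.ones(len(beta)) if weights is None else np.asarray(weights, dtype=float)
    return SnpEffectSet(beta, w, p, iteration)


# ----------------------------------------------------------------- backsolve

def test_zero_gebv_gives_zero_snp_effects():
    rng = np.random.default_rng(0)
    W = rng.standard_normal((5, 12))
    eff = backsolve_snp_effects(np.zeros(5), W)
    assert np.allclose(eff.beta_hat, 0.0)


def test_backsolve_matches_dense_hand_solve_on_toy():
    W = np.array([[1.0, -1.0], [0.5, 2.0]])
    u = np.array([0.3, -0.7])
    eff = backsolve_snp_effects(u, W)
    expected = W.T @ np.linalg.solve(W @ W.T, u)
    assert np.allclose(eff.beta_hat, expected)


def test_backsolve_projection_identity_in_column_space():
    rng = np.random.default_rng(1)
    W = rng.standard_normal((4, 10))
    u = W @ rng.standard_normal(10)
    eff = backsolve_snp_effects(u, W)
    assert np.allclose(W @ eff.beta_hat, u, atol=1e-8)


def test_backsolve_weighted_matches_explicit_formula():
    rng = np.random.default_rng(2)
    W = rng.standard_normal((6, 15))
    d = rng.uniform(0.5, 2.0, 15)
    u = rng.standard_normal(6)
    eff = backsolve_snp_effects(u, W, weights=d)
    expected = d * (W.T @ np.linalg.solve((W * d) @ W.T, u))
    assert np.allclose(eff.beta_hat, expected)


def test_backsolve_dimension_mismatch_raises():
    with pytest.raises(ValueError):
        backsolve_snp_effects(np.zeros(3), np.zeros((4, 5)))


# ----------------------------------------------------------------- weights

def test_uniform_effects_and_frequencies_give_identity_weights():
    eff = make_effects([0.2, -0.2, 0.2, -0.2])
    assert np.allclose(refine_weights(eff), 1.0)


def test_single_nonzero_effect_concentrates_the_trace():
    eff = make_effects([0.0, 0.7, 0.0])
    d = refine_weights(eff)
    assert d[1] == pytest.approx(3.0)
    assert d[0] == d[2] == 0.0


def test_all_zero_effects_degenerate():
    with pytest.raises(ValueError, match="degenerate"):
        refine_weights(make_effects([0.0, 0.0]))


def test_refined_weights_keep_trace_equal_to_snp_count():
    rng = np.random.default_rng(3)
    eff = make_effects(rng.standard_normal(50), p=rng.uniform(0.1, 0.9, 50))
    d = refine_weights(eff)
    assert d.sum() == pytest.approx(50.0)


# ----------------------------------------------------------------- windows

def scan_fixture(n_animals=40, n_snps=60, window=5, n_chrom=2, seed=4,
                 beta=None):
    rng = np.random.default_rng(seed)
    W = rng.standard_normal((n_animals, n_snps))
    per_chrom = [n_snps // n_chrom] * n_chrom
    per_chrom[0] += n_snps - sum(per_chrom)
    chrom = np.repeat(np.arange(n_chrom), per_chrom)
    pos = np.empty(n_snps)
    for c in range(n_chrom):
        pos[chrom == c] = np.sort(rng.uniform(0, 100, (chrom == c).sum()))
    beta = rng.standard_normal(n_snps) if beta is None else beta
    eff = make_effects(beta, p=np.full(n_snps, 0.5))
    scan = window_variance_scan(eff, W, chrom, pos, 100.0, window_size=window)
    return scan, W, chrom, pos, beta


def test_single_active_window_explains_everything():
    beta = np.zeros(60)
    beta[10:15] = 1.0                       # exactly window 2 of chromosome 0
    scan, *_ = scan_fixture(beta=beta)
    assert scan.pct_variance.max() == pytest.approx(100.0)
    assert np.argmax(scan.pct_variance) == 2


def test_window_layout_tiles_chromosomes_in_order():
    scan, _, chrom, pos, _ = scan_fixture(n_snps=63, window=5)
    # windows never span chromosomes and tile each chromosome's loci
    for w in range(scan.n_windows):
        members = np.arange(scan.first_locus[w], scan.last_locus[w] + 1)
        assert len(set(chrom[members])) == 1
    # trailing windows shorter than the window size are kept
    sizes = scan.last_locus - scan.first_locus + 1
    assert sizes.sum() == 63
    assert (sizes <= 5).all()


def test_window_percentages_match_brute_force_recomputation():
    scan, W, chrom, pos, beta = scan_fixture()
    total = np.var(W @ beta)
    for w in range(scan.n_windows):
        members = np.arange(scan.first_locus[w], scan.last_locus[w] + 1)
        expected = 100.0 * np.var(W[:, members] @ beta[members]) / total
        assert scan.pct_variance[w] == pytest.approx(expected, abs=1e-10)


def test_uncorrelated_window_percentages_sum_near_hundred():
    rng = np.random.default_rng(5)
    n, m = 2000, 40
    W = rng.standard_normal((n, m))          # independent columns
    beta = rng.standard_normal(m)
    eff = make_effects(beta, p=np.full(m, 0.5))
    scan = window_variance_scan(eff, W, np.zeros(m, dtype=int),
                                np.linspace(0, 99, m), 100.0, window_size=5)
    assert scan.pct_variance.sum() == pytest.approx(100.0, abs=8.0)


def test_every_position_belongs_to_exactly_one_window():
    scan, _, chrom, pos, _ = scan_fixture()
    for c, p in [(0, 0.0), (0, 50.0), (1, 99.9), (1, 3.3)]:
        hits = [(scan.chrom[w] == c) and (scan.lo_cM[w] <= p < scan.hi_cM[w])
                for w in range(scan.n_windows)]
        assert sum(hits) == 1


# ----------------------------------------------------------------- power

def test_true_qtl_selection_and_power_thresholds():
    beta = np.full(60, 1e-3)        # faint background so no window is exactly 0
    beta[10:15] = 1.0
    beta[40:42] = 0.2
    scan, W, chrom, pos, _ = scan_fixture(beta=beta)
    qtl_chrom = np.array([0, 1, 1])
    qtl_pos = np.array([pos[12], pos[41], pos[55]])
    # threshold 0: every QTL inside a scanned window is a trueQTL
    assert len(define_true_qtl(scan, qtl_chrom, qtl_pos, threshold=0.0)) == 3
    tq = define_true_qtl(scan, qtl_chrom, qtl_pos, threshold=1.0)
    assert 0 in tq                            # the 50%-variance window QTL
    calls = compute_power(scan, qtl_chrom, qtl_pos, tq, threshold=1.0)
    assert calls.power == 1.0                 # same scan as the reference
    # power against a scan with no signal anywhere
    null_scan, *_ = scan_fixture(beta=np.full(60, 1e-6), seed=6)
    null_calls = compute_power(null_scan, qtl_chrom, qtl_pos, tq,
                               threshold=99.0)
    assert null_calls.power == 0.0


def test_power_is_missing_when_no_true_qtl():
    scan, *_ = scan_fixture()
    calls = compute_power(scan, np.array([0]), np.array([5.0]),
                          np.array([], dtype=int))
    assert np.isnan(calls.power)


def test_power_non_increasing_in_threshold():
    scan, W, chrom, pos, beta = scan_fixture(seed=7)
    qtl_chrom = chrom[::6]
    qtl_pos = pos[::6]
    tq = np.arange(len(qtl_pos))
    powers = [compute_power(scan, qtl_chrom, qtl_pos, tq, threshold=t).power
              for t in (0.0, 1.0, 5.0, 20.0)]
    assert all(a >= b for a, b in zip(powers, powers[1:]))


def test_weight_refinement_sharpens_a_single_qtl_signal():
    # one strong causal locus: after refinement its window share must grow
    rng = np.random.default_rng(8)
    n, m = 300, 60
    X = rng.binomial(2, 0.5, size=(n, m)).astype(float)
    p = X.mean(axis=0) / 2
    W = X - 2 * p
    beta_true = np.zeros(m)
    beta_true[30] = 1.0
    u = W @ beta_true + rng.standard_normal(n) * 0.5
    chrom = np.zeros(m, dtype=int)
    pos = np.linspace(0, 99, m)
    eff1 = backsolve_snp_effects(u, W, allele_freqs=p, iteration=1)
    scan1 = window_variance_scan(eff1, W, chrom, pos, 100.0, window_size=5)
    d2 = refine_weights(eff1)
    eff2 = backsolve_snp_effects(u, W, weights=d2, allele_freqs=p, iteration=2)
    scan2 = window_variance_scan(eff2, W, chrom, pos, 100.0, window_size=5)
    qtl_window = scan1.window_of(0, pos[30])
    assert scan2.pct_variance[qtl_window] > scan1.pct_variance[qtl_window]
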