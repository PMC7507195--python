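"""Scenario assembly and the replicate-level study driver.

Ten reference-population scenarios are compared on one simulated
population per replicate:

========  =================  ==========================  =============
scenario  bulls genotyped    progenies                   progeny tier
========  =================  ==========================  =============
SCEN0     no                 genotyped+phenotyped (+QTL)  full
SCEN1-3   no                 genotyped+phenotyped         full/mid/low
SCEN4-6   yes (300)          phenotyped only              full/mid/low
SCEN7-9   no (nobody)        phenotyped only              full/mid/low
========  =================  ==========================  =============

Progeny tiers are nested per-bull subsets (30/15/5 of each bull's
progenies at full scale). Test bulls (G11-G12) are genotyped in every
genomic scenario and never phenotyped; bulls are never phenotyped.
Power is measured against the trueQTL of the same replicate's SCEN0
scan; accuracy is the Pearson correlation between TBV and the predicted
breeding value over the test bulls.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .kinship import build_A_inverse, build_A22, build_G, tune_G, build_H_inverse
from .mixed_model import ModelSpec, estimate_varcomps, solve_mme, VarComps
from .population import Population
from .simulator import simulate_replicate
from .ssgwas import (backsolve_snp_effects, refine_weights,
                     window_variance_scan, define_true_qtl, compute_power,
                     WindowScan, DEFAULT_THRESHOLD, DEFAULT_WINDOW_SIZE)

logger = logging.getLogger(__name__)

__all__ = [
    "SCENARIOS", "ScenarioDataset", "build_scenario", "validate_scenario",
    "evaluate_accuracy", "run_replicate", "run_condition",
    "EvaluationReport", "goddard_expected_accuracy", "summarize_report",
]

# scenario -> (progeny tier index, bulls genotyped, progenies genotyped, QTL included)
SCENARIOS: dict[str, tuple[int, bool, bool, bool]] = {
    "SCEN0": (0, False, True, True),
    "SCEN1": (0, False, True, False),
    "SCEN2": (1, False, True, False),
    "SCEN3": (2, False, True, False),
    "SCEN4": (0, True, False, False),
    "SCEN5": (1, True, False, False),
    "SCEN6": (2, True, False, False),
    "SCEN7": (0, False, False, False),
    "SCEN8": (1, False, False, False),
    "SCEN9": (2, False, False, False),
}

GEBV_SCENARIOS = tuple(f"SCEN{i}" for i in range(7))
EBV_SCENARIOS = ("SCEN7", "SCEN8", "SCEN9")


@dataclass
class ScenarioDataset:
    scenario_id: str
    genotyped_ids: np.ndarray
    phenotyped_ids: np.ndarray
    include_qtl_in_genotypes: bool
    progeny_per_bull: int
    n_progeny: int


def build_scenario(population: Population, scenario_id: str,
                   progeny_per_bull: int | None = None,
                   config: SimulationConfig | None = None) -> ScenarioDataset:
    """Assemble the genotype/phenotype id sets of one Table-row scenario."""
    if scenario_id not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario_id!r}")
    cfg = config or population.meta.get("config")
    if cfg is None:
        raise ValueError("population carries no config; pass config=")
    tier, bulls_g, prog_g, with_qtl = SCENARIOS[scenario_id]
    per_bull = cfg.progeny_tiers[tier] if progeny_per_bull is None else int(progeny_per_bull)
    if per_bull > cfg.progeny_per_bull:
        raise ValueError(
            f"scenario needs {per_bull} progenies per bull but the population "
            f"was simulated with {cfg.progeny_per_bull}")
    prog_ids = population.progeny_ids(per_bull=per_bull)
    genotyped: list[np.ndarray] = []
    if bulls_g:
        genotyped.append(population.bull_ids)
    if prog_g:
        genotyped.append(prog_ids)
    if bulls_g or prog_g or with_qtl:
        genotyped.append(population.test_ids)
    gids = np.sort(np.concatenate(genotyped)) if genotyped else np.array([], dtype=np.int64)
    return ScenarioDataset(scenario_id, gids, np.sort(prog_ids), with_qtl,
                           per_bull, len(prog_ids))


def validate_scenario(dataset: ScenarioDataset, population: Population) -> None:
    """Conformance check of a dataset against its scenario definition."""
    ped = population.pedigree
    tier, bulls_g, prog_g, with_qtl = SCENARIOS[dataset.scenario_id]
    byid = ped.set_index("id")
    phen = byid.loc[dataset.phenotyped_ids]
    if not phen["is_progeny"].all():
        raise AssertionError("phenotyped set must contain progenies only")
    if np.isin(population.bull_ids, dataset.phenotyped_ids).any():
        raise AssertionError("bulls must never be phenotyped")
    geno = set(dataset.genotyped_ids.tolist())
    bulls = set(population.bull_ids.tolist())
    test = set(population.test_ids.tolist())
    prog = set(dataset.phenotyped_ids.tolist())
    expected = set()
    if bulls_g:
        expected |= bulls
    if prog_g:
        expected |= prog
    if bulls_g or prog_g or with_qtl:
        expected |= test
    if geno != expected:
        raise AssertionError(f"{dataset.scenario_id}: genotyped set mismatch")
    if dataset.include_qtl_in_genotypes != with_qtl:
        raise AssertionError("QTL-in-genotypes flag mismatch")


def evaluate_accuracy(u_hat: np.ndarray, population: Population,
                      test_ids: np.ndarray | None = None) -> float:
    """Pearson correlation of TBV and prediction over the test bulls.

    Zero-variance predictions are recorded as accuracy 0 (with a log
    flag) rather than NaN.
    """
    ids = population.test_ids if test_ids is None else np.asarray(test_ids)
    rows = population.rows_of(ids)
    if len(u_hat) != population.n_individuals:
        raise ValueError("predictions must cover the whole pedigree")
    tbv = population.pedigree["tbv"].to_numpy()[rows]
    pred = np.asarray(u_hat)[rows]
    if np.isnan(tbv).any():
        raise ValueError("missing TBV among test animals")
    if pred.std() == 0 or tbv.std() == 0:
        logger.warning("evaluate_accuracy: zero-variance predictions, accuracy=0")
        return 0.0
    return float(np.corrcoef(tbv, pred)[0, 1])


# --------------------------------------------------------------------------
# per-replicate machinery
# --------------------------------------------------------------------------

def _scan_loci(population: Population, include_qtl: bool) -> np.ndarray:
    gm = population.genome
    return np.arange(gm.n_loci) if include_qtl else gm.snp_indices


def _gwas_scan(population: Population, dataset: ScenarioDataset, rel,
               varcomps: VarComps, window_size: int = DEFAULT_WINDOW_SIZE,
               n_iterations: int = 2, mme_tol: float = 1e-10) -> WindowScan:
    """Two-iteration weighted single-step GWAS for one scenario."""
    loci = _scan_loci(population, dataset.include_qtl_in_genotypes)
    gm = population.genome
    X = population.genotypes(dataset.genotyped_ids, loci=loci)
    p = X.mean(axis=0) / 2.0
    # loci fixed (or constant-genotype) within the genotyped set carry no
    # signal and would get zero weight; drop them from the scan up front
    poly = (p > 0) & (p < 1) & (X.var(axis=0) > 0)
    if not poly.all():
        logger.info("%s: dropping %d loci monomorphic among genotyped animals",
                    dataset.scenario_id, int((~poly).sum()))
    loci, X, p = loci[poly], X[:, poly], p[poly]
    W = X - 2.0 * p
    g_rows = population.rows_of(dataset.genotyped_ids)
    A22 = build_A22(rel, g_rows)
    y = population.pedigree.set_index("id").loc[dataset.phenotyped_ids, "phenotype"].to_numpy()
    rec_rows = population.rows_of(dataset.phenotyped_ids)
    d = np.ones(loci.size)
    eff = None
    for it in range(1, n_iterations + 1):
        grm = build_G(X, allele_freqs=p, weights=d)
        Gt, _, _ = tune_G(grm, A22)
        hinv = build_H_inverse(rel, A22, Gt, alpha=1.0, beta=0.0,
                               genotyped_rows=g_rows, ridge=1e-8)
        spec = ModelSpec(y, rec_rows, hinv, varcomps.sigma2_u, varcomps.sigma2_e)
        sol = solve_mme(spec, tol=mme_tol)
        u_g = sol.u_hat[g_rows]
        gram = 2.0 * float(np.sum(p * (1.0 - p))) * hinv.Gb
        eff = backsolve_snp_effects(u_g, W, weights=d, allele_freqs=p,
                                    iteration=it, gram=gram)
        if it < n_iterations:
            d = refine_weights(eff)
    return window_variance_scan(eff, W, gm.chrom[loci], gm.pos_cM[loci],
                                gm.chrom_length, window_size=window_size)


def _genomic_prediction(population: Population, dataset: ScenarioDataset, rel,
                        varcomps: VarComps, alpha: float = 0.95,
                        beta: float = 0.05, mme_tol: float = 1e-10) -> np.ndarray:
    """ssGBLUP GEBVs for all pedigree members under one scenario."""
    loci = _scan_loci(population, dataset.include_qtl_in_genotypes)
    X = population.genotypes(dataset.genotyped_ids, loci=loci)
    g_rows = population.rows_of(dataset.genotyped_ids)
    A22 = build_A22(rel, g_rows)
    grm = build_G(X)
    Gt, _, _ = tune_G(grm, A22)
    hinv = build_H_inverse(rel, A22, Gt, alpha=alpha, beta=beta,
                           genotyped_rows=g_rows)
    y = population.pedigree.set_index("id").loc[dataset.phenotyped_ids, "phenotype"].to_numpy()
    spec = ModelSpec(y, population.rows_of(dataset.phenotyped_ids), hinv,
                     varcomps.sigma2_u, varcomps.sigma2_e)
    return solve_mme(spec, tol=mme_tol).u_hat


def _pedigree_prediction(population: Population, dataset: ScenarioDataset, rel,
                         varcomps: VarComps, mme_tol: float = 1e-10) -> np.ndarray:
    y = population.pedigree.set_index("id").loc[dataset.phenotyped_ids, "phenotype"].to_numpy()
    spec = ModelSpec(y, population.rows_of(dataset.phenotyped_ids), rel,
                     varcomps.sigma2_u, varcomps.sigma2_e)
    return solve_mme(spec, tol=mme_tol).u_hat


def run_replicate(config: SimulationConfig, scenarios: list[str],
                  seed, threshold: float = DEFAULT_THRESHOLD,
                  window_size: int = DEFAULT_WINDOW_SIZE) -> pd.DataFrame:
    """Simulate one population and evaluate all requested scenarios on it."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    pop, trait = simulate_replicate(config, rng)
    pop.meta["config"] = config
    rel = build_A_inverse(pop.pedigree)

    # variance components: once per replicate on the full-progeny dataset
    # with progeny genotypes, GWAS-mode relationship (alpha=1, beta=0)
    vc_ds = build_scenario(pop, "SCEN1", config=config)
    g_rows = pop.rows_of(vc_ds.genotyped_ids)
    A22 = build_A22(rel, g_rows)
    X = pop.genotypes(vc_ds.genotyped_ids, loci=pop.genome.snp_indices)
    grm = build_G(X)
    Gt, _, _ = tune_G(grm, A22)
    hinv_vc = build_H_inverse(rel, A22, Gt, 1.0, 0.0, g_rows, ridge=1e-8)
    y_vc = pop.pedigree.set_index("id").loc[vc_ds.phenotyped_ids, "phenotype"].to_numpy()
    vc = estimate_varcomps(y_vc, pop.rows_of(vc_ds.phenotyped_ids), hinv_vc)

    need_power = any(s in scenarios for s in GEBV_SCENARIOS[1:])
    scen_list = list(scenarios)
    if need_power and "SCEN0" not in scen_list:
        scen_list = ["SCEN0"] + scen_list

    qtl_loci = pop.genome.qtl_indices
    qtl_chrom = pop.genome.chrom[qtl_loci]
    qtl_pos = pop.genome.pos_cM[qtl_loci]
    true_qtl = None
    rows = []
    for scen in scen_list:
        ds = build_scenario(pop, scen, config=config)
        validate_scenario(ds, pop)
        power = math.nan
        n_true = math.nan
        if scen in GEBV_SCENARIOS:
            scan = _gwas_scan(pop, ds, rel, vc, window_size=window_size)
            if scen == "SCEN0":
                true_qtl = define_true_qtl(scan, qtl_chrom, qtl_pos, threshold)
                n_true = len(true_qtl)
                calls = compute_power(scan, qtl_chrom, qtl_pos, true_qtl, threshold)
                power = calls.power
            elif true_qtl is not None:
                n_true = len(true_qtl)
                calls = compute_power(scan, qtl_chrom, qtl_pos, true_qtl, threshold)
                power = calls.power
            u_hat = _genomic_prediction(pop, ds, rel, vc)
            kind = "GEBV"
        else:
            u_hat = _pedigree_prediction(pop, ds, rel, vc)
            kind = "EBV"
        acc = evaluate_accuracy(u_hat, pop)
        rows.append({
            "Ne": config.Ne_target, "h2": config.h2, "nQTL": config.nQTL,
            "scenario": scen, "kind": kind, "n_progeny": ds.n_progeny,
            "power": power, "accuracy": acc, "n_trueqtl": n_true,
            "h2_hat": vc.h2, "sigma2_u_hat": vc.sigma2_u,
            "sigma2_e_hat": vc.sigma2_e,
        })
    return pd.DataFrame(rows)


@dataclass
class EvaluationReport:
    records: pd.DataFrame            # one row per condition x scenario x replicate

    def aggregate(self) -> pd.DataFrame:
        """Replicate mean and SD per condition x scenario (SD NaN at n=1)."""
        grp = self.records.groupby(["Ne", "h2", "nQTL", "scenario"], sort=True)
        out = grp.agg(
            n_replicates=("replicate", "nunique"),
            power_mean=("power", "mean"),
            power_sd=("power", lambda s: s.std(ddof=1)),
            accuracy_mean=("accuracy", "mean"),
            accuracy_sd=("accuracy", lambda s: s.std(ddof=1)),
        ).reset_index()
        return out


def run_condition(config: SimulationConfig, scenarios: list[str] | None = None,
                  n_replicates: int | None = None,
                  master_seed: int = 0) -> EvaluationReport:
    """Replicate loop over one (Ne, h2, nQTL) condition.

    Each replicate simulates a fresh population (historical + recent),
    runs GWAS and genomic/pedigree evaluation for every requested
    scenario, and the report aggregates replicate means and SDs.
    Deterministic given ``master_seed``. A failing replicate is logged
    and the cell reported with reduced n.
    """
    scenarios = list(SCENARIOS) if scenarios is None else list(scenarios)
    n_rep = config.n_replicates if n_replicates is None else int(n_replicates)
    frames = []
    for rep in range(n_rep):
        try:
            df = run_replicate(config, scenarios, seed=[master_seed, rep])
        except Exception:
            logger.exception("replicate %d failed; reporting reduced n", rep)
            continue
        df["replicate"] = rep
        frames.append(df)
    if not frames:
        return EvaluationReport(pd.DataFrame(columns=[
            "Ne", "h2", "nQTL", "scenario", "kind", "n_progeny", "power",
            "accuracy", "n_trueqtl", "h2_hat", "sigma2_u_hat",
            "sigma2_e_hat", "replicate"]))
    return EvaluationReport(pd.concat(frames, ignore_index=True))


def goddard_expected_accuracy(Ne: float, N: float, h2: float, L: float) -> float:
    """Expected GEBV accuracy from the Goddard (2009) closed form.

    Me = 2 Ne L / ln(4 Ne L) independent chromosome segments,
    lambda = Me / (h2 ln(2 Ne)), a = 1 + 2 lambda / N, and

        r = sqrt(1 - lambda / (2 N sqrt(a))
                 * ln((1 + a + 2 sqrt(a)) / (1 + a - 2 sqrt(a))))

    with N phenotyped individuals and total map length L in Morgans.
    """
    if min(Ne, N, h2, L) <= 0:
        raise ValueError("all arguments must be positive")
    Me = 2.0 * Ne * L / math.log(4.0 * Ne * L)
    lam = Me / (h2 * math.log(2.0 * Ne))
    a = 1.0 + 2.0 * lam / N
    sa = math.sqrt(a)
    term = lam / (2.0 * N * sa) * math.log((1.0 + a + 2.0 * sa) /
                                           (1.0 + a - 2.0 * sa))
    return math.sqrt(min(max(1.0 - term, 0.0), 1.0))


def summarize_report(report: EvaluationReport) -> dict[str, pd.DataFrame]:
    """Mean +/- SD tables per scenario x condition, plus per-scenario ranges.

    Ranges (min-max of the scenario mean across the condition sub-grid)
    mirror the style in which simulation studies of this design usually
    print their results. Empty reports give empty tables.
    """
    agg = report.aggregate()
    if agg.empty:
        empty = pd.DataFrame()
        logger.warning("summarize_report: empty report")
        return {"aggregate": agg, "power": empty, "accuracy": empty, "ranges": empty}
    power = agg.pivot_table(index=["Ne", "h2", "nQTL"], columns="scenario",
                            values="power_mean")
    accuracy = agg.pivot_table(index=["Ne", "h2", "nQTL"], columns="scenario",
                               values="accuracy_mean")
    ranges = agg.groupby("scenario").agg(
        power_min=("power_mean", "min"), power_max=("power_mean", "max"),
        accuracy_min=("accuracy_mean", "min"),
        accuracy_max=("accuracy_mean", "max")).reset_index()
    return {"aggregate": agg, "power": power, "accuracy": accuracy,
            "ranges": ranges}
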