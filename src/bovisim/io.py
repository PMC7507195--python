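"""File formats: PLINK .ped/.map, pedigree/phenotype CSVs, HDF5 cache,
and the run manifest.

Genetic positions are stored in cM in the .map genetic-distance column;
the base-pair column is synthesised at 1 cM = 1 Mbp. Alleles are coded
1/2 (allele 0 -> "1", allele 1 -> "2"). Unknown parents are coded 0.
Writes go through a temp-then-rename step so a crash never leaves a
partial file behind.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .genome import GenomeMap, ROLE_QTL
from .population import Population, PEDIGREE_COLUMNS

__all__ = ["write_population", "read_population", "save_population_h5",
           "load_population_h5", "RunManifest"]


def _atomic_write(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def _map_lines(genome: GenomeMap, loci: np.ndarray) -> str:
    lines = []
    for k, loc in enumerate(loci):
        c = genome.chrom[loc] + 1
        pos = genome.pos_cM[loc]
        bp = int(round(pos * 1_000_000))            # 1 cM = 1 Mbp
        lines.append(f"{c}\tSNP{k + 1}\t{pos:.6f}\t{bp}")
    return "\n".join(lines) + "\n"


def write_population(population: Population, out_dir: str | Path) -> dict[str, Path]:
    """Write PLINK .ped/.map (SNP panel), pedigree/phenotype/TBV CSVs and
    the QTL-truth CSV. Returns the file inventory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ped = population.pedigree
    gm = population.genome
    snp = gm.snp_indices

    files = {
        "map": out / "genotypes.map",
        "ped": out / "genotypes.ped",
        "pedigree": out / "pedigree.csv",
        "phenotypes": out / "phenotypes.csv",
        "qtl": out / "qtl_truth.csv",
    }
    _atomic_write(files["map"], _map_lines(gm, snp))

    hap = population.haplotypes[:, :, snp]
    lines = []
    sex_code = ped["sex"].map({"M": 1, "F": 2}).to_numpy()
    for r in range(len(ped)):
        a = (hap[r, 0] + 1).astype("U1")
        b = (hap[r, 1] + 1).astype("U1")
        geno = " ".join(x + " " + y for x, y in zip(a, b))
        row = ped.iloc[r]
        lines.append(f"1 {row['id']} {row['sire']} {row['dam']} {sex_code[r]} -9 {geno}")
    _atomic_write(files["ped"], "\n".join(lines) + "\n")

    role = np.select(
        [ped["is_bull"], ped["is_test"], ped["is_progeny"]],
        ["bull", "test", "progeny"], default="breeding")
    pd_out = ped[["id", "sire", "dam", "sex", "gen"]].copy()
    pd_out["role"] = role                      # human-readable primary role
    for col in ("is_breeding", "is_bull", "is_test", "is_progeny"):
        pd_out[col] = ped[col].astype(int)     # roles overlap (bulls breed)
    pd_out["progeny_rank"] = ped["progeny_rank"]
    _atomic_write(files["pedigree"], pd_out.to_csv(index=False))
    _atomic_write(files["phenotypes"],
                  ped[["id", "phenotype", "tbv"]].to_csv(index=False))

    qtl = gm.qtl_indices
    effects = population.meta.get("qtl_effects")
    qdf = pd.DataFrame({
        "chrom": gm.chrom[qtl] + 1,
        "pos_cM": gm.pos_cM[qtl],
        "effect": effects if effects is not None else np.nan,
    })
    _atomic_write(files["qtl"], qdf.to_csv(index=False))
    return files


def read_population(out_dir: str | Path) -> Population:
    """Re-read a population written by :func:`write_population`.

    Phase order of the .ped allele pairs is preserved by the writer, so
    the haplotypes round-trip exactly; QTL genotypes are not part of the
    PLINK panel, so the genome map of the result holds the SNP panel only.
    """
    out = Path(out_dir)
    mp = pd.read_csv(out / "genotypes.map", sep="\t",
                     names=["chrom", "snp", "cM", "bp"])
    n_chrom = int(mp["chrom"].max())
    gm = GenomeMap(mp["chrom"].to_numpy() - 1, mp["cM"].to_numpy(),
                   np.zeros(len(mp), dtype=np.int8),
                   chrom_length=float(np.ceil(mp["cM"].max())), n_chromosomes=n_chrom)

    ped_csv = pd.read_csv(out / "pedigree.csv")
    phen = pd.read_csv(out / "phenotypes.csv")
    ped = pd.DataFrame({
        "id": ped_csv["id"], "sire": ped_csv["sire"], "dam": ped_csv["dam"],
        "sex": ped_csv["sex"], "gen": ped_csv["gen"],
        "is_breeding": ped_csv["is_breeding"].astype(bool),
        "is_bull": ped_csv["is_bull"].astype(bool),
        "is_test": ped_csv["is_test"].astype(bool),
        "is_progeny": ped_csv["is_progeny"].astype(bool),
        "progeny_rank": ped_csv["progeny_rank"],
        "tbv": phen["tbv"], "phenotype": phen["phenotype"],
    }, columns=PEDIGREE_COLUMNS)

    n, m = len(ped), len(mp)
    hap = np.empty((n, 2, m), dtype=np.uint8)
    with open(out / "genotypes.ped") as fh:
        for r, line in enumerate(fh):
            parts = line.split()
            geno = np.array(parts[6:], dtype=np.uint8) - 1
            hap[r, 0] = geno[0::2]
            hap[r, 1] = geno[1::2]
    return Population(ped, hap, gm)


# --------------------------------------------------------------------------
# HDF5 cache (fast binary round trip, including QTL loci)
# --------------------------------------------------------------------------

def save_population_h5(population: Population, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("haplotypes", data=population.haplotypes,
                         compression="gzip", compression_opts=1)
        g = f.create_group("genome")
        g.create_dataset("chrom", data=population.genome.chrom)
        g.create_dataset("pos_cM", data=population.genome.pos_cM)
        g.create_dataset("role", data=population.genome.role)
        g.attrs["chrom_length"] = population.genome.chrom_length
        g.attrs["n_chromosomes"] = population.genome.n_chromosomes
        ped = population.pedigree
        p = f.create_group("pedigree")
        for col in PEDIGREE_COLUMNS:
            data = ped[col].to_numpy()
            if data.dtype == object:
                data = data.astype("S1")
            p.create_dataset(col, data=data)


def load_population_h5(path: str | Path) -> Population:
    with h5py.File(path, "r") as f:
        hap = f["haplotypes"][...]
        g = f["genome"]
        gm = GenomeMap(g["chrom"][...], g["pos_cM"][...], g["role"][...],
                       float(g.attrs["chrom_length"]), int(g.attrs["n_chromosomes"]))
        cols = {}
        for col in PEDIGREE_COLUMNS:
            data = f["pedigree"][col][...]
            if data.dtype.kind == "S":
                data = data.astype(str)
            cols[col] = data
    return Population(pd.DataFrame(cols, columns=PEDIGREE_COLUMNS), hap, gm)


# --------------------------------------------------------------------------
# run manifest
# --------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class RunManifest:
    """Reproducibility record: config, seeds, timings, file checksums."""

    def __init__(self, config_dict: dict, master_seed: int) -> None:
        from . import __version__
        self.data = {
            "software": "bovisim",
            "version": __version__,
            "config": config_dict,
            "master_seed": master_seed,
            "stage_seeds": {},
            "timings_s": {},
            "files": {},
        }
        self._t0: dict[str, float] = {}

    def stage_seed(self, stage: str, seed) -> None:
        self.data["stage_seeds"][stage] = seed

    def start(self, stage: str) -> None:
        self._t0[stage] = time.perf_counter()

    def stop(self, stage: str) -> None:
        self.data["timings_s"][stage] = round(time.perf_counter() - self._t0[stage], 3)

    def add_files(self, files: dict[str, Path]) -> None:
        for name, path in files.items():
            self.data["files"][str(path)] = _sha256(Path(path))

    def verify(self) -> bool:
        return all(_sha256(Path(p)) == h for p, h in self.data["files"].items())

    def write(self, path: str | Path) -> None:
        _atomic_write(Path(path), json.dumps(self.data, indent=2, default=str))

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        m = cls.__new__(cls)
        m.data = json.loads(Path(path).read_text())
        m._t0 = {}
        return m
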