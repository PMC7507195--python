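# bovisim

Forward-in-time simulation of cattle breeding populations with
single-step GBLUP genomic evaluation and weighted single-step GWAS.

Genotyping a reference population is expensive. A cost-effective
alternative to genotyping thousands of phenotyped animals is to
genotype a few hundred progeny-tested bulls, each of whose genotype
aggregates the information of its phenotyped progenies. `bovisim` is a
simulation laboratory for that trade-off: it breeds a cattle population
with a configurable effective population size (Ne), heritability (h²)
and number of QTL (nQTL), then measures QTL-detection power and the
accuracy of genomic estimated breeding values (GEBV) for young
unphenotyped bulls under ten reference-population scenarios — progenies
genotyped and phenotyped (SCEN1–3, with 9,000/4,500/1,500 progenies at
full scale), bulls genotyped with progenies phenotyped only (SCEN4–6),
nobody genotyped (SCEN7–9, pedigree BLUP), and an idealised reference
with the QTL genotyped alongside the SNPs (SCEN0).

## Model

The single-trait animal model is y = 1μ + Zu + e with
u ~ N(0, H σ²ᵤ) and e ~ N(0, I σ²ₑ), solved through

    H⁻¹ = A⁻¹ + [0 0; 0 (αG + βA₂₂)⁻¹ − A₂₂⁻¹]

where A is the pedigree numerator relationship matrix, A₂₂ its
genotyped block, and G the VanRaden method-1 genomic relationship
matrix rescaled to the pedigree base by mean-matching (α, β = 0.95,
0.05 for evaluation; 1, 0 for GWAS). SNP effects are back-solved from
the genotyped animals' GEBVs as β̂ = DW′(WDW′)⁻¹ûg, the per-SNP weights
D refined once (dᵢ = β̂ᵢ² 2pᵢ(1−pᵢ), trace-normalised) over exactly two
iterations, and the percentage of genetic variance per window of 20
adjacent SNPs scores each region. QTL detectable at >1% of the genetic
variance in SCEN0 define the trueQTL; power is the fraction of trueQTL
recovered in a scenario. Accuracy is the correlation between true and
estimated breeding values over 100 test bulls (G11–G12). Variance
components come from exact REML on the record block. See
`docs/methods.md` for the full account.

## Worked example

One desk-scale replicate (5 chromosomes, 5,000 SNPs, 60 bulls, 600
phenotyped progenies — the `desk` profile; the `paper` profile holds
the full-scale design):

```python
import numpy as np, bovisim as bv

cfg = bv.profile("desk", Ne_target=20, h2=0.5, nQTL=50)
df = bv.run_replicate(cfg, ["SCEN0", "SCEN1", "SCEN4", "SCEN7"], seed=7)
print(df[["scenario", "kind", "n_progeny", "power", "accuracy"]].round(3))
```

prints

```
  scenario  kind  n_progeny  power  accuracy
0    SCEN0  GEBV        600  1.000     0.739
1    SCEN1  GEBV        600  0.833     0.722
2    SCEN4  GEBV        600  0.167     0.223
3    SCEN7   EBV        600    NaN    -0.122
```

Reading the rows: with the QTL themselves genotyped (SCEN0) every
detectable QTL is found and the test bulls' GEBV accuracy is 0.74;
dropping the QTL columns (SCEN1) barely changes accuracy; moving the
genotypes from the 600 progenies to the 60 bulls (SCEN4) costs both
power and accuracy (desk-scale bulls carry only 10 progeny records
each, so this drop is steeper than at full scale); with no genotypes at
all (SCEN7) the unphenotyped test bulls are essentially unevaluable
(the correlation is sampling noise around zero over 20 test bulls, and
power is undefined without a genomic scan). Replicated conditions
aggregate with `bv.run_condition(...)` / `bv.summarize_report(...)`.

The same pipeline is scriptable from the shell:

```sh
bovisim simulate --profile desk --seed 1 --out runs/pop1     # PLINK ped/map + CSVs + HDF5
bovisim evaluate --profile desk --seed 1 --out runs/eval1    # all scenarios, report.tsv
bovisim report --report runs/eval1/report.tsv
```

File formats: PLINK `.ped`/`.map` (alleles 1/2, genetic distance in cM,
base pairs synthesised at 1 cM = 1 Mbp), pedigree/phenotype/TBV/QTL
CSVs (unknown parents coded 0), an HDF5 population cache, and a JSON
run manifest with config, seeds and file checksums.

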