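# Methods

`bovisim` simulates a closed cattle breeding population forward in time
and evaluates two questions on it: how well a weighted single-step GWAS
recovers the simulated QTL, and how accurately single-step GBLUP
predicts the breeding values of young, unphenotyped bulls, when the
reference population consists either of phenotyped+genotyped progenies
or of genotyped progeny-tested bulls whose progenies carry the
phenotypes.

## Simulation model

**Historical phase.** A population of constant size N0 is bred for many
discrete generations by random union of gametes, building
mutation–drift equilibrium and background linkage disequilibrium. The
size then declines linearly over 30 generations to the target effective
size Ne (20 or 100), and expands to the final historical size over 3
generations (linear interpolation in both ramps; only the endpoints are
part of the design, the interpolation is our choice). Base haplotypes
start at allele frequency 0.5 per locus; recurrent mutation (allele
flips at 2.5e-5 per locus per meiosis, for both SNPs and QTL) maintains
variation. Sex ratios are kept exactly balanced each generation: the
breeding design requires every female of a generation as a replacement
dam, so a Bernoulli sex draw would make the design infeasible about
half the time; we treat "equal chances of being male or female" as an
exchangeable balanced assignment.

**Meiosis.** Crossover counts per chromosome are Poisson with mean
equal to the map length in Morgans, positions uniform, no interference
(Haldane model), starting strand a fair coin per chromosome —
chromosomes therefore assort independently.

**Recent population.** From the last historical generation, n_sires
males and n_dams females found G0. Each generation every dam is mated
once (each sire serving an equal random share of dams) and produces a
litter of two; replacements are drawn uniformly with no selection on
merit, for 12 discrete generations. G0–G4 exist only as pedigree.

**Progeny-tested bulls.** In each of G5–G10, a fixed number of bulls is
drawn uniformly from the generation's males, *independently* of the
replacement draw. Each bull sires its quota of phenotyped progenies in
the next generation through extra matings to randomly chosen dams of
its own generation (dams may be reused); these progenies never become
parents. Tagging the breeding sires instead would make every test bull
the son of a progeny-tested bull and gives pedigree-only evaluation a
substantial parent-average accuracy, which contradicts the
near-uninformative pedigree-only evaluation this design is meant to
exhibit; the independent draw is the only reading consistent with that
behaviour. Test bulls are drawn the same way in G11–G12 and carry
genotypes and true breeding values but no phenotypes.

**Genome and trait.** Candidate SNPs and QTL are scattered uniformly on
30 x 100 cM chromosomes (paper-scale profile). Panels are drawn
uniformly among candidates with MAF > 0.05 measured in G0; panels are
never silently shrunk — too few segregating candidates is an error.
QTL effect magnitudes are gamma(shape 0.4) with random sign, rescaled
by one common factor so that the *realized* variance of the QTL score
among the G0 founders equals sigma2_u = h2 * Vp (Vp = 1). We scale to
the realized variance rather than the linkage-equilibrium expression
sum 2p(1-p)a^2 because drift through the bottleneck leaves substantial
LD among QTL; the two differ by up to ~30% at Ne = 20, and the realized
scaling is what "a scale parameter determined internally for the
simulated genetic variance" produces. Phenotypes are TBV plus
independent Gaussian noise with variance 1 - sigma2_u, assigned only to
the designated progenies.

## Relationship matrices and mixed model

* A-inverse: Henderson's rules with inbreeding; inbreeding coefficients
  by the Meuwissen & Luo (1992) algorithm. A-blocks (A22 and arbitrary
  sub-blocks) come from the factorisation A = T D T' by two sparse
  triangular solves (Colleau 2002) — the full A is never formed.
* G: VanRaden (2008) method 1, allele frequencies computed from the
  genotyped set, monomorphic loci excluded with a logged count; then a
  two-scalar adjustment a + bG matching the mean diagonal and mean
  off-diagonal of A22 (the Christensen-style base-scale tuning that is
  the common software default).
* H-inverse: A-inverse plus the genotyped-block correction
  (alpha G + beta A22)^-1 - A22^-1, with (alpha, beta) = (0.95, 0.05)
  for genomic evaluation and (1, 0) for GWAS.
* Mixed-model equations for y = 1 mu + Z u + e are solved by conjugate
  gradients with a diagonal preconditioner (relative residual 1e-10,
  cap 20,000 iterations); a dense direct solver cross-checks small
  systems.
* REML: the records' marginal model y = 1 mu + g + e with
  var(g) = K_phi sigma2_u needs only the record-block relationship
  K_phi (obtained from the single-step identity
  H_SS = A_SS + A_Sg A22^-1 (Gb - A22) A22^-1 A_gS). One
  eigendecomposition turns the restricted likelihood into a
  one-dimensional profile over h2, solved by bounded scalar
  minimisation (h2 in [1e-6, 1-1e-6]); this is exact REML, verified in
  the tests against a direct slogdet likelihood oracle. Components are
  estimated once per replicate on the full-progeny dataset with progeny
  genotypes in GWAS mode and reused for all of that replicate's GWAS,
  GEBV and EBV runs.

## Weighted single-step GWAS

SNP effects are back-solved from the GEBVs of the genotyped animals,
beta = D W' (W D W')^-1 u_g (Wang et al. 2012), with W centred by twice
the allele frequency of the genotyped set. Because those frequencies
come from the same genotypes, W has zero column sums and W D W' is
exactly singular (null vector 1); the pipeline therefore inverts
2 sum p(1-p) times the tuned/blended G used in H — the same matrix up
to the tuning adjustment, and positive definite — as postGS-style
back-solvers do. Weights are refined once, d_i = beta_i^2 2 p_i(1-p_i)
rescaled to trace m, and the GEBV/back-solve cycle runs exactly twice;
the scan uses the final iteration. Loci fixed or constant-genotype
within the genotyped set are dropped from the scan up front.

Windows are non-overlapping blocks of 20 adjacent loci within a
chromosome (a trailing shorter window is kept and logged); the
percentage of genetic variance per window is the variance of the window
score W_w beta_w across genotyped animals divided by the variance of
the total score W beta, times 100 — variances of scores rather than
sum beta^2 2p(1-p), so LD within windows is accounted for. For QTL
matching, window boundaries are extended to midpoints between adjacent
windows (and to the chromosome ends), so every map position belongs to
exactly one window. trueQTL are the simulated QTL whose containing
window exceeds 1.0% of the genetic variance in the idealised SCEN0 scan
(QTL genotyped alongside the SNPs); power in SCEN1–6 is the fraction of
trueQTL whose containing window exceeds the same threshold. An empty
trueQTL set makes power a missing value for that replicate, excluded
from means with a logged count.

## Scenarios and replication

Scenarios follow the ten-row reference-population design: SCEN1–3
progenies genotyped+phenotyped (full/mid/low tier), SCEN4–6 bulls
genotyped with progenies phenotyped only, SCEN7–9 nobody genotyped
(pedigree BLUP); SCEN0 equals SCEN1 plus the QTL columns. One
population per replicate is simulated at the *maximum* progeny count
and the lower tiers take nested first-k-per-bull subsets, so all
scenarios of a replicate share one population and one trueQTL
reference. Test bulls are genotyped in every genomic scenario and never
phenotyped; bulls are never phenotyped. Accuracy is the Pearson
correlation between TBV and prediction over the test bulls
(zero-variance predictions are recorded as 0 with a flag). Replicates
aggregate to means and SDs (SD missing at n = 1); each replicate's
population is fresh and fully determined by the master seed.

The Goddard (2009) closed form used for the expected-accuracy sanity
check is r = sqrt(1 - lambda/(2N sqrt(a)) ln((1+a+2 sqrt a)/(1+a-2
sqrt a))) with Me = 2 Ne L/ln(4 Ne L), lambda = Me/(h2 ln(2 Ne)),
a = 1 + 2 lambda/N; it ignores marker density, so its accuracy tends
to 1 as N grows.

## Problem sizes

Two built-in profiles share one code path. The *paper-scale* profile
(30 chromosomes, 50,000 SNPs, 50 sires x 3,000 dams, 300 bulls, progeny
tiers 30/15/5, 10 replicates) reproduces the full design and is sized
for long unattended runs. The *desk* profile used by the test suite and
the acceptance script keeps every structural element but scales down:
5 chromosomes x 100 cM, 5,000 SNPs (from 9,000 candidates), 10 sires x
200 dams, 60 bulls, progeny tiers 10/5/2 (600/300/120 phenotyped
progenies), 20 test bulls, historical phase 200 generations at N = 200
with the same bottleneck/expansion shape, 3 replicates. These sizes
were fixed once as the smallest design that still shows the qualitative
orderings clearly.

## What the desk scale does and does not show

The generator emulates the study conditions (demography, genome, trait,
breeding design), not real cattle data: no genotyping error or missing
data, no selection on merit, no overlapping generations or elite-sire
reuse, phenotypes from a single additive trait with Gaussian noise.
Desk-scale results reproduce the qualitative findings — power and
accuracy rise with the number of phenotyped progenies, progeny
genotypes clearly beat bull genotypes for a polygenic trait (nQTL=500),
SCEN0 and SCEN1 agree, pedigree-only accuracy for unphenotyped test
bulls is far below the genomic scenarios, and Ne = 20 retains more LD
than Ne = 100 at every distance. Two desk-scale artefacts are worth
noting. First, the small closed nucleus (effective size ~40) builds
background relatedness quickly, so pedigree half-sib relationships run
above the textbook 0.25 and pedigree-only accuracy, while low, is not
as close to zero as in the full design. Second, bulls carry only 2–10
progeny records each, so the bull-genotype scenarios (SCEN4–6) sit much
closer to the pedigree-only floor than the full-scale design, where
each bull's 30 progenies make its genotype far more informative.
Quantitative levels at desk scale are therefore not comparable to the
full-scale numbers; the orderings are.

## Numerical choices

Haplotypes are uint8; all randomness flows through numpy Generators
seeded from explicit seed sequences, making every run bit-reproducible.
Cholesky factorisations guard against numerically zero pivots and
report singular blends with a hint to use beta > 0; the GWAS-mode blend
adds a 1e-8 ridge. PCG tolerance 1e-10 (relative); REML profile
tolerance 1e-8 in h2. Ties in panel selection cannot occur (continuous
positions); trailing GWAS windows shorter than 20 SNPs are kept as
their own windows rather than merged, keeping the denominator of the
power definition unambiguous.
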