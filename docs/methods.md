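# Methods

## Scope

`expansionload` implements a two-part analysis of how a postglacial range
expansion shapes genetic diversity and deleterious mutation load, modelled on
the population genomics of Coho salmon (*Oncorhynchus kisutch*) but exercised
end-to-end on synthetic data with the same statistical structure:

1. **Demographic inference** from the joint site-frequency spectrum (jSFS) of
   two populations under strict isolation (SI), isolation-with-migration
   (IM), ancient migration (AM) and secondary contact (SC), with genomic
   heterogeneity in both migration rate (barrier loci) and effective
   population size (linked selection).
2. **Expansion-load statistics**: β_ST and candidate-source detection,
   singleton rarefaction, Weir–Cockerham F_ST, Tajima's D, π_N/π_S,
   per-individual recessive and total deleterious load, derived-allele-
   frequency (DAF) spectra, and the distance-gradient regressions connecting
   them.

## Divergence models

All models descend from an ancestral population of size N_ref that splits at
time `t_split` (backwards from the present, in units of 2·N_ref generations)
into daughters of relative size ν1, ν2. Migration is scaled as M = 2·N_ref·m
with the receiving-population convention; it acts on (0, t_split) under IM,
(t_am, t_split) under AM, (0, t_sc) under SC, and never under SI. Exponential
growth adds sizes-at-split ν1₀, ν2₀, interpolated as
ν(t) = ν·exp(t·log(ν₀/ν)/t_split).

Genomic heterogeneity enters as a four-category mixture with product weights:

| category | weight | migration | deme sizes |
|---|---|---|---|
| neutral | P(1−Q) | M12, M21 | ν |
| barrier | (1−P)(1−Q) | me12, me21 | ν |
| linked selection | P·Q | M12, M21 | hrf·ν |
| both | (1−P)Q | me12, me21 | hrf·ν |

The Hill–Robertson factor hrf ∈ (0, 1] rescales **every** deme size of the
affected loci, including the ancestral deme, on the view that linked
selection is a property of the locus, not of an epoch. The independence of
the two heterogeneity processes (product weights) is an assumption; both
choices are isolated in `category_weights` so they can be swapped. `me` is a
free parameter not constrained below M; its barrier interpretation is
semantic.

## Expected jSFS: branch-length Monte Carlo

Expected spectra come from simulating genealogies under the structured
coalescent and accumulating, per branch, the time during which it subtends
(i, j) of the sampled lineages; the expected jSFS cell is proportional to
that mean branch length. Time-varying coalescence rates (exponential growth)
are handled by thinning with segment caps that bound the rate variation per
segment by a factor of two. The engine is numba-compiled; 10⁶ genealogies
for 10 samples take about a second.

Design notes:

* A lineage's subtended counts never change between coalescences, so branch
  lengths are accumulated lazily at merge time (O(1) per event).
* The Monte Carlo seed is **frozen per fit**, making the objective a
  deterministic function of the parameters and therefore comparable across
  optimizer starts; the four mixture categories reuse one seed, which makes
  the nested-model identities (me = M, hrf = 1, t_sc = t_split, P or Q
  degenerate) hold exactly at finite Monte Carlo size without biasing the
  expectation.
* msprime, where installed, is used only as an independent cross-check in
  tests, never as the inference backend.

## Composite likelihood and fitting

The fit maximises a Poisson composite likelihood over unmasked jSFS cells
with the overall scale θ profiled analytically (θ̂ = Σobs/Σmodel); the
monomorphic corners are always masked, and folded spectra are supported
throughout (folding is the default for fitting, being robust to
polarization error). AIC counts only the explicit free parameters of a
variant (θ is profiled): SI = 3, IM = 5, AM/SC = 6; "+2M" adds {P, me12,
me21}, "+2N" adds {Q, hrf}, growth adds {ν1₀, ν2₀}; e.g. SC2N2M+growth = 13.

Optimization is multi-start Nelder–Mead on transformed parameters (log for
positive quantities, logit for proportions and for t_sc/t_split, which keeps
every iterate feasible). Two details matter in practice:

* scipy's default initial simplex (5% per coordinate) is far too small for
  log-space traversal of this rugged surface; each start therefore builds an
  explicit simplex of width ≈0.7 in transformed coordinates and runs a
  second, narrower restart at the round-1 solution;
* the first start is a neutral mid-range point (ν = 1, t = 1, M = 1,
  fractions mid-range), which empirically lands in the dominant basin far
  more reliably than random draws; remaining starts are log-uniform draws
  within bounds. 20 starts are the default protocol; recovery experiments
  in the test suite use 2–3.

Model selection uses ΔAIC with Akaike weights; a comparison is flagged
"ambiguous" when the runner-up's ΔAIC is below 10 (a ΔAIC of exactly 10 is
not ambiguous). The hierarchical protocol fits all 16 constant-size variants
first and adds the two growth parameters only to stage-1 winners (every
variant within ΔAIC < 10 of the best), warm-started at the stage-1 solution;
final estimates come from stage 2.

### Parametric bootstrap

Each replicate resimulates the four category datasets at the point estimates
(category locus counts multinomial in the product weights), sums them into
one jSFS with the data's site count, and refits the same variant. Refits are
warm-started at the point estimates but with **over-dispersed jitter**
(sd 0.7 in transformed coordinates, about a factor of two per parameter):
several parameter combinations (notably contact time × migration rate) form
likelihood ridges that are flat at realistic data sizes, and refits anchored
exactly at the point estimate would understate that uncertainty. Refits also
draw fresh Monte Carlo seeds, so the intervals include the engine noise.
Percentile 95% CIs are reported; failed refits are dropped and counted.

A known limitation of the Monte Carlo objective: with the seed frozen, a
long optimization can partly fit the specific noise realization of the
expected spectrum — a fit that looks as good as the generating parameters
at 800 genealogies per evaluation can trail them by hundreds of
log-likelihood units when both are re-evaluated at several thousand.
Weakly identified combinations (contact time × migration rate trade
against each other) absorb most of that slack, so their point estimates
can be biased towards the interior of the near-flat set and percentile
bootstrap intervals — which inherit the same estimator — can under-cover
those particular parameters at desk-scale genealogy budgets. Raising the
per-evaluation genealogy count shrinks the effect in proportion; the
recovery experiments in the test suite document exactly which parameters
are affected at the budgets used. Well-identified parameters (sizes,
split time, P, Q, hrf) are not materially disturbed.

### Unit conversion

N_ref = θ̂/(4μL) with μ = 8×10⁻⁹ per bp per generation and a 3-year
generation time by default; sizes scale by ν·N_ref, times by 2·N_ref·g
years, migration by m = M/(2·N_ref). The conversion is exactly invertible.

## Statistics

* **He** uses the small-sample-unbiased form (2n/(2n−1))(1 − Σp²); per-SNP π
  is the mean pairwise difference, which coincides with unbiased He at
  biallelic SNPs.
* **Weir–Cockerham θ** is the two-population ratio-of-sums over the per-site
  a, b, c variance components (a: between populations, b: between
  individuals within, c: within individuals).
* **β_ST** is the population-specific coefficient
  β_i = (M_i − M_B)/(1 − M_B), with M_i the within-population allele-matching
  proportion over distinct copy pairs and M_B the mean between-population
  matching, both ratio-averaged over sites; the bootstrap (default 1000
  replicates) resamples loci, which is the natural unit for a
  site-aggregated estimator. Negative values flag candidate ancestral
  populations. Note that for finite samples M_i carries a without-replacement
  correction of order 1/(2n), so two literally identical population tables
  give a small negative β rather than exactly 0.
* **Singletons** are defined dataset-wide (a variant whose minor allele is
  carried by exactly one individual across the whole, subsampled, dataset)
  and attributed to that carrier's population; rarefaction subsamples every
  population to 13 individuals, 200 times, and regional differences are
  tested by pairwise Wilcoxon rank-sum with Benjamini–Hochberg correction.
* **Tajima's D** follows the standard constants (a1…e2); folded spectra are
  accepted since i(n−i) is fold-symmetric.
* **Mantel tests** co-permute rows and columns; with ≤7 labels the
  permutation distribution is enumerated exactly, otherwise 10,000 random
  permutations with the add-one correction.

## Load analysis

* **Polarization**: the ancestral allele is the one homozygous in ≥2
  agreeing outgroups of three, provided it matches a focal allele; agreeing
  outgroups carrying a third allele, two outgroups homozygous for different
  alleles, heterozygous outgroups and missing data all leave the site
  unpolarized (excluded from derived-allele analyses).
* **Degeneracy**: codons are reconstructed strand-aware from the spliced
  CDS; positions are classed 0-fold/2-fold/4-fold (3-fold isoleucine sites
  conservatively as 2-fold). π_N uses 0-fold sites, π_S 4-fold sites, 2-fold
  sites are excluded from both — the cleanest estimator consistent with
  "4-fold degenerate" phrasing. π_N/π_S needs no polarization (folded
  quantity), and the tests assert it is invariant to discarding
  polarization.
* **Deleterious** = nonsynonymous with an externally supplied effect score
  ≤ −2.5 (boundary inclusive). Scores are consumed, never computed.
* **Load**: per individual, N_homo (homozygous derived deleterious), N_het,
  and N_total = 2·N_homo + N_het, an exact integer identity asserted
  everywhere; population/region means; pairwise regional Wilcoxon tests.
* **DAF spectra** per population and category (synonymous / nonsynonymous /
  deleterious); regional spectra are hypergeometrically projected to a
  common sample size (default 100 haploid copies, configurable), which
  preserves expected frequency exactly. Kruskal–Wallis across regions and
  populations on the deleterious DAF.

## Synthetic data

### Two-population datasets

`simulate_dataset`/`gen_two_pop_dataset` share the expected-SFS engine with
the inference code and add only sampling noise: loci are assigned to the
four categories multinomially, and the observed jSFS is a multinomial draw
of S segregating sites from the realized category mixture. The recovery
experiments use S = 50,000 sites over 50,000 loci (one SNP per locus, as in
reduced-representation data) with n1 = n2 = 8 haploid copies.

### Serial-founder range expansion

A forward Wright–Fisher simulation of K demes in a linear array; deme k is
founded at generation k·dt_found by F founders from deme k−1 and grows
logistically (factor `growth_rate` per generation) to capacity N. Each
generation applies migration (conservative swaps between adjacent demes,
Binomial(min(sizes), m_step) pairs), viability selection (fitness 1, 1−hs,
1−s per deleterious locus, multiplicative), then reproduction with mutation.
Loci are biallelic; a derived allele arises only at loci where it is
currently absent metapopulation-wide (no recurrent origin while segregating,
no back mutation), so the reference allele is always truly ancestral and
the simulator provides exact truth for polarization and load.

Default study conditions: K = 8 demes × N = 100 diploids, F = 10,
dt_found = 50, m_step = 0.02 (≈2 migrants per generation between
neighbours), growth_rate = 1.4, L = 1000 neutral + 1000 deleterious loci,
u = 10⁻⁴ per locus per gamete, s = 0.01, h = 0.5 (additive), 600
generations of expansion, 25 diploids sampled per deme, distances
deme-index × 100 km. The source deme is initialised from the neutral
stationary frequency density (∝ 1/p) of a large ancestral pool
(n_ancestral = 2000, 70% of loci polymorphic ancestrally) followed by a
100-generation settling phase: a refugial population inherits predominantly
*rare* variants from its large ancestral population, and this matters —
initialising instead at the N = 100 drift equilibrium hands the expansion
mid-frequency standing variants whose local fixation inverts the expected
heterozygosity gradient.

What the generator reproduces, and what it does not: across replicate
seeds the simulation robustly shows the expansion signatures — recessive
load (mean homozygous-derived deleterious count) increasing with distance
from the source, expected heterozygosity decreasing, and Tajima's D
negative after the expansion. The classic prediction that the **total**
(additive) load stays approximately constant along the expansion axis is a
large-N_e approximation and is *not* reliably reproduced at this desk
scale: with N = 100 the front demes' fitness loss is real expansion load,
per-deme mean-load deviations are spatially autocorrelated (neighbouring
demes share surfing episodes), and the naive 8-point OLS t-statistic for
the total-load slope exceeds |t| = 2 far more often than its nominal rate
even though the mean slope is near zero and sign-mixed. Configurations
that push the total-load clause towards flatness (strong migration, long
recovery after an early completed expansion) destroy the He and D
gradients first. The end-to-end test suite asserts the constancy
check anyway, as a permanent record of this limitation, and it is expected
to fail at this scale; the other three checks pass. Conclusions about *real* data should rely on the sign/regression
logic, not on per-replicate t-statistics at N = 100.

### Outgroup panels

Three outgroup columns per site: missing with probability q, homozygous for
the wrong focal allele with probability e, otherwise homozygous ancestral —
giving closed-form mis-polarization rates for testing (≥2 agreeing wrong
outgroups).

## Numerical and edge-case policy

* Missing genotypes use a sentinel (−9), never 0; all boundary rules
  (call rate < 60%, depth < 7, Ho > 0.60, missing > 5%, call rate < 95%,
  score ≤ −2.5, ΔAIC < 10) are asserted at their exact boundaries in tests,
  with integer-arithmetic comparisons where float rounding could flip a
  boundary case.
* SNP thinning keeps one uniformly chosen (seeded) SNP per locus.
* Model cells that are zero where data are observed are floored at 10⁻⁶ of
  the smallest positive cell with a warning.
* Monomorphic F_ST, π_S = 0 ratios, empty DAF categories and populations
  below the rarefaction size degrade to NaN/skip with warnings rather than
  errors; genuinely unusable configurations (both or neither input source,
  all individuals filtered, single population for β_ST) raise.
* Every stochastic routine takes an explicit seed; pipeline outputs embed
  the seed and a config hash, and reruns are bit-identical.

## Problem sizes in the shipped experiments

The test suite and the acceptance script run everything at desk scale,
chosen as the package's own study conditions: 10⁵–10⁶ genealogies for the
engine closed-form checks; 50k-SNP jSFS datasets with 2–3 optimizer starts
and 300–800 genealogies per likelihood evaluation for recovery and model
selection; 100 bootstrap refits; 12–30 replicate expansion simulations.
The analysis drivers under `analysis/` use the same sizes with a few more
optimizer starts.
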