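# expansionload

Joint-SFS demographic inference with heterogeneous migration and linked
selection, plus deleterious expansion-load analysis, for two-population
divergence histories over reduced-representation SNP data.

## The problem

Postglacial range expansions leave two intertwined signatures in a species'
genome. Demographically, populations that diverged around glacial cycles mix
signals of isolation, secondary contact, barriers to gene flow, and linked
selection — all of which distort the joint site-frequency spectrum (jSFS)
that inference methods fit. Genetically, serial founder events at the
expansion front weaken purifying selection, so deleterious variants surf to
high frequency: the *expansion load*. This package — built around the
population genomics of Coho salmon (*Oncorhynchus kisutch*), a Pacific
salmon whose North American range expanded northward from a southern
refugium — implements both analyses as a tested, reusable library plus a set
of narrative analysis scripts, exercised end-to-end on synthetic data with
the same statistical structure.

## The models and statistics at the core

**Divergence models.** Two populations of relative sizes ν₁, ν₂ split from
an ancestral population (N_ref ≡ 1) at time T_split (units of 2·N_ref
generations); gene flow M = 2·N_ref·m is absent (SI), continuous (IM),
ancient only (AM, on (T_am, T_split)) or secondary-contact only (SC, on
(0, T_sc)). A proportion 1−P of loci exchange at reduced effective rates
(me₁₂, me₂₁) — barriers to gene flow — and a proportion Q experience linked
selection, modelled as a Hill–Robertson rescaling of every deme size by
hrf ∈ (0, 1]. Expected spectra come from a numba-compiled branch-length
Monte Carlo under the structured coalescent; fitting maximises a Poisson
composite likelihood with the scale θ profiled out, models are ranked by
AIC (ΔAIC < 10 = ambiguous), uncertainty comes from a parametric bootstrap,
and θ̂ converts to demographic units via N_ref = θ̂/(4μL) with μ = 8×10⁻⁹
and a 3-year generation.

**Load statistics.** Ancestral alleles are called from three outgroup
genomes (homozygous in ≥2 agreeing outgroups, matching a focal allele);
deleterious = nonsynonymous with an external effect score ≤ −2.5; per
individual the recessive load is the count of homozygous-derived deleterious
genotypes N_homo and the total load is N_total = 2·N_homo + N_het. π_N/π_S
contrasts 0-fold against 4-fold degenerate sites. Diversity (Ho, unbiased
He, π), Weir–Cockerham F_ST, the population-specific β_ST (negative values
flag candidate ancestral populations), dataset-wide singletons under
rarefaction, Tajima's D, Mantel tests and the distance-gradient regressions
complete the toolkit. A forward Wright–Fisher simulator of a serial-founder
expansion with deleterious mutations generates every input — so the whole
pipeline runs, and is tested, offline.

## Worked example

```bash
python analysis/01_simulate_expansion.py   # inputs -> scratch/expansion_inputs/
python analysis/02_diversity_gradients.py  # tables -> results/expansion/
python analysis/03_deleterious_load.py
```

The default scenario (8 demes × 100 diploids, 10 founders per wave, s = 0.01
on 1000 deleterious loci, 600 generations) prints, for seed 20260925:

```
after filtering: 200 individuals x 2000 sites
     response     slope  intercept         r       r2            p  n
           He -0.000013   0.039414 -0.745902 0.556370 3.359600e-02  8
         beta  0.000290   0.131347  0.745902 0.556370 3.359600e-02  8
fst_vs_source  0.000473   0.066712  0.997823 0.995651 4.242370e-07  7
    tajimas_d -0.000634   0.122076 -0.723308 0.523175 4.257607e-02  8
Mantel FST x distance: r = 0.977, p = 0.0001
```

Heterozygosity falls and β_ST rises with distance from the source (r ≈ 0.75
either way), F_ST against the source deme grows almost perfectly linearly,
and F_ST correlates with geography (Mantel r = 0.98) — the isolation-by-
distance fingerprint of a one-source colonisation. The load script then
reports

```
1000 deleterious sites; 58.9% of deleterious genotypes are heterozygous
response   predictor subset      slope  intercept         r       r2        p  n
  n_homo distance_km    all   0.004729  14.210000  0.778762 0.606470 0.022779  8
 n_total distance_km    all   0.008805  51.403333  0.706579 0.499253 0.050073  8
 pin_pis distance_km    all   0.000267   0.417003  0.780883 0.609778 0.022168  8
 pin_pis   tajimas_d    all  -0.211046   0.489388 -0.541216 0.292915 0.165969  8
```

i.e. the homozygous (recessive) deleterious burden climbs by ≈0.47 genotypes
per 100 km of expansion (p = 0.02), π_N/π_S rises away from the source and
falls with Tajima's D — expansion load emerging from the founder-event
cascade. Scripts 04–06 simulate a 50,000-SNP jSFS under secondary contact
with heterogeneous migration (P = 0.6) and linked selection (Q = 0.4,
hrf = 0.2) and recover the generating model decisively:

```
SI       logL =    -4116.2  AIC =     8238.3
IM       logL =    -2409.2  AIC =     4828.5
AM       logL =    -3594.2  AIC =     7200.4
SC       logL =    -2332.2  AIC =     4676.5
SC2N     logL =     -662.1  AIC =     1340.3
SC2M     logL =     -559.0  AIC =     1136.0
SC2N2M   logL =     -472.0  AIC =      965.9
stage 2 (SC2N2M+g): logL = -402.4, AIC = 830.8 (stage 1 best AIC 965.9)
```

Every added layer — secondary contact, linked selection (2N), barriers
(2M), growth — buys a decisive AIC improvement, exactly the hierarchical
ladder the inference is designed to climb; script 06 then brackets the
generating parameters with a 100-replicate parametric bootstrap and
converts the fit to demographic units (N_ref, years, per-generation m).

## File formats

* **VCF v4.2** (biallelic SNPs, GT and optional DP) in and out via htslib.
* **Population map**: TSV with header `sample population region lat lon
  distance_km`.
* **jSFS**: flat text grid with a first line `n1 n2 folded` (haploid sample
  sizes and a 0/1 fold flag) followed by the (n1+1)×(n2+1) count rows;
  round-trip tested.
* **Outgroup table**: TSV `chrom pos og1 og2 og3` with two-letter genotypes
  or `NN`; **score table**: TSV `chrom pos score`; CDS annotations as
  GFF3 + FASTA.

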