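# galaxpop

Comparative mitochondrial population genetics for co-distributed fish
species, built around one question: **are the genetic differences between
two species sampled in the same river basin larger than coalescent
stochasticity alone can produce?**

The motivating system is a pair of galaxiid fishes in a southern Chilean
river basin — the diadromous *Galaxias maculatus* (high mtDNA diversity,
strong zone structure, deeply divergent haplogroups) and the
freshwater-resident *G. platei* (low diversity, weak structure) — but
every component works on any rectangular alignment of mtDNA (or other
non-recombining haploid) sequences with per-sample zone metadata.

## What it computes

**Diversity and structure** (per zone and basin-wide): segregating sites
*S*, haplotype count *K*, Nei's unbiased haplotype diversity
*Hd = n/(n−1)·(1 − Σp²)*, nucleotide diversity *π* per site and per
locus, mismatch distributions, pairwise Φ_ST with permutation
significance, island-model gene flow *Nm = (1/F − 1)/2* (haploid,
maternal marker), and three-level AMOVA (Φ_CT, Φ_SC, Φ_ST) over
alternative zone groupings with level-appropriate permutation schemes.

**Neutrality tests**: Tajima's *D* and Fu's *Fs* (Ewens sampling formula
with log-space Stirling numbers, so *Fs* is computable at *n* in the
hundreds), with significance from constant-size coalescent simulation.

**The coalescent-stochasticity null test**: a constant-size Kingman
coalescent simulator with finite-sites mutation drives a two-step
procedure —

1. *Calibration*: simulate 1,000 samples of the low-diversity species'
   design (*n* = 72, *L* = 786 bp, *N* = 10,000) with
   μ ~ U(10⁻⁸, 10⁻⁶); fit a linear τ = 0.05 quantile regression of *S*
   on μ; take μ\* where the fitted 5% lower envelope passes through the
   empirical *S* = 34 — the largest rate at which ~5% of simulated *S*
   still fall at or below the observation.
2. *Null test*: simulate 10,000 replicates of the high-diversity
   species' design (*n* = 217, *L* = 505 bp, same *N*) at μ\* and
   report, for each of *S*, *K* and the mean number of pairwise
   differences π̄, the fraction of replicates at or above the empirical
   value (one-sided empirical p-values).

## Worked example

```bash
galaxpop synth --preset two_species --outdir demo --seed 1
galaxpop diversity --fasta demo/speciesA.fasta --meta demo/speciesA.tsv --out demo/div.tsv
galaxpop nulltest --reps 10000 --seed 1 --out demo/nulltest.json
```

The diversity table for the synthetic high-diversity species prints one
row per zone plus a basin row (columns n, S, K, Hd, π):

```
 species  zone   n   S  K     Hd  pi_site  pi_locus
speciesA    Z1  77 131 35 0.9381  0.05468    27.614
speciesA    Z2  42 127 27 0.9582  0.05687    28.721
speciesA    Z3  56 119 24 0.9383  0.05602    28.292
speciesA    Z4  50 119 28 0.9608  0.05599    28.273
speciesA basin 225 156 60 0.9574  0.06325    31.939
```

and the null-model test prints the calibrated null against the empirical
summaries of the real high-diversity species (S = 116, K = 152,
π̄ = 25.1):

```
                statistic  null_min  null_mean   null_max  observed  count_ge  p_value  exceeds_stochasticity
        segregating sites 14.000000      43.00 110.000000     116.0         0   0.0000                   True
               haplotypes 11.000000      26.07  43.000000     152.0         0   0.0000                   True
mean pairwise differences  0.931217       7.46  37.180492      25.1        26   0.0026                   True
```

Read: across 10,000 calibrated null replicates no simulation reached the
observed 116 segregating sites or 152 haplotypes, and only 26 of 10,000
reached π̄ = 25.1 (p = 0.0026) — the interspecific contrast exceeds what
coalescent stochasticity can generate under a shared demographic model.

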