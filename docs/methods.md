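# Methods

This note documents the models behind `galaxpop`, the parameter choices
that matter, the numerical decisions, and what the synthetic-data tests
do and do not establish about real data.

## Summary statistics

All statistics operate on a rectangular alignment over `{A,C,G,T,N,-}`.
IUPAC ambiguity codes other than `N` are collapsed to `N` on input;
control-region chromatograms commonly contain them and no statistic here
distinguishes the codes. Two missing-data policies are available:

* **complete deletion** (default): any site with a gap or `N` in any
  sequence is dropped for every statistic. This is the transitive
  policy, so haplotype identity is always judged on this site set.
* **pairwise deletion**: each sequence pair is compared over its
  mutually unambiguous sites (the convention of distance-based
  structure analyses). Pairs with no mutually usable site are excluded
  from π and the mismatch histogram with a warning.

The two policies coincide on gap-free data — in particular on everything
the simulator produces. On real alignments they differ slightly; this is
the main dialect axis when comparing against numbers produced by other
programs, and the reason the empirical-reproduction tolerances are wider
than printing precision.

Definitions: *S* counts usable sites with ≥2 distinct non-missing bases;
*K* is the number of sequence identity classes; *Hd* uses Nei's
small-sample correction *n/(n−1)·(1 − Σp²)*; π is reported per locus
(mean pairwise difference count, the quantity the mismatch distribution
averages) and per site (π_locus divided by the usable length). Keeping
both in one record avoids the unit confusion that arises when per-site
values (~10⁻²) and per-locus values (~10¹) are quoted side by side.

## Φ-statistics and AMOVA

"F_ST" on sequence data is implemented as the distance-based Φ_ST from
an analysis of molecular variance on pairwise difference counts (the
default treatment of mtDNA in the standard packages). Distances are raw
counts of differing usable sites — no substitution-model correction —
consistent with the mismatch analysis; corrected distances are out of
scope.

The three-level decomposition follows the classical sums-of-squared-
distances construction with unequal-size coefficients: SSD(total),
SSD(within populations) and SSD(within groups) yield mean squares and
variance components σ²_a (among groups), σ²_b (among populations within
groups), σ²_c (within populations), and

Φ_CT = σ²_a/σ²_T, Φ_SC = σ²_b/(σ²_b+σ²_c), Φ_ST = (σ²_a+σ²_b)/σ²_T.

Negative components are retained rather than truncated, so percentage
decompositions can be slightly negative while still summing to 100 —
matching how such tables are conventionally printed. When total variance
is zero the Φ values are reported as 0 with a `degenerate` flag.

Permutation schemes are level-appropriate: individuals among all
populations for Φ_ST, individuals among populations within their group
for Φ_SC, whole populations among groups for Φ_CT. p-values are raw
proportions of permuted statistics ≥ the observed one, with ties counted
toward the tail — a conservative convention; on data with many
duplicated sequences (hence massively tied Φ values) permutation
p-values are visibly conservative rather than uniform, which is a
property of tied test statistics, not an error. Note that Φ_CT
significance below 0.05 is *unattainable* when few populations are
permuted among groups (four zone-populations in two groups admit only
three distinct splits); group-level testing needs locality-level
populations, which is why the synthetic metadata assigns several
localities per zone.

Gene flow uses the haploid island-model inversion Nm = (1/F − 1)/2,
appropriate for a maternally inherited marker; F ≤ 0 maps to infinite
flow and is printed as `inf`.

## Neutrality tests

Tajima's *D* uses the standard 1989 constants; it is undefined (NaN, not
zero) at S = 0. Fu's *Fs* is ln(S′/(1−S′)) with
S′ = Pr(K ≥ k_obs | θ̂ = π̄) under the Ewens sampling formula. The
unsigned Stirling numbers of the first kind that the formula needs are
computed once per *n* in log space via the recurrence
|s(n+1,k)| = n|s(n,k)| + |s(n,k−1)| with log-sum-exp, so *Fs* is exact
(to double precision) at sample sizes in the hundreds where direct
factorial arithmetic overflows. The pmf normalisation is verified to
1e−9 up to n = 250.

Significance comes from constant-size coalescent simulation conditioned
on θ̂ = π̄ (not on S — the two conventions differ slightly and the
conditioning choice is documented here precisely because reference
programs do not state theirs). Both statistics are tested against the
lower tail, the direction a sudden expansion pushes them. Null
replicates with S = 0 (D undefined) or K = 1 (Fs undefined) are excluded
from the corresponding tail count.

## The coalescent simulator

A single panmictic population of constant size. While k lineages
remain, the next coalescence is exponential with rate C(k,2)/N_e
generations (continuous time, not discrete Wright–Fisher); merging pairs
are uniform. Scaling: μ is per site per generation; the default
`haploid` scaling sets N_e = N (mtDNA, female effective size), giving
θ_locus = 2NμL; a `diploid` option (N_e = 2N) exists. Crucially, the
calibration step absorbs the scaling choice — μ* adjusts so that the
induced θ matches the empirical S — so downstream null-test results are
robust to it.

Mutation is finite-sites and Jukes–Cantor-like: branch counts are
Poisson(branch length × μL), each mutation hits a uniform site and
replaces the current base with one of the three others uniformly;
recurrent and back mutations are possible. At the calibrated
θ ≈ 7–13 on 505–786 bp loci, the finite-sites deficit relative to
infinite-sites closed forms is well under the Monte-Carlo noise; the
simulator's means of S, π and K are tested against the Watterson, Tajima
and Ewens expectations within 3 standard errors (plus a 2–3% finite-site
allowance), and its S distribution is checked against an independent
coalescent simulator (msprime) by two-sample KS test. No
transition/transversion bias or rate heterogeneity is modelled: those
belong to phylogenetic dating analyses outside this package's scope.

The per-replicate summary path never materialises full sequences: only
sites hit by ≥1 mutation are propagated down the genealogy, and S, K and
π are computed from allele counts at those sites. The FASTA path and the
sparse path are tested to agree exactly.

## Mutation-rate calibration

The sweep draws μ ~ U(10⁻⁸, 10⁻⁶) — bounds that bracket the rate needed
to reach S = 34 on the 72 × 786 bp design at N = 10⁴ — and simulates one
sample per draw. The τ = 0.05 conditional quantile of S given μ is fit
as a straight line by exact minimisation of the pinball loss, posed as a
linear program (split residuals, HiGHS solver). The LP route is
preferred over iteratively reweighted fitting because it is exact and
stable on degenerate inputs (noiseless or near-noiseless sweeps); the
tests cross-check it against an independent quantile-regression
implementation on noisy data.

μ* solves `intercept + slope·μ = S_target`, i.e. the largest mutation
rate at which about 5% of simulated S values still fall at or below the
target. Read literally, "the highest rate producing at least 5% of S
values ≥ target" has no maximum (that fraction increases with μ); the
lower-envelope reading is the only self-consistent one and is also the
conservative choice — μ* exceeds the mean-regression solution, widening
the null and making it *harder* for empirical values to look extreme. A
mean-regression alternative (`fit_kind="mean"`) is provided for
sensitivity analysis. Calibration is validated by parameter recovery:
fresh simulation at μ* yields Pr(S ≤ 34) = 0.05 ± 0.02.

The Spearman correlation between μ and S across a 1,000-replicate sweep
is ≈ 0.9 (measured 0.896 at 20,000 replicates); the coalescent's own
variance in S bounds it there, which is exactly why the calibration uses
a regression over the whole sweep rather than inverting single
simulations.

## The stochasticity null test

10,000 replicates of the high-diversity species' sampling design
(n = 217 sequences, L = 505 bp, N = 10,000) at μ*. For each statistic
the report gives null min/mean/max, the count of replicates ≥ the
empirical value, and the raw proportion p = count/reps (ties toward the
tail, no +1 correction — matching the convention in which 20 extreme
replicates out of 10,000 print as p = 0.002). Empirical values for the
unpublished 217-sequence subset are accepted as numbers
(S = 116, K = 152, π̄ = 25.1 by default); the pipeline equally computes
them from a user-supplied alignment, in which case the (n, L) design is
checked against the null's unless explicitly overridden.

Type-I error of the procedure is verified by drawing "empirical" data
from the null itself: the flag rate matches α within binomial error.
The full pipeline (sweep → fit → μ* → null → comparison) is
bit-reproducible from one master seed via independent child streams.

Typical full-scale output (seed 1): null mean S ≈ 43, null mean K ≈ 26,
p(π̄ ≥ 25.1) ≈ 0.0026 — computed in well under a minute on one CPU, so
no scale reduction is applied anywhere in the pipeline.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
with the package's own simulator:

* `make_panmictic` — one coalescent sample split arbitrarily into
  zones: the null case (between-zone Φ_ST centred on 0).
* `make_structured` — haplogroup founders placed a specified number of
  mutational steps apart at distinct sites of a random ancestral
  sequence (infinite-sites placement, so the separation between
  consecutive founders is exact when within-haplogroup θ = 0); per-zone
  samples drawn multinomially across haplogroup-specific coalescent
  pools. Founders separated by zero steps are the same haplogroup and
  are merged (weights add), so zero divergence with equal weights
  reduces *exactly* to the panmictic generator.
* The `basin_like` preset: four zones of 77/42/56/50 samples, 505 bp,
  three haplogroups at 25 and 23 mutational steps, zone-differentiated
  mixing (zones 1–2 dominated by one haplogroup, zones 3–4 by another),
  within-haplogroup θ = 8. The θ and mixing weights were chosen once so
  the preset hits its design targets: sampled Hd near 0.95, most
  molecular variance within populations (as in the real basin tables),
  and >90% power for detecting the zone-pair grouping at site-level
  AMOVA. Its per-site π (~0.05–0.08) runs above the real basin value of
  ~0.027: a constant-size coalescent must use a larger θ to reach the
  observed haplotype richness than the real, historically expanding
  population needed. Metadata assigns three localities per zone
  (round-robin) so site-level AMOVA is possible.
* `make_two_species_fixture` — the `basin_like` species plus a
  low-diversity panmictic companion (θ = 2.6 on 786 bp, zone sizes
  46/49/31/10), written as FASTA + TSV, byte-stable per seed.

What passing synthetic tests show: the statistics, permutation
machinery, calibration and null test behave correctly on data with the
assumed structure (panmixia, zone-partitioned haplogroups, contrasting
θ). What they do not show: correctness of any demographic inference on
real data — real control regions carry expansion signals, rate
heterogeneity and missing data patterns the generator deliberately
omits; empirical reproductions (basin Hd, Tajima's D, Fu's Fs) therefore
require the deposited sequences.

## Numerical and edge-case conventions

* Undefined statistics return NaN (D at S = 0, Fs at K = 1), never 0.
* Degenerate inputs (n < 2, no usable site, a population below minimum
  size, empty nulls) raise typed errors rather than returning values.
* Zero total molecular variance: Φ values report 0 with a flag.
* μ* falling outside the sweep bounds is clipped with a warning and the
  clipping is recorded in the calibration result.
* All simulation entry points accept either an integer seed or a numpy
  Generator; every report records the seed it was run with. Problem
  sizes used by tests (e.g. 1,500–2,000 replicates for moment checks,
  120 fixtures for uniformity checks) are chosen to keep Monte-Carlo
  error well below the asserted tolerances.

## Known limitations

* Single population, constant size: no growth, migration,
  recombination or multi-deme models — by design, since the null being
  tested is "coalescent stochasticity only".
* Finite-sites uniform mutation without transition bias; at the
  calibrated θ this is indistinguishable from infinite sites, but at
  much higher θL the S and K means fall measurably below the classical
  expectations.
* AMOVA percentage tables from the real study are not reproducible at
  zone level because the published grouping significance relies on the
  unpublished locality-level sample partition; the implementation is
  instead validated against a brute-force variance-component oracle and
  its internal Φ consistency relations.
* Fu's Fs evaluates the Ewens distribution at θ̂ = π̄, the standard
  plug-in; it is not a likelihood-ratio quantity and inherits the
  plug-in's bias for very small samples.
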