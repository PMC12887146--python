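# Methods

## The model

`heatnorm` analyses test-day milk yield as a function of two trajectories:
days in milk (DIM, lactation stage) and the temperature-humidity index
(THI, heat load). A record of cow *l* is modelled as

    y = FIXED + Σₙ βₗₙ ωₙ(d) + Σₙ γₗₙ ωₙ(d) + Σₙ δₗₙ ωₙ(t) + Σₙ εₗₙ ωₙ(t) + e

where ωₙ are orthonormal Legendre polynomials of the standardised
covariate, order 3 for DIM (intercept, linear, quadratic, cubic) and order
1 for THI — the THI part is a classical reaction norm with a level (δ₀)
and an environmental-sensitivity slope (δ₁, heat tolerance). β and δ are
additive genetic coefficients, γ and ε permanent-environment (PE)
coefficients, e a residual.

The (co)variance structure is

    var(additive) = K ⊗ G₀ (6×6 joint), var(PE) = I ⊗ P₀ (6×6),
    var(e) = diag σ²ₑ,o over six DIM×THI classes,

with K the pedigree numerator relationship matrix **A** (pedigree-only
evaluation) or the single-step hybrid matrix **H** combining **A** with
the genomic relationship matrix **G** of the genotyped subset
(H⁻¹ = A⁻¹ + [0 0; 0 G_b⁻¹ − A22⁻¹]). G uses VanRaden centring
Z = M − 2p with optional per-SNP weights D, normalised by Σ2pᵢ(1−pᵢ), and
is blended as G_b = 0.95 G + 0.05 A22 before inversion to guarantee
invertibility; allele frequencies come from the current genotyped sample.

Fixed effects: contemporary group (herd-year-month; carries the model
intercept), milking-frequency × DIM-class (treatment-coded), age at
calving (linear + quadratic on a standardised scale centred at 41 months),
DIM linear/quadratic/cubic nested within herd × two-calving-year classes,
and a THI linear term nested within DIM class.

### Class grids

* DIM classes: 50-day grid 5–54, 55–104, 105–154, 155–204, 205–254,
  255–305 (class 6 spans 51 days).
* THI classes: nearest even integer, clamped into 60…80 — 11 classes.
  Ties at odd integers round half up (61 → 62). Values outside [60, 80]
  fall into the boundary classes rather than being discarded (the first
  and last classes are open-ended).
* Residual classes: DIM groups {1}, {2–4}, {5–6} × THI groups
  {60–62}, {64–80}, numbered row-major 1..6.

### THI

THI = 1.8·T + 32 − (0.55 − 0.0055·RH)(1.8·T − 26), with T dry-bulb
temperature (°C) and RH relative humidity (%). The daily THI is the mean
of the THIs at the three standardised observation times (09:00, 15:00,
21:00) — the mean of per-time THIs, not the THI of mean T/RH, because the
index is bilinear in T×RH. Each test-day record receives the mean daily
THI over a six-day window (test day plus five preceding days) at the
herd's reference station. The model regresses on the record's THI class
value (the class scale is the standardisation range 60–80).

### Record editing

Sequential single passes, in this order: DIM restricted to [5, 305];
lactation rules (duration ≥ 90 d, first test before DIM 75, ≥ 4 tests,
age at calving 22–60 months, ≥ 1 known parent); contemporary-group
formation (herd-year-month) and removal of CGs with fewer than four
distinct animals; removal of records beyond 3.0 SD from their CG mean
(population-SD convention, mean/SD from the input values, single pass;
singleton CGs retain their record and are flagged). A consequence of the
population-SD convention: a lone outlier can only exceed 3 SD in a CG of
at least 12 records, since the largest one-point z-score among n values
is (n−1)/√n.

## Estimation

Variance components are estimated by Gibbs sampling (own numba kernel):

* location effects — fixed effects by scalar updates, each animal's
  6-vector (additive, then PE) as a joint 6×6 block draw from its full
  conditional, which resolves the within-animal correlation between the
  DIM and THI intercepts;
* two exact likelihood-invariant Gibbs moves that fix the two flat
  directions of this model: (a) a recorded animal's additive and PE
  coefficient vectors enter the records only through their sum, so their
  split is resampled per animal from the prior conditional (additive
  coupled to relatives through K⁻¹); (b) the DIM and THI trajectory
  intercepts enter only through their sum, so the population-wide split
  is resampled from its prior conditional, which has scalar precision
  c = G₀⁻¹[0,0] + G₀⁻¹[4,4] − 2G₀⁻¹[0,4], local means and covariance
  K/c (a dense Cholesky of the relationship covariance is used; the move
  can be disabled for very large pedigrees). Without these moves the
  effective sample sizes of the level-variance components fall below ~20
  at the default chain lengths;
* the joint additive and PE 6×6 matrices from inverse-Wishart full
  conditionals (scales Θ'K⁻¹Θ + S₀ and Θ'Θ + S₀);
* the six residual variances from scaled inverse-χ² full conditionals.

Priors are weakly informative: inverse-Wishart with the minimal proper
degrees of freedom (dim + 2 = 8) and diagonal scale 0.1·var(y)·I; residual
scale 0.5·var(y) with 4 df. A sample retained at iterations
burn-in + thin, burn-in + 2·thin, …, so a 1,000,000-cycle chain with
600,000 burn-in and thinning 100 keeps exactly 4,000 samples.

The two trajectory intercepts β₀ and δ₀ are confounded in the mean (both
enter every record as 0.7071·coefficient); they are identified only
through the covariance structure and the priors, so their individual
posteriors are wide and mix slowly. This is deliberate: the model keeps
both intercepts exactly as the covariance structure prints them. Retained
samples are monitored with Geweke z-scores (first 10% vs last 50%,
spectral variance via the initial-positive-sequence estimator) and
effective sample sizes (autocorrelation sum truncated at the first
negative consecutive pair). Non-positive-definite proposals are guarded
with escalating diagonal jitter.

Solutions at fixed components (`solve_mme`) come from Henderson's
mixed-model equations solved by diagonally preconditioned conjugate
gradients to relative residual 1e-8 (sparse direct fallback).

## Derived quantities

Variance surfaces evaluate σ²(i,j) = φ_d'G_dim φ_d + φ_t'G_thi φ_t +
2 φ_d'G_cross φ_t at DIM class midpoints (29.5, 79.5, 129.5, 179.5,
229.5, 280) and the 11 even THI values; heritability divides the additive
cell by additive + PE + residual-class variance. Posterior summaries of
surfaces and of derived scalars (level-slope correlation, slope/level
ratio) average per-sample values, not ratios of means, with 95% HPD
intervals from per-sample evaluation — this convention explains small
rounding gaps when recomputing a correlation from a table of posterior
means.

Breeding values: GEBV(d, t) = [φ(d) | φ(t)]·α̂; the 305-day value at a THI
of interest sums the 301 daily values d = 5..305 (linear in α̂, so it also
equals 301 × the GEBV at the mean φ(d) row). Sire summaries rank bulls
with ≥ 10 recorded daughters by the pedigree-based 305-day value at the
thermoneutral class (THI 72) and report Pearson correlations between
pedigree and genomic 305-day values per THI class.

Forward validation removes all test-day records from the cutoff year
(2010) onward, re-solves with the variance components from the complete
data (never re-estimated), and regresses complete-data 305-day values on
reduced-data predictions of the youngest genotyped animals per THI class:
slope b₁ indicates bias, accuracy r = √r² carries the correlation's sign.
All post-cutoff records are removed for every animal (the literal
reading), and "youngest" means latest birth date with ties broken by id.

## Weighted single-step GWAS

SNP effects for the heat-tolerance slope are back-solved from the
genotyped animals' δ̂₁: û = D Z' G_b⁻¹ a_g / Σ2pᵢ(1−pᵢ). Weights iterate
as dᵢ ∝ ûᵢ²·2pᵢ(1−pᵢ), rescaled to sum to the SNP count; each iteration
rebuilds the weighted G, re-solves the mixed-model equations under H⁻¹
and back-solves again (two iterations by default — the first is the
classical unweighted analysis). Five-SNP windows slide by one SNP within
chromosomes; a window's share is Var(Z_w û_w)/Var(Z û)×100 over the
genotyped animals (the denominator is the genomic slope variance —
"total genetic variance" is not defined more precisely anywhere we could
follow, and this choice makes shares self-normalising). Windows above
1.0% are merged when overlapping, and genes whose span intersects the
region ± 200 kb (closed intervals, 1-based inclusive coordinates) are
attached. BED input (0-based half-open) is converted on reading.

## The synthetic-data generator

The generator emulates the study conditions the pipeline assumes:

* multi-herd structure (six herds), monthly test days (30-day intervals,
  first test at DIM 5–20, so ~10 tests between DIM 5 and 305);
* an AI-style breeding design: each generation is sired by a limited
  number of service sires (10 by default), producing the large paternal
  half-sib families that real progeny-tested populations carry — and
  without which the additive vs permanent-environment partition of the
  intercept variance is likelihood-flat (verified against a dense REML
  oracle);
* seasonal station weather built by inverting the THI equation from a
  target THI profile: a warped sinusoid placing THI 70 at the 30th
  percentile, so the windowed THI spans roughly 60–80 with ~70% of test
  days above 70 (the heavy-hot distribution of the source herds); optional
  per-herd climate offsets, and an optional warming trend;
* true coefficients drawn by pedigree gene flow: founders MVN(0, G₀),
  offspring = parent mean + Mendelian deviation with variance
  ½(1 − (F_s + F_d)/2)·G₀; PE i.i.d. per recorded cow; optionally the
  additive coefficients are SNP-driven (a = Z U, "genomic truth");
* gene-dropped genotypes (founder alleles Bernoulli(p), p ~ U(0.05, 0.5);
  offspring alleles drawn from the parents), 5 chromosomes, no LD beyond
  cosegregation; the genotyped subset takes the youngest animals first;
* records assembled exactly from the analysis model, with CG effects
  N(0, 1), a small age polynomial, herd-period DIM curves, negative THI
  slopes in the fixed part, and class-specific residuals.

True (co)variances default to the published reaction-norm posterior means
for the THI blocks (additive level 1.65, slope 0.17, covariance −0.19;
PE 2.98/0.01/0.11 kg²) with DIM blocks and residual classes (2.6–3.5 kg²)
of plausible magnitude for test-day milk yield in dairy buffalo (~8 kg/day
mean yield).

What the generator does **not** emulate: linkage disequilibrium and
genetic maps, selection across generations, multi-breed structure,
culling/missingness patterns, or lactations beyond the first. Passing
tests therefore demonstrate internal statistical correctness of the
pipeline under its own assumptions, not performance on real data.

### Study scenarios and problem sizes

All simulation studies are scaled down to run on a single CPU:

* **Recovery study** — default scenario: 100 founders × 2 generations
  (300 animals), ~150 recorded cows, ~1,500–1,800 records; chains of
  20,000 cycles (10,000 burn-in, thinning 10). Twenty replicates check
  that the true THI-block variances fall inside their 95% HPD intervals.
* **Validation study** — `validation_study_scenario`: 150 founders × 2
  generations, genomic-truth coefficients, 90% genotyped, herd climates
  offset by (−5, −5, 0, 0, +5, +5) THI with paternal families nested in
  herds (weak pedigree connectedness across regions, as across the three
  source states), 150 SNPs standing in for the effective number of
  independent genome segments, slope variance raised to 1 kg² so slope
  differences are expressed at this size, 250 validation animals. This
  design reproduces the direction of the published stability finding on
  average (pedigree accuracy ranges exceed genomic ones by ~0.02 with a
  replicate SD of ~0.035), but the binarised replicate-level comparison
  remains noisy; see the test suite for the exact check.
* **Mapping study** — `simulate_qtl_slope_dataset`: 600 unrelated
  genotyped cows, 1,000 SNPs, one QTL carrying 20% of the slope genetic
  variance, slope variance 1 kg², test days every 20 days. The population
  was sized so that the planted window is recoverable with the ≥ 90%
  frequency the design calls for.

## Numerical choices and degenerate inputs

* Legendre rows error outside the standardisation range (DIM [5, 305],
  THI [60, 80]); surfaces and 305-day sums use the same ranges.
* `genotype_qc` evaluates all marker filters (unmapped, duplicated
  position, non-autosomal, call rate < 0.90, MAF < 0.05, |observed
  heterozygosity − 2p(1−p)| > 0.15) on the raw input statistics and
  applies them jointly, so the survivor set is independent of filter
  order; the sample filter keeps call rates > 0.90.
* Sample-centred Z satisfies Z'1 = 0, so an unblended G from sample
  frequencies is always singular; the blend (and, in toys, external
  frequencies) restores invertibility.
* Zero-variance chains return Geweke z = 0 and ESS = n; empty residual
  classes draw from their prior; degenerate slope samples (S ≤ 0) are
  excluded from correlation summaries and counted.
* HPD intervals are shortest sample intervals; no distributional
  assumption.

## Known limitations

* Single chain per fit; no cross-chain convergence statistic (R-hat).
* The intercept confounding makes the *split* of level variance between
  the DIM and THI trajectories prior-sensitive; the identified quantities
  are the summed intercept variance and all slope-related components.
* The PCG solver treats the fixed block as full rank; fully aliased fixed
  columns raise an error rather than being absorbed.
* Reliability/accuracy from the MME inverse is not computed; validation
  accuracy is the regression-based definition only.
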