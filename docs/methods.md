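# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `nampred`, in the package's own terms.

## Synthetic NAM population

The generator emulates a barley-style nested association mapping design: 25
wild donors each crossed to one elite recurrent parent, one backcross to the
recurrent parent (BC1), then single-seed-descent selfing (three generations
by default, giving BC1S3 lines).

- **Genetic map.** Equally sized chromosomes (default 7 x 150 cM) with
  markers uniformly spaced plus jitter, standing in for a dense genotyping
  array. Positions are in centimorgans and drive recombination directly.
- **Meiosis.** Crossovers are a Poisson process at one event per 100 cM per
  chromosome, without interference. This is the simplest map-consistent
  model; it reproduces the linkage-disequilibrium block structure that
  whole-genome regression relies on, but not crossover interference or
  recombination hot/cold spots of real genomes.
- **Founders.** The recurrent parent is homozygous for the reference allele
  everywhere; each donor is homozygous for the alternative allele at a
  family-specific random half of the markers (configurable), so each family
  segregates only at its donor's subset — the hallmark of NAM genotype data.
  Dosages count donor alleles (0/1/2).
- **Mendelian expectations** used as oracles: donor allele frequency 1/4 at
  segregating loci after BC1 (selfing leaves it unchanged), and expected
  heterozygosity 1/2 x (1/2)^s after s selfings (6.25% at s=3). The
  test-suite checks both within three standard errors across families.
- **Phenotypes.** A trait is a sum of additive effects at `n_qtl` randomly
  chosen segregating markers (effects i.i.d. standard normal). Plot values
  add a year main effect (normal with standard deviation twice the genetic
  one — wide, but it cancels in BLUEs and does not enter heritability), a
  genotype-by-year deviate with variance `gxy_ratio x V_G` (default 0.1),
  and a residual whose variance is solved from
  h2 = V_G / (V_G + V_GY/y + V_R/(y r)) so the realized trial hits the
  target entry-mean heritability exactly in expectation. Default trial: 8
  years x 2 replicates; target h2 defaults to 0.9, in the upper range typical
  of developmental traits in multi-year trials (0.4-0.95 are supported, and
  the residual solver rejects infeasible combinations).
- **Metabolites.** Per metabolite, a target genomic heritability is drawn
  from Beta(1, 9) — mean 0.10 — truncated at 0.50, matching the observed
  pattern that most leaf metabolites carry little genomic signal and the
  best about half. Each metabolite has 10 additive QTL, half of them (by
  default) shared with the trait's QTL so that metabolites and traits are
  genetically related without being redundant; noise is sized so the
  variance ratio hits the target, and the signal is mapped to a positive
  intensity scale (mean 100, sd 10). Missing entries are completely at
  random (default 5%, supporting 0-15%). Real GC-MS intensities additionally
  show left-censoring at the detection limit, batch effects and lognormal
  tails, none of which are modelled; passing tests therefore demonstrate the
  statistical machinery, not robustness to instrument artefacts.
- **Seeding.** One user seed fans out into named sub-streams (map, meiosis,
  phenotypes, metabolites, partitioning, sampler) via CRC-keyed
  `SeedSequence`s, so stages rerun independently yet reproducibly.
- Family sizes are equal by default (the real population's per-family counts
  vary and are configurable).

## Preprocessing

- Marker QC keeps markers that are polymorphic in at least one family, have
  a missing-call fraction strictly below 0.10 and a heterozygote fraction
  strictly below 0.125 (both thresholds configurable; the strictness side of
  the inequalities follows the conventions of the motivating study).
- Within-family-monomorphic markers are recoded to dosage 0 for that family:
  a family that does not segregate at a marker is genetically the recurrent
  parent there, whatever the raw call.
- Missing genotype calls are mean-imputed per marker (MNI) with the
  *continuous* column mean — the downstream regressions accept real-valued
  dosages, and rounding would discard information.
- Metabolites with a missing fraction strictly above 0.10 are dropped;
  remaining gaps are filled with the per-metabolite observed minimum
  (missingness in GC-MS panels is predominantly censoring at the detection
  limit, for which the observed minimum is the natural plug-in).
- Box-Cox transforms pick the exponent from a grid (-3 to 3 by 0.25) by
  maximizing the Box-Cox log-likelihood; non-positive inputs are shifted by
  (1 - min) first. Whether transformed or raw metabolites enter the
  predictors is the caller's choice; the pipeline default is raw intensities
  standardized per column.

## Phenotype model

REML for value = mu + year + genotype + genotype x year + error (year fixed;
genotype, interaction and error random) exploits that both random terms are
genotype-specific: the marginal covariance is block-diagonal by line, so the
restricted likelihood is accumulated from small per-line blocks (one shared
factorization when the design is balanced). Optimization is derivative-free
(Nelder-Mead) on log-variances from three starts — balanced-ANOVA
method-of-moments values plus two spread starts — with 1e-8 tolerances. A
floor of 1e-8 x var(y) keeps the covariance full-rank on degenerate
noise-free inputs, where the restricted likelihood is otherwise unbounded;
estimates below 1e-6 x var(y) are reported as exactly zero. On balanced
designs the result agrees with the classical ANOVA estimators to 1e-5, which
the tests assert against an independent implementation of those estimators.

BLUEs use fixed genotype plus fixed year effects (a random-year variant is
available; on balanced data they coincide). The reported BLUE is each line's
expected value averaged over the observed years, so values are comparable
regardless of the year coding. With a single year the BLUE is the line mean.

Genomic heritability of a line-level trait fits up to three genomic kernels
by REML: additive (centered dosages, K = Xc Xc' scaled to mean diagonal 1),
dominance (centered heterozygosity indicators, likewise), and
additive-by-additive epistasis (Hadamard square of the additive kernel).
`genomic_heritability_batch` is a fast additive-only path that
eigendecomposes the kernel once and profiles each trait's likelihood over
the variance ratio — used to scan whole metabolite panels.

## Predictors

- **RR-BLUP.** The ridge penalty defaults to the variance-component plug-in
  lambda = (s2_R / l) / (s2_G / m); `lam=None` estimates it by REML inside
  the training data instead (spectral parametrization, 1-D bounded search).
  The solver uses the primal mixed-model equations when m <= n and the
  kernel identity g = X'(XX' + lambda I)^{-1}(y - 1 mu) otherwise; repeated
  cross-validation slices one precomputed kernel instead of refitting from
  X, which makes 100 evaluations on ~1,300 lines a matter of seconds.
- **BayesB.** Canonical dosages 0/1/2 are shifted to -1/0/1 before sampling
  (the intercept absorbs the shift, so predictions are coding-invariant —
  asserted in the tests). Default priors: slab variance df0 = 5 with scale
  set so the slab explains half the response variance given the mean
  predictor variance and the prior inclusion rate; residual df 5 with scale
  targeting half the response variance; pi ~ Beta(1, 9) (pi is the
  probability an effect is *zero*); chain 12,000 sweeps, 2,000 burn-in,
  thinning 5 — all configurable, and all echoed into the run manifest since
  they are conventions rather than published values. The indicator update
  integrates the effect out analytically given its variance; an excluded
  effect's variance is refreshed from its prior, keeping the sweep a valid
  Gibbs sampler on the joint posterior. The residual vector is updated in
  place, making each predictor update O(n). A diverging residual variance
  raises an error advising standardization.
- **Combined predictor sets** column-concatenate SNPs and metabolites, with
  the metabolite block standardized (zero mean, unit variance) so
  heterogeneous intensity scales do not dominate the common-variance prior.
- Effects are reported with provenance-tagged predictor ids; the reduction
  utilities consume them directly.

## Evaluation

- "100 cross-validation runs" are 20 independent family-stratified 5-fold
  partitions (20 x 5 = 100 evaluations): within each family, lines are dealt
  round-robin from a random starting fold, so every training set holds about
  80% of each family. This realization guarantees each line is tested once
  per replicate partition; treating the 100 evaluations as independent runs
  is the alternative reading and would differ only in the dependence
  structure of the summary SD.
- A run with constant predictions has undefined correlation; its ability is
  recorded as 0 (with a warning) rather than dropped, keeping n intact.
- Model comparisons are two-sided t-tests on per-run accuracies, paired when
  both results share a partition key and Welch otherwise. Within one trait,
  accuracy is a constant multiple of ability, so the choice of scale does
  not change the test.
- Subset selection ranks predictors by |effect| from a model fitted once on
  the *full* data, as the published reduction experiments did; this leaks
  whole-data information into the subset choice and therefore biases the
  reduced-set ability upward. The leakage-free alternative (re-ranking
  within every training fold) is deliberately not hidden behind the same
  API: callers combine `subset_predictors` with their own fold loop.
- Subset sizes use round(fraction x m) — e.g. 25% of 33,005 markers is
  8,251 — matching the arithmetic of the published counts.

## Problem sizes used in the checks

The acceptance-style checks run on sizes the package chooses for itself: the
full-scale synthetic NAM uses 25 families x 53 lines (1,325 lines, matching
the real population's order of magnitude) with 700 markers for variance
-component recovery, and 500 lines with 2,100 markers plus 128 metabolites
for the prediction-ordering checks. The marker:metabolite ratio is kept
large deliberately: with the study's ~260:1 ratio the combined predictor set
behaves like the SNP set alone, whereas at small ratios a noise-dominated
metabolite block measurably dilutes the ridge fit — a scaling effect worth
remembering when transferring conclusions to other panel sizes. Simulated
cross-validated abilities (about 0.8 for a 100-QTL trait at h2 = 0.9 with
~2,000 markers) sit below the published ~0.9 values, as expected with fewer
markers, fewer lines and no shared-environment structure; the qualitative
orderings, not the ability levels, are the reproducible quantities at this
scale.

## Known limitations

- No selection during population development, no shared ancestry among
  donors, no sequence-level simulation.
- No spatial field-trend correction and no multi-trait mixed models; the
  phenotypic model's only genotype-by-environment term is the
  genotype-by-year interaction.
- The predictors are strictly additive (no dominance or epistatic effect
  terms inside the regressions; those appear only in the genomic-
  heritability kernels).
- REML here targets the crossed random-effects structure of replicated
  multi-year trials; severely unbalanced designs fall back to a slower
  per-line loop and may render components inestimable, which raises rather
  than guesses.
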