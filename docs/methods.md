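# Methods

`dlgwas` implements a complete case-control SNP analysis chain — quality
control, allelic association scan, genotype-to-image encoding, convolutional
classification, and saliency-based locus discovery — together with the
synthetic data generator that makes every stage testable without access to
restricted cohort genotypes.  This note records the models, the parameter
choices and their rationale, and the limits of what the synthetic
experiments demonstrate.

## Synthetic case-control genotypes

Each biallelic autosomal variant receives an unordered pair of distinct
nucleotides and a minor-allele frequency drawn uniformly from `maf_range`
(default 0.05–0.5, the post-QC range of a genotyping array).  Non-causal
genotypes follow Hardy–Weinberg proportions and are mutually independent.
Disease status follows a logistic model on causal minor-allele dosage,

    log-odds(case) = logit(p0) + Σ_j log(OR_j) · dosage_j ,

sampled by rejection until the case and control quotas are met.  `p0` is the
*zero-dosage* intercept, not the population prevalence; with several strong
risk loci the two differ by orders of magnitude, and study-like experiments
should calibrate `p0` downward so the implied population prevalence is
realistic (≈10% for late-onset dementia).  With 10 loci of OR 8 at MAF 0.3
this means `p0 ≈ 1e-8`.

QC failures are injected on top of the clean draw: designated variants and
samples get an extra 20% missingness (call rate ≈ 0.8, safely below the 0.9
threshold), designated variants get an inbreeding-style heterozygote deficit
(f = 0.6, which at n ≥ 500 yields Hardy–Weinberg p ≤ 1e-6 with probability
well above 0.9), and designated samples are exact pre-missingness copies of
earlier samples (identical-by-state everywhere, so PI_HAT = 1).

An optional local-LD mode makes the `ld_block_size − 1` variants that follow
each causal variant in (chromosome, position) order noisy copies of its
genotype (per-allele flip probability `ld_flip_rate`, default 0.1, giving
|r| ≈ 0.8 to the causal variant).  Real arrays exhibit exactly this local
tagging structure, and it is what gives a convolution-plus-pooling
architecture its footing: without LD the class signal lives in isolated
pixels, which spatial pooling averages away.  The default is LD off
(independent variants), which suffices for testing QC and scan mechanics.

What the generator does *not* emulate: genome-wide LD maps, population
structure and admixture, X-dosage association, batch effects, and ordinal
liability across the three diagnostic classes (three-class experiments are
composed of pairwise binary contrasts, matching the study design).  Passing
tests therefore demonstrate the mechanics of the pipeline and its behaviour
under a known generative truth — not performance on real cohort data.

## Quality control

Six criteria in a fixed order, each applied to the survivors of the
previous step: variant call rate ≥ 0.90, sample call rate ≥ 0.90, sex
check, MAF ≥ 0.05, Hardy–Weinberg p > 1e-6, PI_HAT < 0.5.  Choices the
criteria leave open:

* **HWE test.** Default is the 1-df goodness-of-fit chi-square (fast,
  vectorised); the conditional exact test (sum of heterozygote-count
  probabilities no larger than the observed one, given the allele totals)
  is available as `hwe_method="exact"` and is verified against exhaustive
  integer-arithmetic enumeration for every table with ≤ 200 chromosomes.
  HWE is tested in the pooled sample; a controls-only convention can be
  arranged by subsetting first.
* **Sex check.** Reported males with X heterozygosity > 0.2 and reported
  females below 0.2 are flagged, provided ≥ 20 non-missing X calls; with no
  X variants the check is skipped and logged.  The 0.2 cutoff is the common
  array-QC convention.
* **Relatedness.** PI_HAT is the method-of-moments IBD estimate: observed
  IBS0/1/2 counts over jointly non-missing autosomal variants, expected IBS
  probabilities given IBD state from the observed allele frequencies,
  solved for (Z0, Z1, Z2) and clamped; PI_HAT = Z2 + Z1/2.  All-pairs
  computation is done with masked indicator matrix products, so a
  1000-sample dataset takes seconds.  Pairs need ≥ 50 shared variants;
  of a flagged pair the lower-call-rate member is dropped (ties: the later
  sample id).
* QC is run per classification pair, so each pairwise task has its own
  variant universe; the shared-locus stage works on the intersection.

## Association scan and baseline classifier

Per variant, the 1-df allelic chi-square on the 2×2 allele-count table with
the cross-product odds ratio; genome-wide significance at the Bonferroni
level 0.05/N (N = 301,388 post-QC variants gives the production threshold
1.66e-7).  Scan calibration is summarised by λ = median(χ²)/0.4549, and
Manhattan/QQ series use expected quantiles (i − 0.5)/N.  The baseline
classifier is a linear-kernel SVM over repeated stratified train/test
splits (default 500) on standardised minor-allele dosages of the
scan-significant variants — the genotype-only stand-in for intensity-derived
predictors, which do not exist for simulated data.

## Genotype images

Each variant contributes two adjacent pixels (one per allele, alphabetical
order) laid out row-major in (chromosome, position) order; codes A=1, T=2,
C=3, G=4, missing=0, divided by 4.  The mapping is an explicit bijection,
so images decode losslessly and saliency projects back to variants.  A side
of S pixels holds ⌊S²/2⌋ variants; trailing variants are cropped and
recorded (776² holds 301,088).  The default side is data-sized
(⌈√(2M)⌉); 776 reproduces the production configuration.

## Convolutional classifiers

Implemented directly in numpy (im2col convolution via strided views and
einsum, explicit backward passes, Adam with classic L2-in-gradient).  Three
families:

* `plain_cnn`: three conv3×3-ReLU-pool stages (16/32/64 filters) and one
  hidden fully connected layer.  Pooling defaults to *mean*: on
  nucleotide-code images a max saturates toward the largest code present in
  the window and measurably destroys allele-frequency signal, whereas the
  mean preserves it; max pooling remains available.
* `resnet18` / `resnet34`: standard [2,2,2,2] and [3,4,6,3] residual
  layouts over widths 64/128/256/512, H(x) = F(x) + x with projection
  shortcuts on shape change; an input-size-adaptive stem (7×7/2 + pool for
  sides ≥ 128, 3×3/1 otherwise).

A width multiplier scales all channel counts (minimum 4) so desk-scale runs
finish in minutes; multiplier 1 at side 776 is the production size.
Training follows the study protocol: Adam, cross-entropy, batch 8, L2
weight decay (default 1e-4), learning rate 1e-3 for 20 epochs (residual
families) or 1e-2 for 30 epochs (plain CNN), with a stratified 25%
validation split; the weights of the best-validation-loss epoch are kept.
"Maximum iterations" is read as epochs — at batch size 8 and ~1,000
subjects, 20 *batches* would not complete one pass over the data.  The
protocol's validation group exists to guide hyperparameter choice, and at
desk scale (side 64, n = 400) the validated choice differs from the
production one: lr 3e-4 with weight decay 1e-3 and ~40 epochs is what the
validation loss selects; the production defaults overfit instantly there.
An optional genotyping-dropout augmentation (`augment_missing`) masks a
fraction of training pixels to the missing-call value.

Splits: per class, round(0.1·n) subjects to the independent test group,
then floor(0.25·remaining) to validation; 5-fold stratified cross-validation
runs over the training pool, and by default every fold model is evaluated
on the single held-out test group (fold-internal evaluation is a mode
switch).  Metrics are the usual confusion-matrix ratios with undefined
components reported as NaN, plus a threshold-sweep ROC whose trapezoidal
AUC equals the Mann–Whitney concordance.

## Saliency and locus discovery

Class-specific heatmaps come from the last convolutional layer of the last
block.  Two formulations are provided: the classic channel-weighted form
(spatially averaged gradients as channel weights) and an element-wise
gradient×activation form.  The classic form assumes importance is spatially
uniform per channel, which is only true above a global-average-pool head;
under a fully connected head it erases position information, so the
element-wise form is the default for the plain CNN and the classic form for
the residual families.  Because the target layer is coarser than the pixel
grid (one cell covers several variants), maps are additionally sharpened by
the magnitude of the class-score gradient at the input (guided mode,
default on).  Maps are min-max normalised per sample (constant maps become
zero), and per-variant scores are the mean of each variant's two pixels.

Discovery statistics: per-variant Welch two-sample t-test on the per-sample
saliency scores between diagnostic groups, Benjamini–Hochberg adjustment
across variants, flags at both raw p < 0.05 (the production report's
convention) and q < 0.05 (the default for headline counts).  The
shared-locus report intersects the tasks' variant universes and flags
variants significant in all three pairwise tasks.

## Known limitations

* **Saliency resolution.** The target layer has (side/4)² cells at side 64,
  so one cell spans 8 variants; variant-level ranking inside a cell relies
  entirely on the guided input-gradient term.  In the desk-scale planted
  study the median rank of causal variants lands near the middle of the
  distribution — block-level, not variant-level, localisation is what this
  architecture class supports at that scale.
* **Sample-size regime.** With 4,096 independent variants and 400 subjects
  the pixel-space learning problem is information-limited: the
  Bayes-optimal balanced accuracy of the 10-locus OR-4 generative model is
  ≈ 0.87 (≈ 0.93 even as OR → ∞, because the dosage-sum statistic is
  discrete), a convex well-regularised linear model on pixels reaches
  ≈ 0.6 without LD and ≈ 0.9 with LD, and the convolutional models reach
  ≈ 0.75 with LD at n = 800 and ≈ 0.5–0.7 at n = 400 — consistently below
  the selection-based SVM baseline, which sees only scan-significant
  variants.  The desk-scale experiments therefore exercise and verify the
  pipeline's mechanics; they do not reproduce production-scale accuracy
  claims, and the acceptance suite reports these numbers as measured.
* Monomorphic variants carry no relatedness information and are weighted
  out of PI_HAT; variant alleles unobserved in a written .ped file cannot
  round-trip (a .map carries no allele columns).
* Training determinism holds exactly under a fixed seed on a fixed BLAS;
  across BLAS builds, float32 accumulation order may differ in the last
  bits.
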