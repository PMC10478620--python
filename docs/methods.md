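# Methods

## The problem

In livestock GWAS, the usual device for declaring SNPs significant is a fixed
p-value threshold (Bonferroni, FDR). When the same marker panel serves both
association testing and genomic prediction, a fixed threshold says nothing
about how many markers the *prediction* actually needs. This package
implements a GEBV-assisted reduction of SNP sets: markers are ranked by GWAS
p-value, G-BLUP is refit on nested subsets of the top-ranked markers, and the
subset size is chosen from the behaviour of the prediction-ability trace
rather than from a significance level. The chosen subset size maps back to an
equivalent per-test p-value threshold, so the result is directly comparable
with a Bonferroni cutoff.

## Model and procedure

**Association scan.** Each SNP is tested by OLS of the trait on
`[1, covariates, dosage]`; the reported effect is the additive
allele-substitution effect of the A1 allele with a two-sided t-test on
`n − rank(design)` degrees of freedom. Sex enters as a single indicator and
parity as dummy-coded classes (parity classes are groups, not a dose; a
numeric coding is available by removing `parity` from the categorical set).
Bonferroni and Benjamini–Hochberg adjusted p-values are attached for
reporting; the ranking itself always uses raw p.

**G-BLUP.** The animal model is `y = Xb + u + e`, `u ~ N(0, Vu·K)`,
`e ~ N(0, Ve·I)` with `K` the VanRaden method-1 GRM
(`K = ZZ' / 2Σf(1−f)`, `Z` the dosage matrix with columns centred by `2f`).
REML is maximised over `h² = Vu/(Vu+Ve)` on the spectrum of `K`: after
rotating by the eigenvectors of `K` the covariance is diagonal, the global
variance scale has a closed form at every `h²`, and the restricted likelihood
is a one-dimensional profile optimised by bounded scalar search
(`xatol 1e-8`) on `h² ∈ [1e-6, 1−1e-6]`. Eigenvalues are clipped at zero;
an optimum pinned at a boundary, or a residual variance that vanishes after
fixed effects, is flagged `degenerate`. An approximate standard error of
`h²` from the profile curvature is available but not load-bearing.

**Trace and cutoff.** For subset sizes `step, 2·step, …` (default step
1,000 SNPs; a final partial point covers the remainder) the GRM, REML fit and
in-sample GEBVs are recomputed from scratch, and

    PA_i = cor(y, GEBV_i),      CD_i = PA_i − PA_{i−1}.

The trace is reported with per-step newly-covered gene counts when an
annotation (BED, converted from 0-based half-open, or GFF3 gene features,
1-based inclusive) is supplied. The cutoff rule formalises "the region
immediately before the persistently negligible correlation differences":
with `μ = mean |CD|`, the cutoff is the last trace point with `|CD| ≥ μ`
provided every later point stays below `μ`; if the final point itself reaches
`μ` there is no such tail, the decision is flagged `no_plateau`, and the
cutoff falls back to the full ranked set. `|CD|` rather than signed CD is
averaged because negligibility is about magnitude, and CD is routinely
negative once noise markers dilute the GRM. The ratio of `|CD|` just after
the cutoff to `|CD|` at the cutoff is reported as an `abruptness` diagnostic,
not used as a gate.

Two properties of this construction deserve emphasis. First, the trace PA is
**in-sample** (all individuals in one fit), which is optimistically biased —
the bias is the point: it makes the trace smooth enough to difference. The
out-of-sample value of the selected subset is quantified separately by
cross-validation. Second, the bottom of a p-value ranking is *anti-selected*:
the last-added SNPs are those whose dosages are most orthogonal to the trait,
so the final trace step often shows a disproportionate PA drop. On
high-signal synthetic data, where all other CDs are near zero, this terminal
dip can dominate the mean and trigger the `no_plateau` fallback; users should
read a `no_plateau` flag on an otherwise flat trace as "no informative
plateau structure", not as "all markers needed".

**Cross-validation.** The default is Monte-Carlo CV: `n_splits` independent
seeded draws of a 30% test set (the 10-splits-at-0.3 design cannot be
disjoint 10-fold, whose test share would be 0.1; a strict disjoint mode is
behind `disjoint_kfold`). Each split refits variance components and fixed
effects on the training rows and predicts test GEBVs through
`Vu·K[test,train]·(Vu·K[train,train] + Ve·I)^{-1}·(y_train − X_train b̂)`.
PA per split is the correlation of raw test phenotypes with predictions
(covariate-adjusted phenotypes behind `adjust_covariates`). The SNP ranking
is not recomputed inside training splits — a known source of optimism,
documented rather than defaulted away; splits that happen to draw a constant
test phenotype are recorded as missing and excluded from the aggregates. If
a rare covariate class is absent from a training draw, its dummy column is
dropped for that split to keep the design full rank.

## Quality control

Markers are filtered jointly (all three statistics computed on the same
input, so the result is order-independent): MAF ≥ 0.05, per-SNP missingness
≤ 0.05, and exact-test HWE p ≥ 1e-6. The HWE test is the exact conditional
test (sum of probabilities of heterozygote counts no more probable than the
one observed, computed by the stable ratio recurrence), matching the
behaviour of PLINK's `--hwe`. MAF uses non-missing calls only; monomorphic
SNPs get MAF 0 and fail; all-missing SNPs are flagged undefined and fail.
Mean imputation (per-SNP mean dosage into missing cells) is deliberately
simple plumbing — adequate for the low post-QC missingness this package
expects, not a substitute for haplotype-based imputation, and fractional
imputed dosages are never written back into PLINK files.

## Synthetic cohorts

The generator emulates the structure of a Landrace production cohort on a
~60K porcine chip: 18 autosomes, ~50 kb marker spacing (gaps uniform on
20–80 kb), allele frequencies uniform on [0.05, 0.5], Hardy–Weinberg
genotypes, 2,933 individuals split 1,667/1,266 by sex and
698/551/534/472/368/184/85/24/17 across nine parity classes (apportioned
proportionally when a smaller cohort is drawn), additive trait with target
heritability 0.3, and backfat-like anchors (mean 12.46, SD 2.14). Effects
are equal-variance normal by default (`exponential` for skewed
architectures, `equal` for equally strong QTLs); residual variance is set so
var(g)/var(g+e) hits the target, fixed effects (sex 0.5 SD, parity a 0.05 SD
per-class gradient) are added on top, and the affine rescale to the trait
anchors leaves the variance ratio — hence realized h² — unchanged.

What the generator does **not** emulate: linkage disequilibrium, family and
population structure, selection. SNPs are independent, so (a) the effective
marker dimension equals the marker count, making out-of-sample PA at
`m ≫ n·h²` much lower than chip data with LD would give, and (b) the
p-ranking has no clumping. Passing tests on these cohorts validate the
machinery (ranking, REML, BLUP algebra, the cutoff rule, determinism), not
field-data performance.

## Problem sizes and numerical choices

The shared test fixture is 300 × 3,000 with 30 QTLs at h² 0.3 (fixed seed),
traced at step 500; recovery checks use 500 × 1,000 (heritability) and
500 × 5,000 (planted architecture); the acceptance script runs the full
pipeline at 500 × 5,000 with the default 100-QTL h²-0.3 trait and reports
heritability as the mean over five 500 × 1,000 replicate cohorts, where h²
is well identified. P-values are floored at the smallest positive float so
−log₁₀ plots stay finite. Ranking ties break by (chromosome, position);
non-testable SNPs sort last in genome order. All randomness descends from a
single user seed via fixed stream offsets (`[seed, stage]` seed sequences),
so every artifact is bit-reproducible.

## Known limitations

- In-sample PA saturates quickly at high h², leaving little CD texture; the
  cutoff is most informative for moderately heritable, polygenic traits.
- The cutoff rule's fallback (`no_plateau` → full set) is conservative by
  construction and is expected on flat traces with a terminal anti-selection
  dip.
- Dense eigendecompositions bound practical cohort sizes to a few thousand
  individuals per fit.
- Mean imputation and non-nested ranking inside CV are documented sources of
  (small) optimism, chosen for simplicity and parity with common practice.
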