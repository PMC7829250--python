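# Methods

`genobank` implements the statistical core of a genome-wide prediction
workflow for plant gene-bank collections: genomic BLUP (GBLUP) for
quantitative traits with per-individual reliabilities, a probit
one-versus-all GBLUP classifier for unordered categorical traits (growth
habit, spike row type), Rogers-distance principal coordinate analysis for
structure assessment, best linear unbiased estimation (BLUE) of accession
means from multi-year records, and six training/test scenario designs.
This note records the models, the numerical choices, and what the
synthetic test bed does and does not establish.

## Genomic relationship matrix

Genotypes are reference-allele dosages in [0, 2] (fractional values allowed
for imputed calls). The additive genomic relationship matrix is the
VanRaden cross-product

    G = W W' / (2 Σ_k p_k (1 − p_k)),   W = M − 2p,

with `p` the allele-frequency vector. Frequencies default to the observed
means over the supplied accessions; an external frequency vector can be
passed so that prediction-time extensions of `G` center new genotypes with
training-set frequencies. Monomorphic markers are zeroed in `W` and
excluded from the denominator; an all-monomorphic panel is an error.
When `G` must be inverted and its condition number exceeds 1e12, a ridge
of `1e-6 × mean(diag G)` is added with a logged warning.

## Rogers' distance and PCoA

For a biallelic locus the Rogers distance between accessions reduces to
`|d_i − d_j| / 2`; the pairwise distance is the arithmetic mean over loci
(the classical multi-locus definition), hence lies in [0, 1]. PCoA is
classical multidimensional scaling: double-center `−½ D∘D`,
eigendecompose, scale the top-k eigenvectors by the square roots of their
eigenvalues. Negative eigenvalues (non-Euclidean distances) are reported
but excluded from both the coordinates and the explained-variance
denominator, so `explained` sums to at most 1 over the positive spectrum.

## BLUEs from multi-year records

Phenotype records `(accession, trait, year, value)` are adjusted with

    value = genotype (fixed) + year (random, iid) + residual.

The year-variance ratio is estimated by REML, profiled over
`γ = σ²_year/σ²_e` with Woodbury identities keeping every solve at the
size of the year table; genotype effects use cell-means coding, so the
reported BLUE is the adjusted mean itself (algebraically identical to an
intercept plus sum-to-zero effects). Duplicate cells are averaged first; a
single year level degrades to per-accession means. A pluggable `prefilter`
hook accepts outlier-handling rules, which are deliberately out of scope.
Because spring and winter material can score the same trait against
different reference dates, cross-growth-habit runs refuse traits flagged
incomparable rather than silently pooling them.

One caveat found while validating: BLUE errors are correlated through
shared year effects, so prediction abilities measured on *small* test sets
of multi-year BLUEs are noticeably attenuated relative to large test sets.
Tests that compare abilities across designs therefore either use large
test sets or single-record responses.

## Gaussian GBLUP

The model is `y = Xβ + Zg + e`, `g ~ N(0, σ²_g G)`, `e ~ N(0, σ²_e I)`,
with `G` over all accessions (phenotyped and not) and `Z` the phenotype
incidence. `X` always carries an intercept; covariates (subpopulation
dummies in reference coding, or externally estimated ancestry
coefficients) are appended and linearly dependent columns are pruned by
pivoted QR with a log entry, so redundant dummy/ancestry encodings cannot
produce a singular system.

Variance components come from exact REML via the spectral decomposition of
the phenotyped submatrix of `G`: the restricted likelihood is profiled over
`log γ`, `γ = σ²_g/σ²_e`, on a coarse grid over [e−14, e14] refined by
bounded scalar minimization — deterministic, no sampling. (The original
workflow this emulates fitted the same model by Gibbs sampling with
scaled-inverse-χ² priors; REML-BLUP and posterior means agree closely at
these model sizes, and the sampler is retained where it is genuinely
needed, in the binary module.)

Given components, Henderson's mixed model equations

    C = [[X'X, X'Z], [Z'X, Z'Z + λ G⁻¹]],  λ = σ²_e/σ²_g,

are solved jointly for `β` and `g`. Unphenotyped accessions simply lack
rows of `Z`; their BLUPs emerge from the joint system, which equals the
conditional-expectation extension and yields their reliabilities for free.
Reliability is the squared-scale quantity

    r_i = 1 − d_i σ̂²_e / σ̂²_g,

with `d_i` the i-th diagonal of the `C²²` block of the Moore-Penrose
pseudoinverse of `C`, clipped to [0, 1]. Values below −1e−8 before
clipping trigger a diagnostic warning; they arise legitimately for
accessions with `G_ii > 1` and no information flow. Both the MME solution
and the reliabilities are verified against independent closed-form oracles
(direct GLS/BLUP with `V = σ²_g ZGZ' + σ²_e I`; multivariate-normal
conditional variances) to 1e−8 / 1e−6. Note that as `σ²_e → 0` the
reliability of a phenotyped accession tends not to 1 exactly but to
`1 − var(confounded mean)/σ²_g`, because the intercept and the mean
genetic value are confounded; the oracle shares this term.

Prediction ability is the Pearson correlation of predicted and observed
values; it refuses constant vectors and fewer than 3 pairs.

## Binary and categorical GBLUP

Categorical traits use a probit latent-liability GBLUP:
`y* = Xβ + g + e`, `e ~ N(0, 1)` (fixed for identifiability), observed
class `1{y* > 0}`, `g ~ N(0, σ²_g G)` jointly over labeled and unlabeled
accessions. Fitting is data-augmentation Gibbs: truncated-normal latent
draws, conjugate normal updates for `β` and `g` (one Cholesky of the n×n
posterior precision per sweep), and a scaled-inverse-χ² update for `σ²_g`
(prior df 5, scale 1.4, prior mode ≈ 1). The reported membership
probability is the posterior mean of `Φ(x_iβ + g_i)`. Binary models are
intercept-only by default, with optional covariates.

Defaults are 6000 iterations, 1000 burn-in, thinning 5, seed mandatory —
sized for collections up to a few thousand accessions on one core. The
package's own tests and the acceptance script use 1500/500/5 at n ≤ 300,
where the chains mix quickly; chain settings are explicit arguments, not
silent global state.

K-class assignment is one-versus-all: K binary fits (a single fit when
K = 2), argmax of the *raw* membership probabilities (not renormalized;
the probability sum is kept as a diagnostic and the normalized version is
only produced by the sklearn `predict_proba` wrapper). Ties go to the
alphabetically first class with a logged warning. Classes need at least 2
labeled members to be fit at all; scenario-level inclusion uses a separate
configurable threshold (default 10), mirroring the practice of excluding
two-member classes from collection-scale analyses.

## Scenario designs

Balanced k-fold plans stratify so each fold's per-stratum count differs by
at most one member, with fold totals balanced by rotating the starting
fold between strata; plans are reproducible under their seed. Every
evaluation passes a leakage guard (training ∩ test = ∅, both non-empty).

1. *Within*: independent 5-fold CV inside each subpopulation.
2. *Pooled*: 5-fold CV over all subpopulations with the subpopulation
   ignored, as a fixed covariate, or replaced by ancestry coefficients;
   per-subpopulation abilities are computed on each fold's test members.
3. *Across*: each group trains a model evaluated on every other group.
   The across-group run itself has no folds; the reported SD comes from
   10 repeated random 80% subsamples of the training group (a documented
   convention, since dispersion must come from somewhere), and the
   diagonal is filled from scenario 1.
4. *Core*: train on the phenotyped members of a supplied core-collection
   ID list, test on the remaining phenotyped accessions. A core with
   fewer than 10 phenotyped members is flagged low-confidence and borrows
   variance components estimated from all phenotyped accessions; a
   single-member core yields flat predictions (the intercept fits the one
   record exactly), so its ability is reported as NaN rather than a fake
   number.
5. *Predict-all*: fit on every phenotyped accession, emit BLUPs and
   reliabilities for everyone, and summarize the reliability distributions
   of phenotyped vs unphenotyped sets plus the fraction of unphenotyped
   accessions above reliability 0.6.
6. *Cross-habit*: spring trains for winter and vice versa, with
   within-group CV as the reference; refused for incomparable traits.

Reported dispersions are sample standard deviations across folds or
repeated subsamplings. All scenario runs are bit-reproducible under a
fixed seed in single-threaded execution.

## Synthetic gene-bank generator

The simulator emulates the features of a large barley collection that the
methods actually exercise: `K` subpopulations with Balding-Nichols
divergence at a configurable Fst (ancestral frequencies Uniform(0.05,
0.95), subpopulation frequencies Beta-distributed around them), a
major-gene categorical trait, polygenic traits with target single-record
heritability (default 0.8, matching the high heritabilities typical of
multi-year gene-bank BLUEs), non-genetic subpopulation mean shifts,
multi-year records (3–5 per accession over a 5-year pool, year variance
1.0), and missingness in labels and phenotypes. Genetic values are
rescaled so the realized variance ratio hits the target heritability
exactly in every realization.

Class loci are, by default, one strongly differentiated marker per
subpopulation (frequency ≈ 0.9 in its own subpopulation, 0.05 elsewhere)
with class = argmax dosage — a morphological key trait aligned with
structure, which is the regime in which genomic classification of row
type succeeds; a `single_locus` threshold rule is available for
structure-free class simulations. Cross-population transferability loss is
controlled by a single knob, the between-group correlation of QTL effects.

What the simulator does *not* contain: linkage disequilibrium, genotyping
error, pedigree structure, or selection. GBLUP at desk scale does not
require LD — the realized relationships carry the signal — but this means
the effective marker dimensionality equals the panel size `m`. Where a
test needs the relationship-dense regime of real SNP data (hundreds of
thousands of markers collapsing to a few thousand effective segments,
small relative to the training set), it uses a deliberately small panel
(e.g. m = 100 against 1200 accessions for the core-collection comparison,
m = 500 against 1000 accessions for the within-population CV envelope);
the expected abilities follow `r ≈ √(h² n_train/(n_train + m))`, which is
how those panel sizes were chosen. Default sizes (2000 accessions × 5000
markers) run in minutes on one core; collection-scale data (tens of
thousands of accessions × 3×10⁵ SNPs) are explicitly not a test target.
Consequently, passing tests demonstrate correctness of the estimators and
the qualitative orderings (within > across under effect divergence,
covariate adjustment protecting shifted minorities, phenotyped ≥
unphenotyped reliability), not the numerical prediction abilities of any
real collection.

## Reproducibility

Every stochastic component takes an explicit seed; per-stage seeds are
derived from a single root seed via `numpy.random.SeedSequence`. CLI runs
write a JSON manifest (command, config, seed, input digests, version,
timestamp). `scripts/acceptance.py --seed N --out results.json`
regenerates all headline quantities from scratch.
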