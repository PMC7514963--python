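# Methods

## Connectome model and preprocessing

A subject's structural connectome is a square, symmetric, non-negative
matrix `W` whose entry `w_ij` is a streamline-count-derived weight between
parcellated regions `i` and `j` (120 regions by default, with a 12-region
subcortical block: left/right Hippocampus, Amygdala, Caudate, Putamen,
Pallidum, Thalamus).  Files are plain text, one row per line, comma- or
whitespace-delimited; dialects are auto-detected and scientific notation is
accepted.  Validation enforces squareness, atlas dimension, non-negativity
and symmetry; a relative asymmetry up to 1e-8 is attributed to round-off
and symmetrized as `(W + Wᵀ)/2`, anything larger is rejected as a corrupted
file (tractography connectomes are symmetric by construction).  Input
diagonals default to zero but are retained as valid data when present.

Each matrix is normalized by its own global maximum, mapping weights into
[0, 1].  Normalization is applied to the **whole** matrix before the
subcortical block is extracted, so sub-network weights are expressed on the
subject's global scale; extraction itself is a pure index restriction.
Quality control reports the off-diagonal density (fraction of positive
upper-triangle entries) and the within-group inter-subject Pearson
correlation of vectorized upper triangles (diagonal excluded — the
convention is documented because only "upper triangle" is standard usage).

## Communicability

Weighted communicability between nodes p and q sums contributions of walks
of all lengths, a length-k walk down-weighted by 1/k!:

    G = exp(M),  M = D^(-1/2) W D^(-1/2),  D = diag(S),  S_i = Σ_j w_ij.

`M` is invariant to global rescaling of `W` (the strengths rescale too), so
communicability features are unaffected by per-subject max-normalization.
Zero-strength (isolated) nodes make `D^(-1/2)` undefined; their rows and
columns of `M` are set to zero — the vanishing-weight limit — so an
isolated node communicates only with itself and no NaNs propagate.

The exponential of the symmetric `M` is computed by eigendecomposition
(`eigh`, exponentiated eigenvalues, reconstruction), the reconstruction is
re-symmetrized, and round-off negatives larger than −1e-12 are clipped to
zero (analytically every entry is non-negative since `M ≥ 0`).  The unit
tests verify agreement with an independently coded 30-term power series to
1e-10 on random matrices up to 20×20.

Three subcortical representations are computed per subject:

* `Wsub` — the 12×12 weight block;
* `G(Wsub)` — `exp(M)` of the block, with `D` from the block's own
  strengths (walks confined to subcortical regions);
* `[G(W)]sub` — `exp(M)` of the whole network (`D` from whole-network
  strengths, defined once for the network being exponentiated), restricted
  to subcortical rows/columns (walks may route through cortex).

Node summaries: the intra-strength communicability of subcortical node i is
the row sum of `G(Wsub)` over the subcortical set *including* the j = i
self-communicability term (the feature frame deliberately keeps self-pairs,
see below); the inter-strength communicability is the sum of `G(W)_ij` over
cortical j only.

## Group statistics

Pair-type feature sets vectorize the 12×12 matrices as the row-major upper
triangle including the diagonal: 12·13/2 = 78 features, labelled
`"(left Hippocampus, left Putamen)"` etc.  Self-pairs are genuine features
(the diagonal of a communicability matrix is the node's self-communicability
and varies across subjects), so they stay in the frame.

Per feature, the test statistic is the difference of group means
`mean(HC) − mean(AD)`, two-sided, assessed by random relabelling with group
sizes preserved (default 10,000 permutations) and the add-one estimator
`p = (1 + #{|stat_perm| ≥ |stat_obs|})/(n_perm + 1)`, which never returns
an exact zero and counts the observed labelling as one permutation.
Multiple testing is controlled per feature family (78 pairs together, or 12
nodes together) with Benjamini–Hochberg step-up adjusted p-values
(independence/PRDS form); a feature is significant when the adjusted p is
below q = 0.05.  Effect sizes are relative differences
`(mean_HC − mean_AD)/mean_HC` — positive values mean reduction in AD — and
are flagged NaN when the HC mean is zero.

## Classification

The supervised framework is evaluated with repeated stratified k-fold
cross-validation (defaults: 50 repeats × 10 folds; AD is the positive
class).  All feature selection is nested inside each training fold:

1. **Occurrence mask.** From the training fold's HC subjects only, the
   frequency `e_ij` of each subcortical edge being nonzero (in the weight
   block) is computed and thresholded at the smallest occurrence fraction
   that beats chance under a one-sided exact binomial test against
   p₀ = 0.5 at α = 0.01.  The threshold is therefore a function of the
   training-fold HC count, not a constant (≈0.71 at n≈41); a manual
   override is available in the config for reproducing study-specific
   cuts.  The same index mask is applied to whichever feature set is being
   classified — communicability matrices are dense, so occurrence computed
   on them would be uninformative.
2. **SVM-RFE.** A linear SVM (C = 1) is fit on the masked training
   features; the feature with the smallest squared weight is eliminated;
   repeat until none remain.  Near-ties (relative 1e-9) eliminate the
   lowest column index first, making the ranking deterministic.  The top 20
   ranked features (configurable `rfe_keep`; clipped with a warning when
   fewer survive the mask) feed the classifier.
3. **Random forest.** 500 trees, majority vote for the class label, the
   fraction of tree votes as the continuous score for a trapezoidal ROC
   AUC.  Per-fold accuracy, AUC, sensitivity and specificity are averaged
   (mean ± sd) over all repeat × fold evaluations.

Fold partitions and every per-fold random state derive from a single seed
and are independent of the feature set, so comparisons between `Wsub`,
`G(Wsub)` and `[G(W)]sub` use identical partitions and differ only in the
features.  A dedicated test plants an extreme artifact in a held-out
subject and verifies the training-fold mask and RFE selection are
bit-identical — no information leaks across the fold boundary.

## Synthetic cohorts

The generator emulates the summary statistics of a typical DWI streamline
cohort: 46 HC / 40 AD subjects, 120 regions, off-diagonal density ≈ 0.42,
within-group inter-subject correlation ≈ 0.83.  A template connectome is
drawn once (Erdős–Rényi support at the target density; log-normal edge
weights with log-sd `weight_sigma = 1.0`, a heavy right tail as for
streamline counts; zero diagonal; max-normalized).  Each subject multiplies
the template edgewise by i.i.d. log-normal noise `exp(N(0, σ_n²))`
(symmetrized) — preserving non-negativity and the zero pattern — and is
re-max-normalized.  AD subjects receive planted multipliers (on subcortical
pairs and/or subcortical–cortical routes) *before* normalization, so
effects interact with normalization exactly as real group differences
would; pairs named in an effect are forced onto the template support at the
median positive weight.  Ground truth is recorded alongside the cohort.

The noise level is calibrated analytically: with log-normal weights
(log-sd σ_w) on support density p and i.i.d. multiplicative noise σ_n, the
expected inter-subject correlation over the full upper triangle is

    ρ = (e^{σ_w²} − p) / (e^{σ_w² + σ_n²} − p),

so σ_w = 1.0, p = 0.42, ρ = 0.83 give the default `subject_noise_sd = 0.40`
(simulation confirms ρ ≈ 0.83 ± 0.01 and density ≈ 0.42–0.43).

A packaged *compensation-mechanism* scenario (`mechanism_config`) plants
the direction pattern of subcortical AD pathology: direct weight reduction
(×0.7) on five hippocampal/amygdalar/caudate pairs with a simultaneous
strengthening (×2.5) of routes from six subcortical regions to six cortical
regions each.  The route boost must be strong because the strength
normalization in `M` partially absorbs uniform weight increases: a boosted
node's strength rises, damping all of its normalized entries, and a boost
of ~1.6 roughly breaks even.  Under this scenario direct weights fall in AD
(positive relative differences in `Wsub`) while extracted communicability
between the boosted regions rises (negative relative differences in
`[G(W)]sub`), and `[G(W)]sub` classifies markedly better than `Wsub` —
the qualitative signature of cortically mediated compensation.

### What the generator does and does not emulate

It reproduces group sizes, density, inter-subject correlation, weight
non-negativity/symmetry/zero-pattern stability, and controllable group
effects.  It does **not** emulate spatial embedding, hemispheric symmetry,
degree distribution, modularity or subject-specific support (all subjects
share one template support; real cohorts vary in density 0.42 ± 0.06).
Passing tests therefore validate the statistical machinery and the
direction of communicability effects, not anatomical realism.

### A power ceiling intrinsic to the calibration

The correlation target caps recoverable effect sizes.  For any template
dispersion σ_w, solving the formula above for ρ = 0.83 forces
σ_n ∈ [0.34, 0.43], i.e. a per-edge coefficient of variation ≥ 0.35, on
top of which the per-subject max-normalization contributes a shared scale
fluctuation (the sample maximum of ~3000 noisy edges has cv ≈ 0.2 at the
defaults).  A 30% weight reduction then corresponds to a standardized group
difference of d ≈ 0.55–0.8 at n = 46/40 — enough to reach raw p ≈ 0.001–0.03
but frequently short of the ≈ 0.003 Benjamini–Hochberg threshold implied by
a 78-feature family with five true effects.  Recovery of ≥4/5 planted pairs
at FDR 0.05 consequently succeeds in only ~30–50% of generator seeds; a
larger planted effect, more affected pairs, or a weaker correlation target
would each lift it.  This is a property of the i.i.d.-noise calibration,
not of the test (whose type-I error is verified to be exact).

## Problem sizes used in the automated checks

The test-suite and summary-script runs scale the Monte-Carlo sizes to
desk-scale: 1,000 permutations (from 10,000), 5 × 10-fold CV (from 50×),
2 × 10-fold inside the null-classification average, and 30-region cohorts
for the type-I-error study (one feature tested per independent cohort so
the binomial reference distribution applies; within one cohort the 78
features are strongly cross-correlated and the rejection-rate variance is
super-binomial).  All defaults in the public API remain at the full study
settings.

## Known limitations

* The binomial occurrence-mask null (p₀ = 0.5) is a modelling choice; with
  an empirically estimated null the threshold would differ.
* Permutation tests use the difference of group means; no covariate
  adjustment (age, sex) is provided.
* The RFE keep-count (20) is a pragmatic default; performance is not
  sensitive to it in the packaged scenarios but it is exposed in the
  config and echoed in reports.
* CV AUC on null data has heavy per-cohort tails (a chance group split can
  be genuinely separable within a finite cohort), so null-behaviour checks
  average over several label permutations.
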