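# Methods

`cortexbench` is a benchmark pipeline for a question that recurs in multi-site
neuroimaging: when a classifier separates patients from controls on pooled
multi-site data, how much of that separation is disease signal and how much is
*site*?  The package implements the full vertex-wise cortical morphometry
classification pipeline — spherical projection to 2D images, two
cross-validation protocols, ComBat harmonization with a reference-batch stage
for unseen sites, normative residualization, and nested-CV linear SVM
evaluation — together with a synthetic cohort generator whose site, covariate
and diagnosis effects are known exactly, so the pipeline's behaviour can be
asserted rather than argued.

## Generative model

For subject *j* at site *i*, vertex *v*, each modality/hemisphere map is

    y_ijv = mu_v + b_age,v (age_j − mean age) + b_sex,v sex_j + b_dx,v dx_j
            + gamma_iv + delta_i eps_ijv ,      eps_ijv ~ N(0, sigma^2)

* `mu`, `b_age`, `b_sex` and each site map `gamma_i` are random band-limited
  spherical-harmonic fields (degrees ≤ `harmonic_degree_max`, default 8),
  rescaled so their spatial SD equals the configured amplitude.  Smooth fields
  mimic the strong spatial autocorrelation of real sulcal depth / curvature /
  thickness maps; the degree cap is the smoothness dial.
* `b_dx` is constant on a contiguous spherical cap covering
  `dx_effect_support` of the sphere (default 20%) and zero elsewhere —
  a focal, spatially coherent disease effect of known amplitude.
* `gamma_i` (additive site map, spatial SD `site_loc_sd`) and `delta_i`
  (multiplicative residual scale, drawn uniformly per site) are exactly the
  location/scale batch structure the ComBat model assumes, so harmonization
  quality is measurable as parameter recovery.
* The noise stream is keyed by (seed, modality, hemisphere) and is independent
  of the diagnosis draw.  Consequently, with `dx_effect_amp = 0`, regenerating
  the cohort with permuted diagnosis labels reproduces the feature arrays
  bit-for-bit: the null is *exact*, not approximate.

Demographics are drawn per site (age normal, truncated at 10 y; sex and
diagnosis Bernoulli).  `SiteProfile.balance_cases` draws exactly
`round(n · case_prob)` cases per site instead; see "Scenario design" for why
that matters.

What the generator does **not** emulate: real cortical folding geometry,
medial-wall anatomy, scanner-specific spatial noise correlation, nonlinear
age effects, and site-by-covariate interactions in the *generating* model.
Passing tests therefore show that the pipeline machinery behaves correctly
under the location/scale site-effect model — not that any particular real
dataset is free of subtler effects.

## Projection

Vertex maps are rendered to fixed-size images by two map families:

* **latitude/longitude** (equirectangular): row ∝ latitude, column ∝
  longitude.  Simple, but the Jacobian ∝ cos(latitude) inflates polar areas.
* **equal-area** (Lambert cylindrical): row ∝ sin(latitude).  The Jacobian is
  constant, so equal sphere areas receive equal image areas — the defining
  property of area-preserving cortical projections, and an analytically
  testable one (uniform sphere points must fill equal-height row bands
  uniformly; chi-square checks this).  The projection interface is pluggable,
  so a numerically optimized area-preserving map could be added without
  touching the rest of the pipeline.

Conventions, fixed once: north at row 0; longitude half-open in (−π, π] with
0 at the center column; forward maps are linear onto [0, H−1] × [0, W−1] so
the poles land exactly on the first/last rows.  Rendering inverse-projects
each pixel center to the sphere and interpolates over the k = 3 nearest
vertices with inverse-great-circle-distance weights (ε = 1e−8 rad); pixels
whose nearest vertex is beyond 3× the mesh's median edge length are marked
invalid and render as 0.  Each image plane is z-normalized (mean 0, SD 1 over
valid pixels; constant planes become zero), matching the common practice of
per-image standardization before classification.

## Harmonization (ComBat)

The parametric empirical-Bayes formulation: per-feature least squares with
batch indicators and preserved covariates (age, sex), standardization by the
pooled residual SD, normal prior on standardized batch locations,
inverse-gamma on batch variances, method-of-moments hyperpriors, and iterated
conditional updates (tolerance 1e−4, ≤ 100 iterations; non-convergence is
recorded, not fatal).  Covariate-explained variance is re-added after
adjustment.  Constant features (e.g. pixels outside the projected cortex)
bypass standardization and pass through unchanged.  The implementation agrees
with Bioconductor's `sva::ComBat` to ~1e−14 on shared fixtures (standard and
reference-batch modes); `sva` is kept as an independent oracle in the test
suite, never as the implementation.

Two protocols mirror the two CV strategies:

* mixed-site folds: parameters fitted on the training folds apply directly to
  test subjects (their sites were seen in training);
* whole-site folds: ComBat runs twice — standard harmonization of the
  training sites, then a reference-batch model in which all harmonized
  training data form one fixed reference batch and each unseen test site is
  adjusted toward it.  Reference data are returned bit-for-bit unchanged; the
  test suite asserts this bitwise.

A note on the "identity limit": the canonical estimator uses the unbiased
(ddof = 1) within-batch variance against an N-normalized pooled variance, so
even data with no batch effect is rescaled by √((n−1)/n).  Re-applying ComBat
to its own output is therefore an identity only to O(1/n); tests assert it at
that rate.

Harmonization operates on whatever representation is fed to the classifier —
projected pixels by default, vertex features equally well — the functions are
representation-agnostic (subjects × features).

## Cross-validation protocols

* **age_sex** (mixed-site): within each site, subjects are stratified by
  (sex, diagnosis), ordered by age with seeded tie-breaking, and dealt
  round-robin into k = 10 folds from a seeded per-site starting offset.  Every
  site is spread across all folds as evenly as integer rounding allows, and
  fold age/sex/case profiles are balanced.
* **site** (leave-site-out): greedy number partitioning — sites sorted by
  size descending (ties lexicographic), each assigned to the currently
  smallest fold (ties to the lowest index).  Deterministic, seedless, and
  carries the standard greedy bound max fold ≤ mean + max site size.

`validate_fold_plan` emits the per-fold QC table (n, age mean/SD, female and
case counts, site lists) plus cross-fold ranges.

## Normative residualization

Per feature, ordinary least squares of the feature on
[1, age − mean(age_HC), sex], fitted **only** on healthy subjects of the
training folds, then subtracted from every subject.  Fitting on controls
keeps disease effects out of the regressors; fitting on training folds keeps
test data out.  Age is centered at the healthy-training mean so the intercept
is the expected healthy value at that age; sex is coded 0 = M, 1 = F.
Degenerate designs degrade gracefully (single-sex or age-constant healthy
sets fix the corresponding coefficient at 0, with a warning).  The fitted row
set is recorded, making leakage assertable: perturbing any row outside it
must reproduce the model bit-for-bit.

## Classification and metrics

Reference classifier: linear soft-margin SVM.  It is fit through
scikit-learn's `SVC` on a precomputed linear Gram matrix — mathematically the
same model as `SVC(kernel="linear")`, but the n × n Gram is computed once per
outer fold and sliced inside the inner loop, which is orders of magnitude
cheaper than refitting primal solvers when features (~10^4) vastly outnumber
subjects (~10^2–10^3).  Hyperparameter search: nested CV over nine
log-spaced C values (1e−4 … 1e4), inner k = 5 stratified folds, selecting the
C maximizing mean inner balanced accuracy, ties to the smallest C (strongest
regularization).  No feature scaling is applied beyond image z-normalization
and no class weighting is used; both choices are recorded in report
provenance.  A deep two-stream CNN variant is out of scope; the linear SVM is
the reference model for every benchmark.

Metrics per outer fold: sensitivity, specificity, balanced accuracy
(= their mean, exactly, recomputable from the stored confusion counts), and
the rank-based AUC (Mann–Whitney: fraction of case/control pairs ranked
correctly, ties ½; cross-checked against `sklearn.roc_auc_score`).  Reports
carry per-fold tables, aggregate mean ± SD, and provenance (strategy, ComBat
flag, seed, config hash); identical configurations reproduce reports
bit-for-bit.

## Scenario design

Benchmark conditions are fixed at 10 sites × 60 subjects, icosphere level 3
(642 vertices/hemisphere — the subdivision family that scales unchanged to
fsaverage6-like resolutions), 64 × 64 equal-area images, thickness maps for
both hemispheres (8,192 features), noise SD 1.  Site-effect magnitudes are
scenario constants, not estimates of any real dataset:

* **null**: site maps of SD 0.5 everywhere, case ratio exactly ½ per site
  (`balance_cases`), no diagnosis effect.  Exact balance matters: with
  Bernoulli draws the *realized* per-site case ratios deviate by ~±6% at
  n = 60, and a classifier that identifies sites (easy, with thousands of
  pixels) genuinely exploits that finite-sample association — a miniature of
  the very confound under study.  The balanced draw is the same control
  design as balancing case ratios within every site in a real analysis.
* **confound**: no diagnosis effect, but per-site case probability
  (0.2 → 0.8) increases with per-site additive-effect SD (0.3 → 1.5).
  Demographic profiles stay heterogeneous across sites but are assigned in a
  fixed scrambled order, decorrelated from case probability — otherwise the
  scenario would also contain a case–age confound, a different phenomenon
  that covariate-*preserving* harmonization is explicitly not meant to
  remove.  Expected behaviour: mixed-site folds inflate balanced accuracy by
  well over 0.05; whole-site folds sit at chance; ComBat collapses the gap.
* **power**: diagnosis effect of {0, 0.5, 1.0, 1.5} × noise SD on a 20% cap;
  accuracy must be monotone and high at the top amplitude.
* **recovery**: 2 × 100 subjects, equal age distributions (so the
  pre-harmonization slope is not site–age confounded), distinct
  location/scale effects; ComBat is fitted on 200 vertex columns and judged
  on parameter recovery and slope preservation.  Slope preservation is
  evaluated on features whose true slope exceeds the slope map's RMS, where
  per-feature OLS sampling noise (~1% absolute) is small relative to the
  slope.
* **sex**: two site-effect-free halves of one cohort with a clear sex effect;
  used to compare the two projections on the auxiliary male/female task
  (the cohort is recoded so sex becomes the target and is excluded from
  residualization).

## Numerical choices and edge cases

* One master seed fans out to demographics, effect maps, site effects, noise,
  fold shuffles and inner-CV splits through hashed named streams; derived
  seeds stay below 2^31.
* Ties are broken lexicographically (sites) or toward the smallest value
  (fold index, C), so results are platform-stable.
* Empty/masked pixels: z-normalization statistics use valid pixels only and
  invalid pixels are set to 0 afterwards, keeping normalization
  mask-invariant; ComBat then treats them as constant features and passes
  them through.
* Degenerate inputs fail loudly with specific errors: unseen site at ComBat
  apply time (pointing to reference mode), overlapping train/test sites,
  single-class folds, uncovered subjects in a fold plan, malformed
  morphometry files (with the offending byte offset).

## Known limitations

* The equal-area map is an analytic stand-in for numerically optimized
  area-preserving projections; it shares their defining property, not their
  exact pixel geometry.
* Parametric ComBat only; no nonparametric priors, CovBat, or GAM-based
  harmonization.
* Linear SVM only; conclusions about nonlinear classifiers (which may pick up
  site information that survives location/scale harmonization) are out of
  scope.
* Synthetic maps are band-limited harmonics, far smoother and more
  homogeneous than real cortical data; effect sizes are not calibrated to any
  real cohort.
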