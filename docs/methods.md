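# Methods

`connharm` compares two stages at which ComBat multisite harmonization can be
applied to structural-connectome data: on the edge weights of each subject's
weighted adjacency matrix before any graph analysis ("matrix harmonization"),
or on the five global network metrics computed from unharmonized matrices
("parameter harmonization"). Because the multi-scanner pediatric cohort this
design emulates is not publicly deposited, everything runs on synthetic
cohorts whose structure copies the study's: six scanners with very unequal
sample sizes, children aged 8.00–16.99 years, ~60% male, ~64% mTBI, and
FA-weighted 90-node connectomes thresholded at 0.10.

## The harmonization model

ComBat models feature `v` of subject `j` at site `i` as

    y_ijv = alpha_v + x_ij' beta_v + gamma_iv + delta_iv * eps_ijv

with biological covariates `x` (injury group, age, sex), an additive site
effect `gamma` and a multiplicative site effect `delta` on the error scale.
Estimation follows the standard location/scale recipe: feature-wise least
squares on [site indicators | covariates] with the grand intercept defined as
the site-size-weighted mean of site means; pooled residual variance
`sigma_v^2` (mean squared residual over all subjects); standardization;
per-site means and variances of the standardized data; and, when empirical
Bayes is on, parametric shrinkage across features (normal prior on `gamma`,
inverse-gamma prior on `delta^2`, method-of-moments hyperparameters,
fixed-point iteration of the conditional posterior means to an absolute
tolerance of 1e-4, at most 100 iterations). Adjusted data subtract the site
location, divide by the site scale, and add back the covariate fit, so
biological variance is preserved.

Numerical conventions worth knowing:

* Within-site variances use the 1/n convention (`delta_ddof=0`). This makes
  single-site harmonization the exact identity and maps a pure site shift to
  exactly equal site means. The R reference implementations use 1/(n−1);
  `delta_ddof=1` reproduces them (the cross-check test against
  `sva::ComBat` does exactly that and agrees to ~1e-7).
* Constant features (e.g. an edge absent in every subject) are excluded from
  fitting and passed through unchanged; features fitted exactly by the
  design raise an error, since standardization is undefined.
* Harmonizing twice is exactly idempotent for `eb=False` without covariates.
  With covariates, per-site rescaling of residuals perturbs the refitted
  slopes at O(n^-1/2); with EB, shrinkage bias leaves small residual site
  effects a second pass would remove. Neither is an implementation artifact:
  the reference implementations behave the same way.
* EB shrinkage places each `gamma*` between the raw estimate and the
  cross-feature prior mean; the flat-prior limit (`tau^2 → ∞`) recovers the
  raw estimates and the degenerate prior (`tau^2 = 0`) collapses onto the
  prior mean.

The matrix pipeline vectorizes each subject's lower triangle (4,005 features
for 90 nodes), harmonizes with EB on (thousands of features, tens of
subjects per site — exactly the regime shrinkage is for), reconstructs the
symmetric matrices, and multiplies by the subject's original binary topology:
harmonization drives most originally-zero weights negative, and those must
return to zero before graph analysis. Residual negative values at
originally-present edges (possible but not typical) are clamped to zero and
counted in the run log; under default synthetic conditions the count is zero.
The parameter pipeline harmonizes each global metric in its own
single-feature model with EB off, since with one feature there is nothing to
borrow strength across.

## Global network metrics

Five global parameters per subject, computed from the weighted adjacency
matrix:

* **Density** — fraction of connected node pairs; ignores weights entirely.
* **Global efficiency** — mean inverse shortest-path distance with edge
  length 1/w; unreachable pairs contribute zero.
* **Clustering coefficient** — Onnela geometric-mean form on weights
  normalized by the global maximum; nodes of degree < 2 contribute zero
  (Barrat's form is available via configuration).
* **Modularity** — best weighted Newman–Girvan Q over 10 seeded Louvain
  restarts. A single community has Q = 0 by definition, so the result is
  never negative.
* **Small-worldness** — sigma = (C/⟨C_null⟩)/(L/⟨L_null⟩), with L the
  characteristic path length over the largest connected component
  (unreachable pairs excluded) and null networks built by Maslov–Sneppen
  double-edge swaps (10 attempted swaps per edge) followed by random
  reassignment of the original weight multiset. Degrees and the sorted
  weight multiset are preserved exactly. The published analyses of this
  design normalize against 1,000 nulls; the package default is 100 and the
  test suite uses 50, which stabilizes sigma's mean at the cohort level
  while keeping runs tractable on one CPU.

Whether metrics beyond sigma should be divided by their null means is
ambiguous in how such analyses are usually described; both behaviors are
implemented (`normalize_by_null`), default off (raw values).

Useful exact properties, all asserted in the tests: uniform weight rescaling
leaves C, D, Q and sigma unchanged and scales efficiency linearly; adding an
edge never decreases efficiency or density; nulls preserve degree sequences
and weight multisets exactly; complete graphs have sigma = 1 identically.

## The synthetic cohort generator

Per subject `j` at site `i` and node pair `e`:

    present = backbone_e XOR Bernoulli(flip_i)
    w = clip[0.10, 1]( mu_e + beta_age (age - age_mid) + beta_sex male
                       + beta_group mtbi + u_j + gamma_i + delta_i eps )

with `mu_e ~ N(0.45, 0.08^2)` shared across subjects, noise
`eps ~ N(0, 0.04^2)`, a per-subject global offset `u_j ~ N(0, 0.03^2)`, and
a shared Bernoulli(0.35) backbone topology. Site effects are drawn once per
cohort: `gamma_i ~ N(0, 0.03^2)` (location), `delta_i ~ U(0.8, 1.25)`
(scale), and per-site edge-flip probabilities
`flip_i = 0.02 * exp(U(-log 4, log 4))` (topology). Ages are uniform on
[8.00, 16.99] with `beta_age = 0.006` FA/year; sex and group effects default
to zero. Defaults matter:

* The **topology site effect** (`flip_i`) is what gives density — a
  weights-blind metric — a site effect at all. Real multi-scanner data show
  large density differences by scanner, and edge-weight harmonization leaves
  them untouched (masking restores each subject's original topology), so
  this term is required for the synthetic cohorts to reproduce the central
  contrast between the two pipelines.
* The **per-subject offset** `u_j` represents global individual differences
  in FA beyond age/sex/group. Without it, edge noise averages out over
  ~1,400 present edges and the age correlation of strength-driven metrics
  approaches 1.0; real cohorts of this design report r ≈ 0.16–0.44. With
  `subject_sd = 0.03` the generator lands r(age, efficiency) ≈ 0.4.
* Clipping to (0.10, 1) is counted, and configurations are validated against
  an analytic expected-clip fraction < 0.1%, so the linear generative model
  stays faithful (defaults sit near 2e-4).

`null_config()` switches every site effect off for calibration studies;
`inject_site_effects` adds location/scale effects to an existing cohort
(residuals taken about cross-cohort per-edge means), for recovery tests.

What the generator does **not** emulate: spatially structured scanner
effects (site effects are edge-constant up to noise scaling), distance- or
module-dependent topology, heavy-tailed FA distributions, motion artifacts,
and site–age confounding (available via `site_age_shift`, default off).
Passing tests therefore demonstrate correctness of the estimators and the
qualitative pipeline contrast under a faithful location/scale world, not
performance on real scanner physics.

## Evaluation battery

Per metric and stage: one-way fixed-effects site ANOVA with eta-squared;
all 15 pairwise Welch t-tests, uncorrected, with the proportion significant
at alpha = 0.05; within-site ICC between stages using the two-way mixed,
single-measures, *consistency* form ICC(3,1) — chosen because harmonization
intentionally shifts means, which an absolute-agreement ICC would penalize —
banded as poor (<0.50), moderate (0.50–0.75), good (0.75–0.90), excellent
(≥0.90); ANCOVA (Type II) on site + age + sex + group plus a Welch t-test
for group; pooled Pearson age correlations per stage compared with the
Hittner–Silver–May z for dependent overlapping correlations (Dunn & Clark's
z with the back-transformed average of the two Fisher z's in the covariance
term); and the sample-size-weighted mean of within-site age correlations as
the reference a successfully harmonized pooled correlation should
approximate (raw-r weighting; a Fisher-z-averaged variant exists behind a
flag). All p-values are two-sided; no multiple-comparison correction is
applied to the pairwise follow-ups, deliberately, as the more conservative
screen for residual scanner effects.

Degenerate inputs are surfaced, not silently handled: zero total variance in
an ANOVA, zero between-subject variance in an ICC, |r| = 1 in a Fisher
transform, sites below the minimum size, and single-site ANCOVAs (the site
term is dropped with a warning).

## Expected behavior on default synthetic cohorts

At full cohort scale (n = 484, six sites) every metric shows a strong
unharmonized site effect; after parameter harmonization no metric differs by
site (all p > 0.05, 0/15 pairwise) and pooled age correlations agree with
the weighted within-site reference to within ±0.05. Density is preserved
exactly through the matrix pipeline (per-site ICC = 1.00) because masking
restores each subject's topology. Matrix harmonization reduces edge-level
site variance but leaves metric-level effects metric-dependent —
efficiency improves markedly while clustering can get worse — because
per-edge adjustment noise propagates nonlinearly into triangle intensities
and discrete community structure. Under null site effects the site ANOVA
rejects at the nominal 5% rate.

Two limits of the design are worth stating plainly. First, within-site
consistency between unharmonized and matrix-harmonized values is excellent
for efficiency and density but genuinely low for clustering and modularity
under null-effect synthetic conditions, where those metrics' between-subject
variance is tiny and the ICC denominator is noise-limited. Second, when
topology varies by site, harmonizing edge weights cannot equalize
present-edge-conditional summaries — only metric-level harmonization
removes those effects, which is precisely the comparison's point.

## Problem sizes and determinism

Simulation-backed tests run at Table-1 proportions: the full 484-subject
cohort where the checks need its power (site-effect removal, covariate
preservation, ComBat recovery), a 150-subject version for the matrix
pipeline, 30-node cohorts for fast unit checks, and 1,000 tiny replicates
for type-I calibration. All randomness flows from a single seed through
`numpy` generators; per-subject seeds are spawned deterministically in
manifest order, so every pipeline is bit-reproducible given (cohort, seed,
settings), including Louvain restarts and null-network generation.
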