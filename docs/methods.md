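# Methods

## Model

Each methylation outcome m is modeled independently as a linear mixed
model with a single cluster random intercept,

    y_im = x_i' β_m + α_{j_i m} + ε_im,   α_jm ~ N(0, G_m),  ε_im ~ N(0, R_m),

with α and ε independent. The estimand is the mixed effect
θ_im = x_i'β_m + α_{j_i m}: the sample's expected methylation given its
covariates and latent subgroup, free of measurement error. Outcomes are
assumed to be on the M-value scale, standardized within cancer type, so
that the Gaussian assumptions are plausible and variances are comparable
across outcomes. Cluster labels j_i are shared across outcomes (they are a
property of the patient, estimated once from the full methylation profile),
while β_m, G_m, R_m and the BLUPs are outcome-specific.

## Estimation

**Clustering.** k-means (Lloyd's algorithm, k-means++ seeding, `n_init=10`
restarts, relative tolerance 1e-4, max 300 iterations) on the training
samples using all M outcomes. k is chosen by the gap statistic on a
default grid of 2–15: Gap(k) = mean_b log W*_kb − log W_k with B = 50
reference datasets drawn uniformly over each feature's observed range, the
sd of the reference log-dispersions carrying the √(1+1/B) factor. The
selection rule is Tibshirani's firstSEmax — the smallest k with
Gap(k) ≥ Gap(k+1) − se(k+1) — because it encodes "high gap but not too
many clusters"; a global-max rule is selectable. The reference
distribution is the plain per-feature-range uniform box (not PCA-rotated):
simpler, seeded, and documented, since published gap implementations vary.

**Mixed-model fit.** REML per outcome (chosen over ML because the
parametric bootstrap consumes Ĝ and R̂ and benefits from less biased
variance components). The REML criterion is profiled down to the single
variance ratio γ = G/R and maximized by bounded scalar search over
log γ ∈ [−12, 12] (tolerance 1e-8), with the γ = 0 boundary (OLS) checked
explicitly; Ĝ = 0 is a legal boundary estimate and degenerates the
predictor to regression. β̂ is GLS at the optimum; BLUPs are the shrunken
cluster-mean residuals α̂_j = (n_j γ̂ / (1 + n_j γ̂)) r̄_j. Because the
design and partition are shared across outcomes, X'X, the per-cluster
design sums, and a Woodbury factorization are precomputed once, making
each REML evaluation O(k²p + k³) rather than O(np²); this is what keeps
thousands of per-outcome fits and bootstrap refits cheap. Categorical
covariates use reference-cell coding against the alphabetically first
level; a rank-deficient design or a prediction-time level unseen in
training is an error, never silently dropped.

**CMMP.** Every test observation is its own group of size one. Matched
classification reduces, in that case, to nearest-residual matching:
Î_m = argmin_j (y_nm − x_n'β̂_m − α̂_jm)², ties to the lowest label, and
θ̂_nm = x_n'β̂_m + α̂_{Î m}. Variance-weighting terms in the general
classification criterion are constant across clusters here (common Ĝ_m,
R̂_m) and cannot change the argmin; the criterion function is nonetheless
pluggable. Per-outcome assignments are made independently; the per-sample
consensus (modal) cluster is reported for diagnostics only.

**Parametric bootstrap MSE.** For real data the MSE of θ̂_nm is estimated
by regenerating, B times, training and test outcomes from the fitted
(β̂, Ĝ, R̂) with fresh cluster intercepts — each test observation keeping
its original assignment Î_m — then refitting the mixed model and rerunning
CMMP on each replicate. k-means is *not* rerun inside replicates; the
cluster partition is treated as fixed. Two targets are offered:
`as_written` compares replicate predictions to the original prediction
(predictor variability about the fitted model), and `bootstrap_truth`
compares them to the replicate's own true mixed effect
x_n'β̂_m + α^b_{Î m} (the conventional MSPE target). `as_written` is the
default for fidelity to the procedure as stated; the calibration test uses
`bootstrap_truth`, which is the variant that tracks the directly simulated
MSE (within ~3% at the default configuration in our check).

## Synthetic cohort generator

The generator emulates a two-cancer (CESC + LUAD) 450K-style cohort on the
standardized M-value scale: n = 655 samples, M = 2275 outcomes (reducible;
desk scale uses 50–200), 65 CNA covariates, error variance .9, coefficient
variance .03, c clusters with intercept SD σ, and a "clumpy dependence"
structure in which two blocks of M/4 outcomes each share within-block
intercept covariance .07 (sampled via a shared block factor plus an
idiosyncratic term, never a dense M × M Cholesky). The bias knob b fixes
the number of White samples at exactly round(b·n) (round-half-even); the
remaining samples draw from the renormalized non-White distribution.
Defaults: b = .78, c = 6, σ = .2.

Where the original cohort's empirical covariate distributions are not
available, the generator uses parametric stand-ins, all config-overridable:
CNA levels on {−2,…,2} with P = (.005, .03, .93, .03, .005); age truncated
normal (mean 60, sd 13, range 20–90), standardized inside the truth design
so age does not dominate the signal; stage I–IV with P = (.45, .2, .25, .1);
P(CESC) = 254/655 with CESC always female and LUAD 45% female; non-White
mass split Black .55 / Asian .35 / AI-AN .06 / NHPI .04. These were
calibrated once so that Var(y) ≈ 1.1 and the signal-to-noise ratio
Var(Xβ)/R ≈ 0.2–0.3, consistent with outcomes that are standardized to
unit variance yet carry error variance .9. The train/test split puts all
LUAD samples plus 70% of CESC samples in training; the CESC hold-out is
stratified by race so small minority groups stay represented on both sides
(a plain random split is selectable).

**Non-PSD block covariance.** For σ ∈ {.1, .2} the nominal block
covariance .07 exceeds σ², which is not a valid covariance structure. The
default clamps the block covariance to .99·σ² with a warning (preserving
the σ grid while keeping a proper Gaussian model); a strict mode raises
instead, and a "correlation" mode reads .07 as a correlation (τ = .07·σ²).
Block membership is deterministic (the first 2·(M/4) outcome indices) for
testability, and configurable.

What the generator does **not** emulate: beta-scale (0,1) measurement
noise and its heteroskedasticity, probe-level artifacts, batch effects,
linkage between CNA features, or covariate-dependent cluster membership
(clusters are uniform and independent of covariates). Passing tests
therefore certify the estimator's behavior under the stated model, not
performance on raw array data.

## Experiment harness and problem sizes

The simulation study varies one parameter at a time around the default
configuration (b = .78, c = 6, σ = .2, k = 6) and compares (i) k-means +
CMMP, (ii) regression prediction (OLS, same design), (iii) the naive
estimate y_nm itself, and (iv) oracle CMMP fitted on the true training
labels. Metrics: MSE against the true mixed effect over test cells, the
same restricted to racial-minority samples (race ≠ White), and the
adjusted Rand index of train and (consensus) test cluster assignments
against truth. The package's default experiment scale is M = 100 outcomes
and 30 replicates per cell — the qualitative orderings are already stable
there — with full-scale settings one config flag away.

## Numerical notes and edge cases

- Identical config + seed reproduces datasets and pipelines bit for bit;
  stage seeds derive from one master seed via
  `SeedSequence(master, spawn_key=(stage, counter))`, so adding a stage
  never perturbs earlier draws.
- A single cluster fixes Ĝ = 0 (not identifiable); k = 1 CMMP, Ĝ = 0
  CMMP, and regression then coincide.
- Ties (classification, consensus, nearest centroid) resolve to the lowest
  label. Correlation pruning removes, among highest-degree features, the
  one with the larger mean |r|, then the later input position — greedy and
  deterministic; it matches exhaustive maximum-independent-set search on
  small instances but carries no optimality guarantee.
- "Top 15% variance" is implemented as ≥ the linear-interpolation 85th
  percentile; the SD filter keeps features with SD ≥ .2 (closed threshold);
  the correlation filter uses |r| > .7 (anti-correlated features are
  equally redundant), with a signed option.
- Mixed-model non-convergence is flagged on the fit, not raised; bootstrap
  replicates that fail to converge are dropped with a count (warning above
  10%).

## Known limitations

Single random intercept per outcome (no random slopes, crossed effects, or
multivariate outcome covariance in estimation — the generator's clumpy
dependence is deliberately *not* exploited by the fit); matched CMMP only
(test samples assumed to come from a training cluster); prediction
requires the observed noisy outcome y_nm, so the method denoises rather
than forecasts; at very weak cluster signal the estimated clustering is
close to arbitrary and CMMP's advantage over regression is small (its
safety in that regime rests on Ĝ shrinking toward 0).
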