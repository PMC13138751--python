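# Methods

`phylohand` implements a Bayesian phylogenetic comparative meta-analysis of
population-level primate handedness. Two response variables are analysed:
MHI (mean handedness index, the direction of hand preference, in [-1, 1])
and MABSHI (mean absolute handedness index, the strength of preference
regardless of direction, in [0, 1]). The meta-analytic unit is one published
tube-task measurement for one species, with its standard error.

## The model

Record *k* reports effect size *y_k* for species *s(k)* from study *g(k)*
with known sampling standard error *se_k*:

    y_k ~ Normal(eta_k, se_k^2)
    eta_k = x_{s(k)} · beta + a_{s(k)} + u_{s(k)} + b_{g(k)}

* `beta` — fixed effects of species covariates (intercept included), prior
  Normal(0, 1) per coefficient. Responses live in [-1, 1], and continuous
  predictors are standardized, so this is weakly informative.
* `a ~ MVN(0, sigma_p^2 C)` — phylogenetic species effects; `C` is the
  matrix of shared root-to-MRCA path lengths scaled by the maximum
  root-to-tip depth (the expected trait correlation under Brownian motion;
  unit diagonal for ultrametric trees, < 1 on the diagonal for fossil tips,
  where less evolutionary time has accrued).
* `u ~ iid Normal(0, sigma_s^2)` — non-phylogenetic species effects
  (niche/environment effects independent of shared ancestry).
* `b ~ iid Normal(0, tau^2)` — study effects; `tau^2` is the between-study
  heterogeneity of true effects.
* Priors on all three standard deviations: half-Cauchy(0, 0.05) —
  nonnegative, concentrated near zero, heavy-tailed.

Phylogenetic signal is Lynch's heritability
`h^2 = sigma_p^2 / (sigma_p^2 + sigma_s^2 + tau^2)` (equivalent to Pagel's
lambda in this model class). The known measurement-error variances are
excluded from the denominator because the lambda equivalence holds among
the latent components; the alternative denominator without `tau^2` is
available via `lynch_h2(include_tau=False)`. Bayesian multilevel R² is
reported in two flavours: `fixed_only` (variance of `x·beta` against all
latent components plus mean squared measurement error) and `conditional`
(variance of `eta` against mean squared measurement error). Which of the
two a published analysis reports is often ambiguous, so both are exposed.

## Posterior computation

Sampling is a collapsed Metropolis-within-Gibbs scheme, all blocks exact:

1. `(sigma_p, sigma_s)` — joint random-walk Metropolis on the log scale
   against the marginal likelihood with `beta` *and* both species-effect
   blocks integrated out (the marginal covariance is
   `sigma_beta^2 XX' + sigma_p^2 C_rec + sigma_s^2 J_rec + diag(se^2)`).
   Conditioning on the effects instead produces the well-known pathological
   coupling between scales and effects and was measurably too sticky.
2. `beta | sigma, b` — closed-form Gaussian with species effects collapsed.
3. `(a, u) | beta, sigma, b` — one joint Gaussian draw (their separate
   conditionals are strongly negatively coupled within species).
4. `tau` — stepping-out slice sampling on `log tau` against the marginal
   with study effects integrated out (a rank-1 Sherman–Morrison identity
   per study), then `b | tau` in closed form.
5. A cheap conditional slice refresh of `sigma_p`, `sigma_s` given the
   drawn effects supplements step 1.

Default settings replicate the source analysis (2 chains, 12,000
iterations, 4,000 warmup, no thinning); `TEST_SETTINGS` (2 chains × 1,500
retained draws) is used throughout the test suite. Convergence diagnostics
(rank-normalized split R-hat, bulk/tail ESS) are implemented directly and
cross-checked against ArviZ in the tests. Variance components can be pinned
(`fit(fixed={"sigma_p": 0, ...})`), which degenerates the model to
closed-form-checkable conjugate cases.

Numerical choices: `C` gets diagonal jitter 1e-8 before factorization
(zero-length branches); slice sampling uses width 0.5 with stepping-out;
the MH log-step is 0.25. Pointwise log-likelihoods are stored per draw for
LOO.

## Imputation

Missing IMI (intermembral index) and DIM (body-mass dimorphism) values are
imputed by maximum-likelihood multivariate Brownian motion with body mass
as the auxiliary trait: the joint distribution of all species × trait cells
is `MVN(1 ⊗ mu, C_time ⊗ R)` with `R` the evolutionary trait covariance
per unit branch length, optimized in a log-Cholesky parameterization
(L-BFGS-B, moment-based start, bounded log-diagonal). Missing cells get
their conditional expectation; conditional variances are reported but not
propagated downstream (two-step workflow — a documented limitation).
Imputation runs on log10-transformed traits on the MCC tree only, and the
completed table is reused across the whole tree set.

## Model selection and reduction

The eco-evolutionary hypothesis battery is a YAML file of named covariate
sets — data, not code. Each applicable hypothesis is fitted across the tree
set; reported values average the per-tree posterior summaries (not pooled
draws; pooling is available via `pool_draws=True`). Hypotheses with at
least one credible predictor (95% CI excluding zero) are compared by
PSIS-LOO; Pareto-smoothing uses `arviz.psislw`, and any record with shape
diagnostic k > 0.7 is re-evaluated by an exact refit without that record.
Two models are declared indistinguishable when |Δelpd| < 4 and < 2·SE(Δ).

Model reduction removes one predictor at a time: among the non-credible
predictors (a categorical predictor counts only if *every* dummy level is
non-credible), the one with the smallest strongest-level |median|/sd is
dropped, and the model refitted, until every remaining predictor is
credible (possibly an intercept-only model). The removal trace is recorded.

## Outlier test and fossil prediction

For a species excluded from fitting, the posterior predictive of its
response conditions the Brownian process on the fitted species effects per
draw: `a* | a ~ Normal(C_fo C_oo^{-1} a, sigma_p^2 (C_ff − C_fo C_oo^{-1}
C_of))`, then adds fixed effects (covariates transformed with the *fit's*
stored constants), a fresh non-phylogenetic effect `u* ~ N(0, sigma_s^2)`,
and measurement noise at the target's pooled standard error. An observed
value outside the 95% predictive interval flags the species as a
phylogenetic outlier. Fossil taxa on a grafted tree are predicted jointly
(one conditional Gaussian draw across all fossil tips per posterior draw);
their diagonal entries of `C` are < 1, so fossil predictives are tighter
than extant ones at the same topological position. Predictions are *not*
truncated to the response bounds (the fitted likelihood is an unbounded
Gaussian); a fossil's "human-level" standard error defaults to the
precision-weighted pooled SE of the focal species' records.

Design choices left open by the source description, resolved here:
grafting uses the MCC tree of the input set as the "consensus" phylogeny;
fossil predictions condition jointly rather than per-taxon; the study
random effect groups by publication (switchable to publication × species);
imputation operates on the log10 scale.

## The synthetic world

The generator emulates the real corpus with known ground truth:

* Trees: birth–death (birth 0.2/My, death 0.05/My) conditioned on 41
  extant tips, scaled to a 40 My root depth (anthropoid-crown scale). The
  simulator's terminal zero-length cherry is removed by extending all tip
  edges by one draw of the inter-event waiting time.
* Covariates: continuous traits as Brownian motion on the tree around a
  shared "size" axis (body mass ~0.3–60 kg, ECV correlated with mass, IMI
  around 95, dimorphism around 1.3); diet proportions via logistic-BM;
  categorical traits via a symmetric Markov switch (rate 0.03/My) along
  branches.
* Records: species means `x·beta + a + u` with `sigma_p = 0.30`,
  `sigma_s = 0.20`, `tau = 0.15` — a generative h² of 0.59, inside the
  reported anthropoid range (0.48 direction, 0.66 strength), with a
  species-mean spread (±0.3–0.4) matching published forest plots. Studies
  per species uniform on {1..4} and individuals per study uniform on
  {8..32} give an expected total of ~2,050 individuals, matching the
  ~2,000-individual scale of the real corpus; per-study
  `se = 0.6 / sqrt(n)` spans the magnitudes implied by published study
  sizes. Responses are clipped to their bounds with every clip event
  logged (< 2% of records under defaults, so the Gaussian likelihood
  remains a fair approximation).
* An optional outlier species receives a fixed post-hoc shift; masking for
  the imputation stage is completely at random per trait and never touches
  body mass.

What a green test on this world does *not* establish: the generator has no
publication bias, no correlated missingness, no within-species repeated
individuals across studies, exact Gaussian effects rather than bounded
ones, and covariates evolved under pure BM — real comparative data violate
all of these to some degree.

## Known limitations and measured behaviour

* **Prior-induced h² shrinkage.** With 41 species, the half-Cauchy(0, 0.05)
  prior on `sigma_p` is informative when the true phylogenetic SD is ~0.3
  (6× the prior scale): across 40 synthetic replicates the mean
  posterior-mean h² is ~0.40 against a generative 0.59, and `sigma_p`'s
  95% CI covers truth ~80% of the time. The identical experiment with
  prior scale 1.0 recovers `sigma_p` and h² essentially unbiased, so this
  is prior shrinkage, not a sampler defect. Users fitting data with
  substantial phylogenetic variance should check sensitivity via
  `prior_sd_scale`.
* **Outlier-test power.** The test is well calibrated (~5% false flags in
  no-outlier worlds), but a +0.7 shift on one tip is detected in only
  ~55–80% of replicates at the default world: the response bounds clip
  part of the injected shift (~20% of shifted records; mean realized shift
  ~0.66), and the predictive spread for a new tip — conditional
  phylogenetic SD plus the irreducible `sigma_s` plus measurement error —
  is comparable to the shift itself. A human-scale singularity sits just
  past the detection margin, which is consistent with it being remarkable
  in the first place.
* Imputation uncertainty is not propagated into the meta-analytic fits.
* PSIS-LOO inside the battery runner reports without exact refits (the
  flagged records are listed); refits are available through
  `PhyloMetaResults.loo(refit=True)`.
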