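# Methods

## The model

`abundint` fits directed multispecies interaction models to repeated
detection/non-detection surveys.  A study visits `I` sites on `J`
occasions; each occasion may consist of `K` subsamples (e.g. seven daily
intervals within a weekly occasion), and the data for an abundance-state
species are the per-occasion counts `y[i,j] ∈ {0..K}` of subsamples with a
detection.

Each species contributes two submodels:

**Abundance state (Royle–Nichols).**

    N_i   ~ Poisson(λ_i),            log λ_i   = x_i' β
    p_ij  = 1 − (1 − r_ij)^{N_i},    logit r_ij = w_i' α
    y_ij  ~ Binomial(K, p_ij)

Heterogeneity in site-level detection `p` is driven by latent abundance
`N`, which is what makes `N` estimable from detection/non-detection data.

**Occupancy state (MacKenzie).**

    z_i  ~ Bernoulli(ψ_i),   logit ψ_i = x_i' β
    y_ij ~ Bernoulli(p_ij · z_i)

**Interactions.**  A directed edge `A → B` adds an abundance-mediated term
to one of B's linear predictors:

    … + γ0 · N_i^A + γ1 · N_i^A · x_i

so the occupancy or abundance of B depends on the *latent abundance* of A,
optionally modulated by an environmental covariate.  The graph must be
acyclic and its directionality declared a priori (dominant → intermediate
→ subordinate).  Year-specific intercepts (dummy coding, first year as
reference) can be enabled on every submodel for multi-year designs.

**Co-occurrence comparison variant.**  `as_occupancy_mediated(graph)`
produces the classic presence/absence alternative: every species that
sources an edge is re-declared as an occupancy state and interactions
enter as `γ0 · z^A`.  We implement the comparison this way — rather than
keeping the source's abundance model and thresholding `1{N>0}` inside the
linear predictor — because it is the model a practitioner would actually
fit when "modeling interactions as a function of occupancy", and because
the thresholded-R–N hybrid measurably overstates the comparison's error
(|mean RB| ≈ 0.42 instead of ≈ 0.30 at λ_D = 0.5) by retaining abundance
information the occupancy framing is supposed to lack.

## Sampler

Inference is by Metropolis-within-Gibbs, one systematic sweep per
iteration:

1. **Latent states** are drawn from their exact full conditionals by
   categorical draws: for abundance states the support is `0..N_max`
   (default 30, raised to `10·⌈λ̂⌉` when a naive occupancy-based guess of
   λ is large), with the unnormalized mass at each candidate including the
   Poisson prior, the site's binomial observation terms, and the state
   densities of every downstream species in which the candidate value
   appears.  A detection at a site makes `N = 0` (or `z = 0`) a structural
   zero.  Enumeration stops early once the log-mass falls 34 nats below
   the running maximum while decreasing; the neglected tail (< e⁻³⁰
   relative mass) is far below every tolerance used in the tests.
   Truncation is monitored: any update in which the weight at `N_max`
   carries more than 1e-6 of the conditional mass is counted and reported
   as a fit warning.
2. **Coefficients** take one adaptive random-walk Metropolis step each
   (Gaussian proposals, per-parameter scales), with independent
   Normal(0, 2.5) priors on the link scale — a standard weakly-informative
   choice for logit/log regressions, user-overridable.
3. **Ridge moves.**  For every interaction edge one extra joint proposal
   shifts the target-submodel intercept and the edge's γ0 in opposite
   directions.  When the source species is present at most sites these two
   parameters are nearly collinear and per-parameter walks stall (we
   measured ESS ≈ 13 for the pair in the co-occurrence variant at
   λ_D = 2); the joint move restores ESS > 1000 at negligible cost.

Proposal scales adapt toward 0.44 acceptance by Robbins–Monro updates
during burn-in only, so the post-burn-in kernel is fixed and valid.
Chains are initialized overdispersed: `N` at the detection indicator plus
Poisson(1) jitter, `z` at the detection indicator, coefficients from
N(0, 1), per chain.

**Site-collapsed updates.**  When every submodel is intercept-only (no
covariates, year dummies or interaction modifiers), two sites with equal
sufficient statistics `(Σ_j y_ij, Σ_j K)` and equal neighbouring latent
states have *identical* full conditionals, and equal likelihood terms.
The kernel then computes one conditional per equivalence class per sweep
and draws each site from its class table, and pools likelihood sums over
classes inside the Metropolis steps.  This is an exact computational
equivalence: the collapsed path performs the same arithmetic on
representative sites and consumes the random stream in the same order, so
chains are bit-identical to the generic path (asserted in the test
suite).  It is what makes the replicated simulation studies cheap — a
three-chain fit of the two-species design at 600 sites takes a few
seconds.  Models with covariates (e.g. the case-study structure) fall
back to the generic per-site path automatically.

**Chain lengths.**  The desk-scale default is 3 chains × 6,000 iterations
with 1,000 burn-in and thinning 5 (3,000 retained draws), which gives
R̂ upper bounds comfortably below 1.1 and ESS in the hundreds-to-thousands
for the study designs shipped here.  `McmcConfig.paper()` provides the
long-run preset (3 × 50,000, burn-in 20,000, thin 18, ≈ 5,000 retained)
for full-scale replication.

## Diagnostics and summaries

- **R̂**: classic Gelman–Rubin potential scale reduction factor with the
  Brooks–Gelman 97.5% upper bound (the implementation reproduces R's
  `coda::gelman.diag` to 1e-6; a test checks this against `Rscript`).  A
  fit is *converged* only if every parameter's upper bound is < 1.1; with
  a single chain R̂ is reported unavailable.
- **Point estimates**: posterior mode, computed as the midpoint of the
  highest bin of a fixed 512-bin histogram over the pooled draws —
  deterministic and testable, where a kernel-density argmax would not be.
  Means, sds and equal-tailed 95% credible intervals (empirical 2.5%/97.5%
  quantiles) accompany it.  Equal-tailed rather than HPD intervals are a
  deliberate choice and are what the coverage computations use.
- **ESS**: bulk effective sample size via arviz.
- **Posterior predictive checks**: Pearson χ² discrepancy
  `Σ (y_ij − E[y_ij|θ])² / (Var[y_ij|θ] + 0.5)` over sampled cells, with
  moments conditional on the draw's latent states, against replicate data
  simulated from the same draw; reported as the Bayesian p-value
  `P(T(y_rep) ≥ T(y_obs))`.  The +0.5 variance floor stabilizes cells with
  tiny variance.  Calibration under the truth is good (p-values
  concentrate well inside (0.05, 0.95)), but this latent-conditional
  discrepancy has essentially **no power against interaction
  misspecification**: fitting a no-interaction model to strongly coupled
  data moved the p-value by ~0.01 in our experiments, because the latent
  states absorb the unmodelled heterogeneity.  Treat a clean PPC as "the
  observation model is not contradicted", not as evidence the interaction
  structure is right.

## Simulator and study presets

`simulate_dataset` draws covariates (independent standard Normal per
site), then species states in topological order using the realized
upstream abundances, then observations.  Three preset families mirror the
simulation studies:

- **Comparison preset** (`preset_study1(λ_D)`): two species, I=600, J=4,
  K=1, r_D=0.3, p_S=0.5, mean ψ_S=0.75, γ0=−1, λ_D ∈ {0.5, 1, 2}.  K=1
  reflects plain detection/non-detection occasions.
- **Effort preset** (`preset_study2(I, J, varying)`): r_D=0.5, p_S=0.5,
  λ_D=1, mean ψ_S=0.5, γ0=−1; `varying` adds γ1=1 on an independent
  standard-Normal modifier.
- **Three-species preset** (`preset_study3(r_D, p_S)`):
  abundance–abundance–occupancy chain, λ_D=0.5, mean λ_I=0.5, mean
  ψ_S=0.5, edges D→I=−1, I→S=−1, D→S=+1, r_I fixed at 0.5, I=600, J=4.
- **Case-study-shaped preset** (`preset_casestudy_synthetic()`): 195
  sample units × 3 years (13 units unsampled in year 2), J=3 weekly
  occasions of K=7 daily subsamples, three abundance-state carnivores
  with year intercepts on every submodel.  All true values are synthetic
  defaults chosen for plausibility; they are not estimates from any real
  dataset.

Where a preset pins a *mean* occupancy or abundance for a downstream
species, the state intercept is solved so that the scenario-average of
the inverse-link over the covariate and upstream-abundance distribution
hits the target (Monte Carlo with a fixed internal seed, 200,000 pseudo
sites; brentq for logit means, closed form for log means).  The solved
intercept is recorded as the truth that bias and coverage are computed
against.

What the simulator deliberately does **not** emulate: spatial
autocorrelation in covariates or states, open-population dynamics (the
closure assumption is taken at face value), false positives, and
individual detection heterogeneity beyond abundance.  Passing recovery
tests therefore show the estimator is correct *under the model's own
assumptions*, not that those assumptions hold in field data.

## Study harness

`run_study` simulates `n_reps` datasets (seeds `base_seed + k`), fits the
requested variants, discards fits in which any parameter's R̂ upper bound
is ≥ 1.1 (the filter applies jointly per fit), and evaluates posterior
modes against the generating truths: relative bias `(θ̂−θ)/θ` (absolute
bias when θ=0), equal-tailed 95% CrI coverage (boundary counts as
covered), and a Type S / Type M classification with an unbiasedness
threshold of ±0.05.  Because "mean relative bias" can be read as the
signed mean or the mean magnitude, the summary table carries `mean_rb`,
`|mean_rb|` (`abs_mean_rb`, the quantity compared against reported
values) and `mean_abs_rb`, plus a Monte Carlo standard error so
reduced-replicate runs can be compared against full-scale numbers.

Default scale is 25 replicates with the desk MCMC preset; the acceptance
script (`scripts/acceptance.py`) runs three experiments at that scale in
a few minutes on one CPU.

## Numerical conventions

- Probabilities inside log-densities are clamped to [1e-12, 1−1e-12];
  the structural zeros (detection with N=0 or z=0) are exact −∞.
- Log/logit links throughout; no complementary-log-log option.
- Posterior-mode ties break toward the lowest bin; categorical draws use
  inverse-CDF with a single uniform per site.
- Coefficient proposals with non-finite log-likelihood are rejected,
  never fatal; a latent conditional losing all mass aborts the chain with
  site context and flags the fit unusable.
- All randomness flows from explicit seeds: chain c uses `seed + c`, and
  the harness derives per-replicate simulation and MCMC seeds from
  `base_seed` (all below 2³¹).

## Known limitations

- Detection covariates are site-level (constant across occasions within a
  site); occasion-varying detection designs are out of scope of the fast
  path and the current compiler.
- Occupancy-state species use a Bernoulli observation per occasion; a
  binomial-over-K occupancy observation model is not provided.
- No marginalized-likelihood/HMC backend, no model averaging, no
  WAIC/DIC model selection; alternative hypotheses are expressed as
  alternative graphs and fit separately.
- The latent-conditional PPC is weak against structural misspecification
  (see above).
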