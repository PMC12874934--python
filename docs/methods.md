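# Methods

## The model

`districtsae` estimates district-level prevalence of a binary survey
outcome — women's participation in household decision-making, coded 1 if a
woman decides alone or jointly with her husband/partner in any of three
domains (own healthcare, large purchases, visits to family) — from a
nationally sampled household survey whose direct district samples are too
small for reliable direct estimation. It does so with a four-level
random-intercept logistic model for woman *i* in cluster (primary sampling
unit) *j*, district *k*, state *l*:

    logit P(Y_ijkl = 1) = β₀ + u_jkl + v_kl + f_l
    u_jkl ~ N(0, σ²_u0),  v_kl ~ N(0, σ²_v0),  f_l ~ N(0, σ²_f0)

No covariates enter the model, and because the outcome is binary the
individual-level variance is fixed, not estimated. The variance
partitioning coefficient (VPC) for a level is its share of the total
geographic random-effect variance,
`100 · σ²_level / (σ²_u0 + σ²_v0 + σ²_f0)`; the individual-level term is
deliberately absent from the denominator (no π²/3 latent-logistic term),
so the three VPCs always sum to 100.

Small-area ("precision-weighted") estimates are formed in two steps:
posterior residuals are pushed through the inverse logit to give shrunken
cluster prevalences `100·expit(β₀ + u + v + f)`, and cluster prevalences
are averaged — unweighted, by default — within districts. Shrinkage is
automatic: a cluster with little data contributes a residual pulled toward
zero, so its prediction collapses toward the district/state baseline,
while a large cluster's prediction approaches its raw proportion.

## Sampler

A single chain combining:

- **random-walk Metropolis** updates for β₀ (flat improper prior) and for
  every residual. Residuals at one level are conditionally independent
  given the rest, so each level is updated as one vectorised block of
  independent scalar moves. Because there are no covariates, all women in
  a cluster share one linear predictor and the likelihood reduces to
  per-cluster binomial sufficient statistics — this is what makes desk-scale
  fits take seconds.
- **conjugate Gibbs** draws for the three variances from
  Inverse-Gamma(a + n/2, b + Σr²/2), default prior a = b = 0.001 (the
  convention of the multilevel-MCMC software family this model class is
  usually fitted with). Any variance can instead be pinned with
  `ModelConfig.fix_sigma2` (used by the oracle and shrinkage tests).
- **recentering sweeps**: exact Gibbs moves that translate mass between
  adjacent levels (β₀↔states, states↔districts, districts↔clusters) while
  leaving every linear predictor unchanged. These are conjugate normal
  draws in the centred parameterisation. They were added after profiling
  showed the classic centering pathology: with pure single-site updates the
  intercept's effective sample size was ~10 per 5,000 draws and the state
  variance absorbed intercept drift; with the sweeps the intercept ESS is
  ~3,900 per 5,000 draws.

Proposal scales adapt by Robbins–Monro (step `min(0.1, t^{-1/2})`) toward
44% acceptance during burn-in only and are frozen afterwards, so the
monitored chain is a valid time-homogeneous Markov chain (the frozen
scales are asserted in the test suite). Defaults follow the model family's
common practice: burn-in 1,000, 25,000 monitored iterations, thinning 1.
Starting values are deterministic: β₀ at the overall empirical logit,
residuals at zero, variances from an empirical-logit variance
decomposition across units at each level, floored at 0.01 — a cheap
deterministic stand-in for a quasi-likelihood pre-fit; starting values
only affect burn-in length.

Convergence is monitored through the effective sample size
`ESS = n / (1 + 2Σρ_k)` with Geyer's initial-positive-sequence truncation
of the autocorrelations; parameters with ESS below 250 (configurable) are
flagged as unreliable. Constant series are reported as ESS 0 with a
warning.

During development the sampler was cross-checked against an independent
MCMC implementation of the identical model and priors on an 8×6×8×30
instance; posterior means and credible intervals of β₀ and all three
variances agreed within Monte Carlo error. The shipped test suite instead
checks the sampler against a deterministic quadrature oracle (dense grid
over β₀, Gauss–Hermite over each cluster effect) on a two-level toy, which
is exact and fast.

## District intervals and change classification

District 95% credible intervals are percentile intervals of the per-draw
district means (every cluster prevalence recomputed at each stored draw,
averaged within district). The point estimate defaults to the plug-in rule
(posterior-mean residuals through the inverse logit), mirroring the
two-step procedure described above; per-draw averaging is available
(`point="perdraw"`) and is the statistically cleaner alternative. The two
agree within ~1–2 percentage points on well-mixed fits; because they can
disagree slightly, `ci_low ≤ prevalence ≤ ci_high` is not an enforced
invariant of the plug-in estimate.

Two-round comparison: decile thresholds are the 10th–90th percentiles
(linear interpolation) of the baseline district distribution and are
reused to classify the follow-up round, with right-closed bins so boundary
values fall in the lower bin and out-of-range follow-up values land in
bins 1/10. Percentage-point changes map onto seven categories with
continuous half-open boundaries — ≤−10, (−10,−5], (−5,−2.5], (−2.5,2.5),
[2.5,5), [5,10), ≥10 — the two-decimal bin labels usually printed with
such maps (e.g. "−9.99 to −5.00") are rounded renderings of these
boundaries, and the chosen closures make the bins a partition of the line.
Districts present in only one round are excluded from change records and
logged.

## Synthetic data generator

The generator emulates a DHS-style state-module sample: a balanced
hierarchy (defaults 10 states × 8 districts × 10 clusters × 20 women),
normal random intercepts with default variances 0.54 (state), 0.16
(district), 0.94 (cluster) on the logit scale, an intercept of
logit(0.84) ≈ 1.6582 so the national prevalence is near 84%, lognormal(0,
0.25) sampling weights (only positivity matters downstream), uniform ages
15–49, ~29% of rows flipped to not-currently-married (the eligibility
filter's main exclusion share), and 2 cluster ids rewritten so they are
absent from the crosswalk.

The composite outcome is drawn directly as Bernoulli(expit(β₀+u+v+f)), so
the fitted model holds exactly for the analysed outcome; the three domain
responses are then generated consistently with it. A participating woman
participates in each domain independently with probability
`domain_correlation` (default 0.8; one domain forced if all three would
fail), a non-participating woman participates in none. This reproduces the
qualitative pattern of real data — per-domain prevalences a little below
the composite, domains strongly but not perfectly aligned — and guarantees
the coding rule `outcome_any = 1{any domain ∈ {self, joint}}` on every
row. The split of participation into "self"/"joint" (0.35/0.65) and of
non-participation into husband/someone-else/other (0.85/0.10/0.05) is
cosmetic for the pipeline. One master seed drives independent sub-streams
for effects, outcomes, domains and perturbations, and the generator is
bit-reproducible.

What the generator does **not** emulate: informative sampling weights
(weights are independent of the outcome), unbalanced cluster sizes beyond
those created by the eligibility filter, spatial correlation between
neighbouring districts, non-normal random effects, item missingness, and
survey recode-file layouts. Passing tests therefore demonstrate correct
recovery under the model's own assumptions, not robustness to their
violation.

## Problem sizes and numerical choices

The test suite fits reduced problems chosen to give stable checks at desk
scale: a shared 40-district fixture (~4.8k eligible women, 500 + 2,500
iterations), ten replicates at the 10×8×10×20 configuration with 1,000 +
5,000 iterations for variance-component recovery, and a 30,000-draw chain
on the two-level quadrature toy. At the recovery configuration the
posterior is honestly diffuse: with only 10 states the realized state
variance of a replicate scatters with ~47% relative SD around its nominal
value, and the diffuse inverse-gamma prior inflates the posterior-mean
summary of a 10-unit variance by roughly S/(S−2) ≈ 25%; recovery is
therefore assessed as unbiasedness of the mean across replicates plus
credible-interval coverage, not per-replicate agreement.

Other numerical conventions: percentile credible intervals (2.5/97.5);
quantiles by linear interpolation everywhere (affects the IQR and decile
cuts at small counts); empirical logits use the (k+½)/(n+1) correction;
degenerate all-0/all-1 outcome vectors are rejected at initialization;
single-woman clusters are allowed (their residuals are simply shrunk
hard); a non-finite chain state aborts with the iteration number.

## Known limitations

- Single chain; no between-chain diagnostics (R-hat). ESS flags are the
  convergence guard.
- The sampler is tuned for the no-covariate model; adding fixed effects
  would require replacing the sufficient-statistic likelihood.
- Survey weights enter only the design-weighted prevalence, not the
  model (unweighted likelihood), mirroring the two-stage practice this
  pipeline reproduces.
- District credible intervals are one defensible construction (per-draw
  district series); other constructions could differ at the margins.
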