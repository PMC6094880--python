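# Methods

## Clinical setting

Juvenile dermatomyositis activity is tracked with four routinely collected
parameters: serum creatine kinase (CK, IU/L), the Childhood Myositis
Assessment Scale (CMAS, 0–52, 52 best), the Manual Muscle Test of eight
groups (MMT8, 0–80, 80 best) and the physician's global assessment of disease
activity (PGA, 0–10 visual-analogue, 0 best). The three clinical scores pile
up at their best value once a patient responds to treatment, so their
distributions are semicontinuous; CK is strictly positive and right-skewed.
`jdmjm` fits a single joint longitudinal model of all four, rather than four
separate models, so that the correlation between parameters and their joint
evolution under treatment can be quantified.

## Outcome transforms

CK is modelled on the natural-log scale. CMAS, MMT8 and PGA are modelled on a
square-root scale oriented so that the best value is a boundary:
`y = sqrt(52 − CMAS)`, `y = sqrt(80 − MMT8)`, `y = sqrt(PGA)`. On these
scales each score has a point mass at 0 (the best value) and a continuous
part on a bounded interval.

## Model

For patient *i*, visit at time *t* (years since diagnosis), outcome
*k ∈ {ck, cmas, mmt8, pga}* with transformed value *y*:

- **CK (continuous):**
  `y = β0_ck + β_t,ck · t + x'(γ ⊙ β_ck) + b_i,ck + s_i · t + ε`,
  with residual ε ~ N(0, σ²_ck) and a patient-specific time slope
  `s_i ~ N(0, τ)`.
- **Hurdle outcomes (cmas, mmt8, pga):** with probability
  `π = logit⁻¹(α0_k + α_t,k · t + α_b,k · b_i,k)` the outcome sits at its
  best value (transformed 0); otherwise it follows a Gaussian
  `N(μ, σ²_k)` truncated to the open continuous support, where
  `μ = β0_k + β_t,k · t + x'(γ ⊙ β_k) + b_i,k`. The hurdle probability loads
  on the same random intercept as the continuous part, linking "how good the
  patient is" to "how likely the score is perfect".
- **Random effects:** the four intercepts `b_i ~ MVN(0, Σ)` with a full,
  estimated 4×4 covariance; their correlations are a primary estimand (e.g.
  the CMAS–MMT8 correlation).
- **Covariates:** binary signs/symptoms at onset, baseline history items and
  time-varying treatment indicators, collected in `x`. A shared spike-and-
  slab indicator `γ_j ∈ {0, 1}` switches covariate *j* in or out of **all
  four** outcome equations at once (all-or-none selection); treatments are
  forced in (`γ ≡ 1`). Posterior inclusion probabilities (PIPs) summarise the
  evidence per covariate.
- **Missing covariates:** cells missing at random are treated as unknowns
  with `x_ij ~ Bernoulli(θ_j)`, `θ_j ~ Beta(1, 1)`, and are imputed inside
  the sampler from their exact full conditional, so selection and effect
  estimates propagate imputation uncertainty.

Priors: Gaussian slab on included effects, Gaussian on intercepts, time
slopes and hurdle coefficients, inverse-Wishart on Σ, inverse-gamma on τ and
half-Gaussian-like (log-scale random-walk updated) residual SDs; see
`ModelConfig` for the hyperparameters.

## Pre-selection

Before the joint fit, each candidate covariate is screened with univariate
linear mixed models (one per outcome, random intercept per patient, time as
fixed effect) via `statsmodels` `MixedLM`. Candidates are ranked by their best
absolute Wald statistic across the four outcomes and the top half is kept;
treatment covariates bypass the screen. The joint model's spike-and-slab then
performs the final selection among the survivors.

## Posterior computation

A Metropolis-within-Gibbs sampler (`GibbsSampler`) sweeps:

1. missing covariate cells (exact Bernoulli full conditional),
2. covariate prevalences θ (Beta),
3. CK fixed effects (conjugate multivariate normal),
4. hurdle-outcome fixed effects (per-coordinate random-walk MH with cached
   truncation constants),
5. inclusion indicators γ (Metropolized add/delete; the slab proposal cancels
   against the prior),
6. hurdle coefficients α (random-walk MH),
7. per-patient random effects, jointly (b_i, s_i) (vectorised random-walk MH),
8. Σ (conjugate inverse-Wishart), τ (conjugate inverse-gamma),
9. residual SDs (log-scale random-walk MH with Jacobian).

Proposal scales adapt during burn-in only; chains are reproducible from a
single seed and runs are bit-identical across repeats. Hot loops (truncated-
normal log-densities and the proposal delta kernels) are `numba`-compiled
when available, with pure-NumPy fallbacks. Convergence is reported via
split-R̂ and rank-normalized ESS on all scalar parameters.

## Validation

- **Likelihood oracles.** `visit_loglik` is checked against an independently
  coded density summation (scipy distributions) and the sampler's internal
  caches against brute-force recomputation. `marginal_loglik_patient`
  (Gauss–Hermite tensor quadrature over the random effects) matches the
  conjugate closed form in the Gaussian-only case.
- **Joint-distribution (Geweke) test.** Marginal-conditional samples
  (prior → data) are compared with a successive-conditional chain
  (resimulate data, one Gibbs sweep, repeat) on ~30 functions of parameters
  and data, using z-tests with rank-normalized ESS in the standard error and
  a Bonferroni 1% level. A single-transition paired variant (one sweep
  applied to an exact joint sample) runs in the fast test suite.
- **Calibration.** On simulated cohorts, the randomized probability integral
  transform (PIT) of each observation under the *marginal* posterior
  predictive (random effects integrated over their population distribution)
  should be uniform; the fraction outside the central 95% band is checked
  against 5%. The per-patient band conditioned on posterior random effects —
  what the pipeline reports for monitoring — is conservative in sample by
  construction. Held-out calibration uses leave-patients-out refits with
  per-draw Bernoulli imputation of the held-out patients' missing covariates.
- **Classification accuracy.** Predicted probabilities of the inactive state
  (CK ≤ cutoff, CMAS ≥ 48, MMT8 ≥ 78, PGA ≤ 0.2) are scored with the scaled
  Brier score, `1 − Brier / Brier_reference`, where the reference predicts
  the observed prevalence everywhere.

## Reproducing the study

The numbered scripts under `analysis/` run the full pipeline on synthetic
cohorts: simulate, pre-select, fit (writing draws, summaries, bands, Brier
scores, correlations and a manifest with file digests), leave-patients-out
evaluation, and the sampler validation suite. `scripts/acceptance.py --seed S
--out out.json` reproduces the headline quantities in one JSON file.
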