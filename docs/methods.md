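# Methods

This note documents the models, algorithms, numerical choices and open design
decisions behind `mabpk`, in the spirit of the methods documentation of
mature statistical packages.  It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Structural PK model (`pk_model`)

An open two-compartment model with first-order elimination from the central
compartment describes mAb disposition; subcutaneous (SC) administration adds
a depot compartment with first-order absorption.  Parameters: CL (L/day),
Vc (L), Q (L/day), Vp (L), F ∈ (0,1], ka (1/day).  Micro constants are
k10 = CL/Vc, k12 = Q/Vc, k21 = Q/Vp; the phase exponents alpha ≥ beta are the
roots of `s² − (k10+k12+k21)s + k10·k21`, with half-lives ln2/alpha
(distribution) and ln2/beta (elimination).

* **IV bolus assumption.**  Intravenous administration is modelled as an
  instantaneous bolus.  The earliest sampling time used is day 1, where a
  short infusion is indistinguishable from a bolus; infusion duration is
  therefore unidentifiable and ignored.
* **Closed forms and oracle.**  Single-dose IV (bi-exponential) and SC
  (tri-exponential) solutions are closed-form; multi-dose kinetics use
  linear superposition.  An independent ODE integrator over the
  depot/central/peripheral/eliminated states (LSODA, rtol 1e-10) serves as a
  verification oracle only; tests require ≤1e-6 relative agreement over 1000
  random parameter draws and check mass balance of the F-adjusted dose.
* **Degenerate absorption rate.**  When ka falls within 1e-10 (relative) of
  alpha or beta the tri-exponential coefficients are singular; ka is nudged
  off the pole by 1e-7 relative instead of switching to the secular
  (t·e^{−αt}) limiting form.  The induced error is O(1e-7), below every
  tolerance used, and the pole set has probability zero under the generator.
* **Units.**  µg/mL ≡ mg/L; doses in mg (mg/kg × body weight); times in days.
* **One-compartment limit.**  k12 = k21 = 0 collapses both phases to k10;
  both half-lives are then reported as ln2/k10.

## Synthetic trials (`synthetic_trial`)

The generator emulates the pooled three-trial design so that every
downstream stage is testable without data access.  Its defaults *are* the
stated study conditions:

* 100 single / 46 combination participants; dose levels 2.5/5/20 mg/kg by IV
  or SC route, once (day 0) or twice (days 0 and 112); serum sampled at days
  1, 3, 6, 14, 28, 56, 84 after the first administration and every 28 days
  (the lower end of the studies' 4–8-week window, fixed for determinism)
  after later ones, to day 168.
* Covariates calibrated to the published baseline table: weight medians
  76/71 kg (ranges (48,114)/(46,109)), 61%/52% female, ages 18–50 with
  median ≈28, creatinine clearance medians ≈120 mL/min obtained from
  generated serum creatinine via Cockcroft–Gault (0.85 female factor).
  Only medians and ranges are published, so weight and creatinine use
  truncated log-normals and age a truncated shifted exponential; matching
  the published medians/ranges — not the unpublished full shapes — is the
  calibration target.  The deliberate group-wise weight/sex imbalance gives
  the causal adjustment real confounding to remove.
* Individual (CL, Vc, Q, Vp) are log-normal around the published population
  estimates with the published random-effect SDs (0.29/0.40/0.57/0.24).  The
  random-effect correlations were modelled but not published; the generator
  default is a modest CL–Vc correlation of 0.3, and the fitter estimates the
  full covariance freely.
* Observed concentrations add combined residual error (sigma_add 0.13 µg/mL,
  sigma_prop 0.14); values below the assay limit (BAMA 0.0457 µg/mL default,
  ELISA 1.0 µg/mL) are flagged below-quantification; values driven negative
  by the additive term are truncated at zero (resampling available).
* Exact per-arm allocation across dose groups is only reported graphically
  in the source trials; subjects rotate deterministically through a
  representative per-group regimen list (configurable).
* `simulate_feature_table` draws PK features directly from the generative
  model (optionally with allometric weight effects, exponents 0.75 on
  clearances and 0.6 on volumes, and a −0.1 log shift on Vc for female sex)
  so the TMLE stage can be calibrated in isolation from popPK estimation
  noise.  The generator's seeding is keyed so that cohort covariate draws and
  PK random-effect draws are independent streams even when the same integer
  seed is supplied to both.

What a green test on synthetic data does *not* establish: agreement with the
real trial data (not redistributable), assay-specific measurement artefacts,
protocol deviations, or dropout — none of which are modelled.

## Population fit (`poppk_fit`)

SAEM with a random-walk Metropolis E-step on the individual log parameters:

* Random effects on CL, Vc, Q, Vp only (log-normal, full covariance); ka and
  F are fixed effects without between-subject variability, mirroring the
  sparse SC data.  Inside the MCMC kernel they carry a small fixed auxiliary
  SD (0.10) so the chain can move them — the standard SAEM device — and only
  their population means are reported.  F is estimated on the logit scale.
* Defaults: 3 chains, 400 exploration iterations (step size 1) + 200
  smoothing iterations (step size k^−0.7), 2 Metropolis sweeps per iteration
  with per-component adaptive proposals targeting ~30% acceptance.
  Exploration applies simulated-annealing floors (factor 0.95 per iteration)
  to the variance components to prevent premature collapse; near-noise-free
  data need a gentler schedule (0.98–0.99), exposed as `anneal`.
* Residual model: variance = sigma_add² + (sigma_prop·ĉ)² — the combined
  form, because the error *variance* is the stated sum of an additive and a
  proportional term.  The M-step maximises the smoothed residual statistics
  over (sigma_add, sigma_prop) directly (Nelder–Mead on the log scale).
* Below-quantification records are discarded by default (the fine assay's
  limit is ~4 orders of magnitude below typical concentrations, so the
  information loss is negligible); a censored-likelihood (M3, normal-CDF
  contribution) mode is available via `blq="censored"`.
* Initial values: naive two-stage (per-subject non-compartmental Vc and
  CL from dose/first-concentration and dose/AUC, F from the SC/IV
  dose-normalised AUC ratio), pooled by medians, with generic mAb fallbacks.
* Uncertainty: %RSE from a stochastic approximation of the Fisher
  information using per-subject conditional scores (Fisher identity) over
  the final smoothing window.  The random-effect-SD scores use a
  marginal-normal approximation, so their RSEs are approximate when
  correlations are strong; confidence intervals in the fit report are Wald
  on the log scale and labelled as such.
* Marginal log-likelihood (for likelihood-ratio pruning) by importance
  sampling with an inflated Laplace proposal at each subject's conditional
  mode (finite-difference Hessian).
* Determinism: one seed drives everything; subjects are processed in sorted-id
  order, so estimates are bit-identical under input row permutation.
* Empirical-Bayes estimates are conditional-posterior modes (MAP) of the four
  structural random effects by L-BFGS, warm-started at the MCMC conditional
  means; a subject without observations shrinks exactly to the population
  values.

## PK features (`pk_features`)

Eleven features per subject from the EB estimates: CL, Vc, Q, Vp,
distribution and elimination half-lives, dose-normalised steady-state AUC,
and predicted concentrations at days 1/28/56/112 after a reference 1.4 g IV
dose (20 mg/kg × 70 kg).  The steady-state dose-normalised AUC is computed
exactly as 1/CL (linear PK over a dosing interval), avoiding pseudo
steady-state simulation; week 16 is evaluated at 112 days (16 × 7).
Trajectory bands evaluate each individual's predicted IV curve on a daily
grid and report pointwise 2.5/50/97.5 percentiles per administration group,
using the EB estimates (a re-simulation mode can be built on
`simulate_trial` if population-level bands are wanted instead).

## Group comparison (`group_compare`)

TMLE of the ATE on each log feature, adjusting for weight, creatinine
clearance, age and sex at birth:

* Outcome regression and propensity score fit by a super learner stacking
  GLM, best-subset-BIC (the stepwise equivalent), random forest,
  piecewise-linear hinge-spline regression (the MARS equivalent),
  cross-validated lasso, and the grand mean, by non-negative least squares on
  10-fold cross-validated predictions.  The substitutions for the R learners
  are recorded in the report metadata.
* Outcomes are min–max scaled to [0,1]; the fluctuation is logistic with
  clever covariates A/g(W) and (1−A)/(1−g(W)).  Because each clever covariate
  vanishes on the opposite arm, the two-dimensional fluctuation separates
  into two one-dimensional Newton solves.
* Propensities are truncated to [0.025, 0.975] (common TMLE practice at this
  sample size; a warning fires if truncation touches >20% of subjects).
* Estimates average 20 repetitions with fresh cross-validation splits drawn
  from one master seed; the propensity fit is shared across features within
  a repetition.
* Inference: participant bootstrap (B = 500), resampling subjects jointly
  with all their features — exactly what preserves the co-variability of
  EB-derived features from a common popPK fit.  Bootstrap replicates use a
  single TMLE repetition each (the 20-run averaging is a stability device
  whose repetition inside every replicate would be computationally
  prohibitive without changing the bootstrap mean).  A full-refit bootstrap
  is intentionally out of scope for the default path.
* 95% CIs are bootstrap percentile intervals (expanded, if ever necessary,
  to contain the point estimate); the p-value is a normal approximation
  using the bootstrap SE of the log ratio, since no specific test is
  prescribed.  Group "means" are geometric — exponentiated adjusted mean
  logs — because the analysis is on the log scale; this is flagged in the
  report metadata.  Holm adjustment runs across the eleven-feature family.

## Covariate model (`covariate_model`)

Approach 2: continuous covariates enter the log-parameter means as power
terms centred at the cohort median; sex and coadministration as indicator
effects.  Model building approximates the proprietary COSSAC strategy with a
documented two-step loop: forward — Pearson-correlation screening of the
conditional random-effect means against unused covariates, adding the
smallest p below p_in = 0.01; backward — likelihood-ratio pruning (importance-
sampled marginal likelihoods, χ²₁) of effects with p above p_out = 0.05;
iterate to a fixed point with oscillation detection.  The M-step for the
covariate coefficients is per-parameter OLS on the smoothed conditional
means (exact for diagonal random-effect covariance, a standard approximation
otherwise).  Collinear covariate pairs (|r| > 0.95) on one parameter are
rejected by name.

## Pipeline (`pipeline_cli`)

One declarative config (YAML-loadable dataclass) with named seeds for
simulation, fitting, TMLE and bootstrap drives simulate → fit → EB →
features → compare (→ optional covariate search).  Every stage writes CSV/
JSON artifacts plus a manifest with the config hash, seeds and stage
runtimes; identical configs produce byte-identical numeric outputs.  Stage
failures propagate with the stage name recorded and completed artifacts
preserved.

## Known limitations

* SAEM standard errors for random-effect SDs use a marginal approximation;
  bootstrap the fit if exact uncertainty on omega is needed.
* The null-calibration and coverage tests run at reduced n, B and learner
  libraries to fit CI budgets; claims and tolerances are unchanged, but the
  Monte Carlo slack is correspondingly wider.
* No target-mediated or FcRn-saturation (nonlinear) elimination: the fitted
  model is linear, consistent with the dose-proportionality the source data
  support.  No intramuscular route.
* The stepwise covariate search is an approximation of a proprietary
  algorithm; selected structures should be read as supportive, not causal.
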