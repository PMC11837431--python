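# mabpk

Cross-protocol population-pharmacokinetic (popPK) interaction analysis for
monoclonal antibodies, built around the question: *does co-administering an
HIV broadly neutralizing antibody (bnAb) with other mAbs change its
pharmacokinetics compared with giving it alone?*  The package re-implements,
as a tested and reusable pipeline, the analysis used to answer that question
for VRC07-523LS pooled across three phase-1 trials: a two-compartment popPK
model fitted by SAEM, empirical-Bayes individual estimates, derived PK
features, and a targeted-maximum-likelihood (TMLE) covariate-adjusted
comparison of those features between combination and single administration.

It is aimed at biostatisticians and pharmacometricians who want an
end-to-end, fully seeded reference implementation of this design — including
a synthetic-trial generator that emulates the pooled study designs, so every
stage can be exercised and calibrated without access to the trial data.

## The model

Serum concentration kinetics follow an open two-compartment model with
first-order elimination from the central compartment, parameterised by
clearance CL (L/day), central volume Vc (L), inter-compartmental clearance Q
(L/day) and peripheral volume Vp (L); subcutaneous doses pass through a depot
compartment with absorption rate ka (1/day) and bioavailability F.
Individual parameters are log-normal around population values with an
estimated 4×4 random-effect covariance on (CL, Vc, Q, Vp); residual error
variance is combined, `sigma_add² + (sigma_prop · ĉ)²`.  Estimation is by
Stochastic Approximation EM (SAEM) with an MCMC E-step; per-subject empirical
Bayes (MAP) estimates feed eleven derived features (the structural
parameters, distribution/elimination half-lives `ln2/alpha`, `ln2/beta`,
dose-normalised steady-state AUC `1/CL`, and predicted concentrations at day
1 and weeks 4/8/16 after a 1.4 g IV dose).

The causal contrast is the average treatment effect on each log feature —
the difference in its expected value if everyone received the combination
versus the single regimen — estimated by TMLE with a super-learner library
(GLM, stepwise-BIC, random forest, spline/MARS-equivalent, lasso, mean)
for both the outcome regression and the propensity score, a participant
bootstrap for 95% CIs and p-values, and Holm adjustment across the eleven
features.  A supportive covariate-adjusted popPK model (COSSAC-style stepwise
covariate search) is also provided.

## Worked example

```python
import mabpk as m

# 1. a synthetic 146-subject cross-protocol trial at the published estimates
cohort = m.generate_cohort(seed=1)                    # 100 single / 46 combination
trial = m.simulate_trial(cohort, seed=1)              # doses + sampled concentrations

# 2. fit the base population model and inspect the fixed effects
fit = m.fit_saem(trial, config=m.SAEMConfig(seed=11))
f = fit.estimate.fixed
print(f"F={f.F:.2f}  CL={f.CL:.3f} L/day  Vc={f.Vc:.2f} L  Vp={f.Vp:.2f} L")
# F=0.46  CL=0.117 L/day  Vc=3.87 L  Vp=3.49 L

# 3. half-lives implied by the published estimates
hc = m.hybrid_constants(*m.micro_constants(
    m.StructuralParams(CL=0.12, Vc=3.88, Q=0.30, Vp=3.60)))
print(f"elimination half-life {hc.t_half_elim:.1f} d, distribution {hc.t_half_dist:.1f} d")
# elimination half-life 47.6 d, distribution 3.9 d
```

The fitted values sit within sampling error of the generative truth
(F = 0.47, CL = 0.12 L/day, Vc = 3.88 L, Vp = 3.60 L); the implied
elimination half-life of 47.6 days reproduces the published "48 days"
for single administration.  Downstream, `eb_estimates` → `derive_features` →
`compare_features` produce the feature table and the TMLE comparison report
(ratio, bootstrap 95% CI, Holm-adjusted p per feature), and
`mabpk run-all` drives the whole chain from one YAML config with a
reproducibility manifest.

## Command line

```
mabpk simulate | fit | features | compare | covsearch | run-all
```

Each subcommand is a thin wrapper over the library; `run-all` writes the
dataset, fit report, EB estimates, features, trajectory bands, comparison
table and a manifest (config hash, seeds, stage runtimes) to one directory.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
recomputes the headline quantities from scratch: it simulates five
146-subject trials at the published base-model estimates and refits each by
SAEM (reporting median F, CL, Vc, Vp across seeds), and runs the
covariate-adjusted TMLE on twenty replicate feature tables with a 25%
combination effect injected on Vc (reporting the median recovered percent
increase).  Everything is derived at run time from the named seed.

See `docs/methods.md` for the modelling and design details.
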