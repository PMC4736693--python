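# Methods

This note documents the models, priors, samplers and design choices behind
`hierpk`, and what the synthetic-data experiments do and do not demonstrate.

## Profile-level model

Each profile is one meal window of plasma insulin concentrations for one
woman at one visit.  Insulin delivered by pump enters a two-compartment
subcutaneous cascade,

    dQ1/dt = Inf(t) + Bol(t) − Q1/t_max,
    dQ2/dt = (Q1 − Q2)/t_max,     Q1(0) = Q2(0) = 0,

with Q1, Q2 in mU and time in minutes since midnight of day 1.  Integration
always starts at t = 0 so that the state at the start of the observation
window is determined by the recorded dosing alone (a run-in, not an estimated
initial condition).  `t_max` (minutes) is both compartments' inverse rate
constant; the impulse response of Q2 peaks exactly `t_max` minutes after a
bolus, which is what makes the parameter clinically interpretable as
time-to-peak.

The regression function is

    μ(θ, z, t) = u · Q2(t)/(t_max · wt · MCR) + a·(t − t_end) + b,

with body weight `wt` (kg), metabolic clearance rate `MCR` (l/kg/min), and a
linear "residual insulin" drift absorbing long-acting insulin taken before
the study: `a` (pmol/l/min) is its accumulation rate and `b` (pmol/l) the
residual concentration at `t_end`, the 5 h post-meal reference time.  `u` is
the mU→pmol conversion.  No published factor accompanies the model, so `u`
is a configurable constant, default 6.0 pmol per mU (1 U = 6 nmol); it only
rescales Q2/(t_max·wt·MCR), so the choice is absorbed by MCR in any fit and
affects nothing but the reported MCR scale.

Observations are `y ~ N(μ, κ² + λ²μ²)`: an additive floor κ (pmol/l,
prior U(0,100)) plus a multiplicative component λ (prior U(0,1); residuals
larger than the modelled concentration are implausible, hence the upper
bound).

### Numerical integration

The cascade is solved by an adaptive embedded Cash–Karp Runge–Kutta 4(5)
pair written for this 2-state system (relative and absolute tolerance 1e−6;
error-based step control with safety factor 0.9 and step-growth cap 5).
Every dosing discontinuity and every output time is a forced step boundary,
so the embedded error estimate is never evaluated across a jump in the input
rate.  Because the system is linear with piecewise-constant input it also has
an exact per-segment closed form; that closed form is kept in the package
*only* as an independent test oracle (`closed_form_compartments`), and the
test suite holds the integrator to ≤ 1e−5 relative error against it on
randomized schedules.  Boluses are square pulses (1 min by default; longer
durations are representable).  The inner loops are numba-compiled, which is
what lets the test suite run full MCMC pipelines in minutes.

## Population models

With l indexing (t_max, MCR, a, b), profile parameters follow

    θ_l ~ LogNormal(η_l, σ_θl²)   for t_max, MCR,
    θ_l ~ Normal(η_l, σ_θl²)      for a, b,

deliberately without cross-parameter correlation (a full covariance matrix
with an inverse-Wishart prior would be more informative than it looks at
these sample sizes, and would confound with covariate inclusion).  Four
hierarchy variants supply the intercept of η: global only ("one"); woman
intercepts ψ_il ~ N(φ_l, σ_ψl²) ("two"); and visit- or meal-specific
intercepts χ ~ N(ψ_il, σ_χl²) ("threeV"/"threeM").  Priors: φ_l ~ N(0, 100²)
on the log scale for t_max and MCR and N(0, 1000²) for a and b; all sds
uniform on (0, 100).  These constants are deliberately not user-tunable.

### Covariate selection

Covariates enter η linearly in three groups — 7 standardized continuous, 4
binary, and 4 mutually exclusive study-by-mealtime interaction indicators
(which replace the separate study and mealtime factors so that interactions
are searchable) — each group a separate reversible-jump block per parameter,
12 blocks in all.  Coefficient priors are N(0, (Δβ_l / 1.96·Δx)²) with
Δx = 1 for indicators and 2·1.96 for standardized continuous covariates; the
plausible-range width Δβ_l defaults to the spread (log scale for t_max, MCR)
of the stage-1 posterior medians — a mild, deliberate double use of the data,
since an informative scale is essential for inclusion probabilities to mean
anything.  Model-space priors are Binomial(c, 1/2) on the group size for the
continuous and binary groups and (1/12, 4/12, 6/12, 1/12, 0) on the number of
interaction indicators, with subsets uniform given the size: every distinct
identifiable model is equally probable a priori.  All four indicators
together would be unidentifiable (they span the intercept), and the four
3-indicator models are equivalent reparameterizations of one model; they are
kept as four labelled states carrying 1/48 each, preserving uniformity over
the 12 distinct models while keeping the state space simple.

## Two-stage inference

**Stage 1** samples each profile's posterior independently under flat priors
(t_max ~ U(5, 500), MCR ~ U(0, 0.25) — physiological plausibility bounds —
a, b ~ N(0, 100²), plus the nuisance priors above) with componentwise
random-walk Metropolis on transformed scales (log t_max; logit of MCR/0.25,
κ/100 and λ; identity for a, b), Jacobians included exactly.  Proposal scales
adapt toward 0.44 acceptance during burn-in only, so the post-burn-in kernel
satisfies detailed balance.  Two chains start from dispersed draws over the
uniform supports (a and b start in the central prior region — a full
N(0, 100²) draw can start a short chain hundreds of units from the data for
no diagnostic benefit); convergence is checked by the Brooks–Gelman–Rubin
statistic.  Only t_max enters the ODE, so one solve per sweep suffices;
updates of MCR, a, b, κ, λ reuse the cached solution.

A profile is flagged "unfittable" when BGR > 1.1 on any kinetic parameter or
more than 5% of the t_max or MCR posterior mass sits within 1% of a prior
bound — a reproducible proxy for the judgement call of dropping profiles the
model cannot fit; flagged profiles are excluded from stage 2 with the flag
recorded as the reason.

**Stage 2** targets the full joint hierarchical posterior.  One sweep:
Gibbs draws for every intercept (all full conditionals are normal; log-scale
values of t_max and MCR act as the children), stepping-out/shrinkage slice
sampling for every sd on its (0, 100) support, a resampling
Metropolis–Hastings update per profile, and the 12 reversible-jump blocks.
The resampling update proposes a uniformly chosen stored stage-1 draw;
because the proposal density is the stage-1 posterior, the likelihood and
nuisance priors cancel, leaving

    ρ = [p(θ*|Ω)/p(θ|Ω)] · [p₁(θ)/p₁(θ*)].

The uniform components of p₁ cancel exactly within support; the N(0, 100²)
components for a and b are computed exactly rather than treated as ≈ 1 —
exactness costs nothing and keeps the kernel correct for any stage-1 prior.
The ratio is free of (κ, λ), so the error parameters simply ride along with
the stored draw index.  The package asserts the structural consequence in
tests: perturbing the stored (κ, λ) arbitrarily changes no decision, and an
instrumented counter shows zero ODE-solver launches during stage 2.

Reversible-jump moves are chosen uniformly from the valid menu at the
current state: *add* (entering coefficient drawn from its prior, which then
cancels), *delete*, *swap* (uniform over (out, in) pairs, entering
coefficient from the prior) and a conjugate Gibbs *refresh* of the
coefficients at fixed model.  With a flat likelihood this chain samples the
model-space prior exactly, which the tests verify to Monte Carlo accuracy —
a sharp end-to-end check of the acceptance ratios.  Initial state: each
profile at its stage-1 draw nearest the posterior medians, intercepts and
sds from the medians' means and dispersions, all covariate models empty.

**Reference single-stage sampler.**  `hierpk.reference.fit_joint_onelevel`
fits the one-level model directly, evaluating the ODE likelihood at every
profile-parameter proposal.  It exists to verify, not to replace, the
two-stage route; the acceptance suite requires posterior means of φ_l and
σ_θl to agree within 0.1 pooled posterior sd and draw sets within 0.1 KS
distance on an 8-profile trial.  The hierarchical model is defined with the
physiological support box (t_max ∈ (5, 500), MCR ∈ (0, 0.25)) as part of the
random-effect distribution in both routes; the two-stage sampler inherits the
box from its proposal pool, so the direct sampler imposes it too, keeping the
two targets identical (the truncation is numerically irrelevant when the
population mass lies well inside the box, as it does at physiological scale).

## Leave-one-out model criticism

Random effects, not responses, are the object of interest, so the
discrepancy is defined on the kinetic parameters: for each profile the model
is refitted without it (one cheap stage-2 run; stage 1 is never repeated),
`θ_pred` is simulated from the predictive prior — fitted woman/cell
intercepts are used when a sibling profile identifies them, otherwise fresh
intercepts are drawn from their population distributions, following the
predictive-prior integral literally — and the profile's own stage-1 draws
stand in for the unobservable `θ_obs`.  The Bayesian p-value
P = Pr(θ_pred − θ_obs ≤ 0) is estimated by independently resampling both
draw sets with replacement (defaults: as many pairs as stored draws; both
counts configurable).  Under the generating model the p-values are
approximately uniform; they are not independent across profiles, so the
quantile–quantile plot and KS statistic are guides rather than exact tests.

## Synthetic trials

The generator reproduces the motivating study's design: 22 women (10 in a
sedentary study 1, 12 in an exercise study 2), two visits, an evening meal on
day 1 (window 17:30–23:00) and a morning meal on day 2 (window 06:30–12:00),
sampling every 10 min for 90 min post-meal, every 15 min to 5 h post-meal,
and every 30 min otherwise within the window (half-open post-meal grids; the
published schedule does not pin down exact times).  Meal boluses are placed
30 min after each window opens (18:00 and 07:00), making both windows
30 min pre-meal + 5 h post-meal; the source description contains an
inconsistent 11:00 breakfast-bolus time that cannot be reconciled with 5 h of
post-breakfast monitoring inside the stated window, and the symmetric
reading was chosen.  Basal rates are log-normal with median 0.6 U/h
(log-sd 0.6 — the published interquartile range is inflated by within-visit
closed-loop modulation that a constant per-profile basal cannot express),
boluses log-normal with median 8.9 U (log-sd 0.46, matching the published
IQR), delivered over 1 min (15 min for the "long bolus" profiles).  The 13
covariates are drawn to match the study's published means/sds and
prevalences; body weight derives from BMI and a sampled height.

Default truth: three-level (visit) population model with typical values
t_max ≈ 55 min, MCR ≈ 0.025 l/kg/min, a ≈ −0.03 pmol/l/min, b ≈ 31 pmol/l;
variance components of order 0.1 (log scale) for t_max, smaller for MCR,
and a faster-absorption effect after study-2 breakfasts plus
gestation/duration effects on log t_max at the magnitudes the study reports.
The within-woman correlation magnitudes were published only graphically, so
the component sds are order-of-magnitude choices, and recovery tests compare
against the recorded truth, never against published estimates.  Error
parameters: κ log-normal around 4 pmol/l, λ ~ U(0.03, 0.08) (an assay CV of
a few percent).  One master seed spawns independent per-profile streams, so
subsetting profiles leaves the rest bit-identical.

What passing tests show — and what they do not: the synthetic data follow
the assumed model exactly (Gaussian heteroscedastic errors, log-normal/normal
random effects, time-invariant covariates, exogenous square-pulse dosing).
Recovery and calibration results therefore validate the *inference
machinery*, not the kinetic model's adequacy for real plasma data, which has
closed-loop basal modulation, assay artefacts and model misspecification the
generator deliberately omits.

## Problem sizes and numerical choices

The package's own test scale: stage 1 uses 2 chains of 3,000–5,000 burn-in
and 6,000–50,000 kept iterations (thinned to 500–5,000 stored draws per
profile) depending on the check; production-scale settings (10⁶ iterations,
thin 100, 10⁴ stored draws) are a configuration choice, not a code path.
Recovery experiments use the full 88-profile design for selection behaviour
and 20 replicates of a 6-woman (24-profile) design for interval coverage;
cross-validation calibration uses a 12-profile design.  Stage-2 runs use
3,000–40,000 sweeps.  Degenerate inputs are rejected loudly: zero observation
variance, constant continuous covariates, profiles with fewer than 6
observations (the model has 6 free parameters), empty draw stores, and
non-finite integrator states each raise a specific error.  Slice sampling
uses width 1.0 with stepping out clipped to (0, 100); Gibbs updates are
exact, so neither has tuning parameters that affect correctness.

## Known limitations

- Stage-2 correctness relies on the stage-1 pools covering the region where
  the population density is non-negligible; with very small stores (H of a
  few hundred) the resampling proposal discretizes the profile-parameter
  space and mixing of variance components slows.
- The reversible-jump proposal (uniform move menu, prior draws for entering
  coefficients) is simple and valid; at much larger covariate counts a
  better-tuned proposal would mix faster.  It is isolated in
  `rj_update_group` and designed to be replaceable.
- No multivariate random-effects covariance and no woman-specific covariate
  slopes, by design (four profiles per woman cannot support them).
- The LOO p-values inherit the usual conservatism of posterior-predictive
  checks and are cross-profile dependent; the KS test on them is a
  diagnostic, not a calibrated size-α test.
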