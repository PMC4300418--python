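# Methods

## The model

`copdjm` implements a joint nonlinear mixed-effects model for trough FEV1
(the clinical endpoint of COPD bronchodilator trials, in liters) and for
study dropout, together with the simulation machinery needed to generate
virtual trials from it and recover its parameters.

**Disease progression.** FEV1 follows an indirect-response (turnover)
model,

    dFEV1/dt = Kin(t) − Kout(t) · FEV1,

with a zero-order input Kin (L/day) and first-order loss Kout (1/day).
The *disease status* Dis(t) = Kin/Kout is the steady-state FEV1 in the
absence of drug and declines linearly,

    Dis(t) = Int_Dis + Slope_Dis · t,      Slope_Dis < 0 = decline.

Kin is the structural parameter; Kout(t) = Kin / Dis(t) is derived.  The
printed estimate of the historical fit we emulate reports the slope with a
per-day label that would drive Dis negative within days and a Kin that
implies a multi-year turnover half-life; both are treated as unit
misprints.  The package defaults are Slope_Dis = −1e−4 L/day (≈ −37 mL per
year, a realistic COPD decline) and Kin = 0.116 L/day so that Kout ≈
0.1/day (turnover half-life about one week), which makes bronchodilator
onset resolvable at the 2–4-week visit spacing.  Both are configurable and
neither is an estimation target of the recovery protocol.

Note one structural subtlety: with a nonzero slope the FEV1 trajectory does
not sit exactly on Dis(t) but trails it by the quasi-steady-state lag
Slope_Dis/Kout (≈ 1 mL at the defaults), which the closed-form solution
reproduces exactly.

**Drug effect (KPD).** Plasma pharmacokinetics of inhaled salmeterol are
unavailable, so exposure is a kinetic-pharmacodynamic (KPD) compartment
driven by dose with first-order loss KDE.  Three exposure markers are
supported: (a) the superposed decaying amount (default), (b) the dose
itself, (c) the input rate KDE·D.  The published KDE (52.46 hr⁻¹) is
implausible for trough-only sampling; the default is 1/day on the master
day clock, fixed (not estimated) in recovery fits.  Effect is a saturable
Emax function of exposure A,

    E(A) = Emax · A / (EDK50 + A),

applied multiplicatively on Kin in the final model (Kin·(1+E)); additive
and Kout-sided variants are implemented for model discrimination but are
untuned.  Because only one active dose level exists, EDK50 is parameterised
through the ratio EDK50/Emax (8.66 μg in the final model), which is fixed
in recovery fits unless the historical prior is enabled.

Visits are trough (pre-dose) measurements: exposure at a visit is the
pre-dose superposition value, and the baseline visit precedes the first
dose, so FEV1(0) = Dis(0).

**Covariates and IIV.** Continuous covariates enter as power functions
centred at their reference (median) value, categorical covariates as
multiplicative factors on the non-reference level; the final model carries
severity (0.62), male sex (0.82), PICS (0.92) and height (power 1.90) on
Int_Dis, and severity (0.94) and reversibility (1.05) on Emax.  The sex
factor below 1 for males is kept as published even though it is
physiologically surprising.  Inter-individual variability is lognormal,
P_i = TVP·exp(η_i), η ~ N(0, Ω).  The recovery preset places IIV on
Int_Dis (ω² = 0.0625, CV 25%) and Emax (ω² = 0.49, CV 70%) — the two
dominant terms of the final model; a `full` preset adds Kin.  CV% is
reported as 100·√ω² (first-order); the exact lognormal formula
100·√(exp(ω²)−1) is available as an option.  EDK50's typical value is tied
to the *raw* typical Emax through the ratio and does not inherit Emax's
covariate factors.

**Residual error.** Additive (default, σ = 0.13 L), proportional and
combined Gaussian residual models.

**Dropout.** Time-to-event with hazard (per week)

    h(t) = base(t) · exp(β1·FEV1_obs + β2·IPRED),

base(t) constant (β0), Gompertz ("exponential") or Weibull.  β1 and β2
carry at-random and non-random (informative) missingness; the final model
is constant hazard with β0 = 0.006/week and β2 = −0.88 on the
individual-predicted FEV1.  The source text prints 0.06 where its table
prints 0.006; the table value on a per-week clock is adopted because it
reproduces the observed single-digit-to-low-teens dropout percentage over
16–24 weeks.  A subject dropping between visits contributes the interval
probability S(t_last) − S(t_next); completers contribute S(t_end).  IPRED
(and observed FEV1, when β1 ≠ 0) is held piecewise constant at the *left*
visit endpoint inside all hazard integrals — visits are the only times the
trajectory is materialised in a dataset — and the simulator draws dropout
times by inverse-CDF sampling of exactly that piecewise-constant hazard, so
simulation and likelihood are mutually consistent by construction.

## Estimation

The marginal likelihood integrates the random effects out per subject with
the Laplace approximation: an inner safeguarded Newton maximisation of
log p(y|η) + log N(η; 0, Ω) followed by the usual curvature correction.
The joint objective is

    MOFV = −2 Σ_i log L_i  (+ prior penalty),

minimised over transformed parameters (log scale for positive quantities,
identity for β1/β2, the slope and power exponents), so the outer problem is
unconstrained and start-point invariant.

Numerical choices that matter:

- **Inner optimisation.** The conditional log-likelihood is evaluated for
  the whole cohort at once (the trajectory has a closed form per inter-visit
  segment), so the inner Newton iteration runs for all subjects in parallel
  with finite-difference derivatives (central, step 1e−4).  Far from the
  mode the joint can be locally *convex* (e.g. a subject whose baseline sits
  several η-SDs from the typical value), so the Newton step uses the
  saddle-free modification — eigendirections scaled by |curvature| — plus a
  backtracking line search.  The η for Int_Dis is warm-started from the
  baseline observation (FEV1(0) = Int_Dis_i identifies it directly).
- **Tolerances.** The inner iteration stops at an η-gradient norm of 1e−6,
  which is the finite-difference noise floor for subjects with several
  hundred log-likelihood units; the induced error in the marginal is
  O(grad²/curvature) ≈ 1e−13 per subject.  The final curvature for the
  log-determinant is re-evaluated with a 10× wider stencil: the
  log-determinant enters the objective directly and the wider step keeps
  FD rounding noise (which would otherwise make the outer objective
  path-dependent at the 1e−6 level) two orders of magnitude below the
  smooth truncation bias.
- **Outer optimisation.** L-BFGS-B (FD gradients, step 1e−5), optionally
  polished by a short Nelder-Mead pass and then by full-Newton steps on the
  outer objective using the central-difference Hessian (shared with the
  standard-error computation).  With the polish, estimates agree to ≈2e−5
  relative across widely dispersed starts.  Standard errors come from the
  inverse MOFV Hessian (delta method back to the natural scale) and are
  reported only when that Hessian is positive definite.
- **Degenerate inputs.** Placebo subjects are flat in the Emax η; the
  Laplace factor for that dimension cancels exactly against the prior, so
  including or excluding the dimension changes nothing (tested).  Subjects
  whose trial η would drive Dis(t) ≤ 0 get a large finite penalty rather
  than an exception, which the line search rejects smoothly.  Ω → 0
  degenerates to the η = 0 likelihood.

**Prior.** With one dose level, Emax and EDK50 are jointly weakly
identified.  The optional penalty adds a multivariate-normal −2 log density
on (Emax, EDK50/Emax ratio) — historical means 0.78 and 4/0.78 μg — and an
inverse-Wishart −2 log density (df 24, scale 0.24/0.14 with covariance 0.1)
on the covered IIV block.  The historical fit's covariance matrix is not
available, so the θ-covariance defaults to the diagonal of the printed IIV
prior scale; this is a documented approximation and user-replaceable.  The
prior is stated on the (Emax, ratio) parameterisation; whether the original
applied it to (Emax, EDK50) directly is unknowable from the source, so the
choice is a config switch.  When the model's Ω lacks part of the prior
block (the final model dropped IIV on EDK50), the matching sub-block is
used.

**Covariate search.** Forward inclusion while the best candidate drops the
MOFV by ≥ 3.84 (χ²₁ at 0.05; a drop of exactly 3.84 is *in*), ties broken
by the larger drop then lexicographic (covariate, parameter) order;
backward deletion removes, weakest first, any retained covariate whose
deletion raises the MOFV by ≤ 11 (χ²₁ at 0.001).  Candidates whose refit
fails are logged in the step table and skipped.

**Bootstrap.** Case resampling of subjects with replacement, each replicate
refit warm-started at the full-data estimates; non-converged replicates are
counted and excluded, more than 50% failures aborts.  Percentile 90% CIs by
default (n_boot = 100).

## The synthetic-trial generator

The generator is the package's data source and defines the study
conditions: two arms (placebo and salmeterol 50 μg BID, 1:1 by default —
the pooled historical studies were placebo-heavy, but a balanced allocation
is the natural choice for a recovery experiment and is configurable), 24
weeks with visits every 4 weeks (within the 2–4-week protocol range), and
cohort marginals matching the published demographics: 30% female, 67%
severe, 26% reversible, 40% PICS, 42% smokers, age 65 [40–90] years,
height 170 [135–203] cm.  Continuous covariates are scaled Beta
distributions matched to the printed median and range (no SDs were
published); the concentration parameter defaults to 4, a moderate spread.
BMI (median 26, range 16–40 — typical of COPD cohorts) and weight =
BMI·(height/100)² are the package's own choices since those marginals were
not published.  Covariates are sampled independently — only marginals are
known — with a hook for a user-supplied joint sampler.

What the generator does *not* emulate, hence what green tests do not show
about real trials: between-study heterogeneity of the six pooled studies,
covariate correlations (height–sex, severity–reversibility), rescue
medication and exacerbation episodes, center effects, serial within-day
FEV1, missed visits other than terminal dropout, and measurement-occasion
variability beyond the additive residual.

## Recovery protocol (the acceptance surface)

One simulated trial (n = 2000, conditions above, generative parameters =
published final-model column with the slope/Kin/KDE substitutions) is
refit jointly by Laplace.  Free parameters: Int_Dis, Emax, σ_add, β0, β2
and the two IIV variances.  Fixed at generative values: KDE and the
EDK50/Emax ratio (unidentified with one dose level and no prior), Kin and
Slope_Dis (invisible at trough-visit resolution relative to σ), and the
covariate θs (their recovery is exercised separately by the stepwise-search
experiment).  The fit uses the L-BFGS stage only; the polish stages change
estimates at the 1e−4 level, far below the Monte-Carlo scatter of the
experiment.

Scale choices for the remaining experiments (all chosen for one CPU core):
the covariate-search calibration runs 100 replicates of a 200-subject,
12-week placebo cohort with IIV on Int_Dis only; the informative-dropout
comparison uses n = 1200 and β0 = 0.015/week, which yields ≈ 13% dropout —
matching the observed dropout percentage more closely than the final-model
β0 itself and making the MNAR selection effect visible above Monte-Carlo
noise; NPDE calibration runs 100 replicates of 120 subjects with K = 500
simulation replicates under the completely-random-dropout configuration,
because the NPDE null distribution assumes a noninformative observation
process (under MNAR dropout the diagnostic is mildly miscalibrated by
construction, which is a property of the method, not of this
implementation).

## Diagnostics

The VPC re-simulates complete replicate trials for the observed cohort —
same covariates and arms, fresh η, residual noise *and dropout* — and
overlays the observed 5th/50th/95th percentiles per visit bin on the 95%
envelopes of the same percentiles across replicates; one bin per scheduled
visit, no smoothing.  Strata: arm, severity, reversibility, PICS.  The
Kaplan-Meier overlay (via lifelines) carries the dropout half of the same
check.  NPDE follows the standard simulation-based construction: per
subject, K unconditional replicates at the observed times, decorrelation by
the simulated mean and Cholesky factor, ranks with a ±1/(2K) continuity
correction mapped through the standard-normal quantile.  Goodness-of-fit
tables report PRED (η = 0), IPRED (empirical-Bayes η), RES and IWRES;
FOCE-linearised conditional weighted residuals are out of scope — NPDE and
IWRES carry the residual-diagnostic role.

## Known limitations

- The estimation engine supports the closed-form drug-effect modes
  (multiplicative/additive on Kin, multiplicative on Kout); the additive
  Kout mode is simulation/numeric-solver only.
- Estimated Ω is diagonal (the final model dropped all covariances as
  < 0.1); full matrices are accepted for simulation.
- Datasets must share a common visit grid (the generator's native shape);
  free-form observation times would require a ragged likelihood engine.
- The Emax IIV variance is noticeably shrunken in small trials (few active
  subjects, ~50% η-shrinkage); its recovery is reliable only at the n=2000
  scale of the acceptance experiment.
- Finite-difference derivatives bound the reproducibility of the MOFV at
  roughly 1e−6; reported estimates are invariant to starts at ~2e−5
  relative, not machine precision.
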