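# Methods

## The model

`popmm` analyses intravenous glucose tolerance test (IVGTT) data with the
one-compartment glucose minimal model driven by measured insulin:

    dG/dt = -(GEZI + X(t)) G(t) + (GEZI + Xb) Gb,    G(0) = Gb + Dose/V
    dX/dt = -p2 X(t) + p2 SI I(t),                   X(0) = SI Ib

with plasma glucose G (mmol/L), remote insulin action X (1/min), the
piecewise-linear interpolant I(t) of the measured insulin concentrations
(pmol/L, constant extrapolation outside the measured range), basal levels
Gb and Ib (taken as the last measured values), and Xb = SI·Ib.  The four
individual parameters are

| parameter | meaning | units | typical value (base model) |
|---|---|---|---|
| GEZI | glucose effectiveness at zero insulin | 1/min | 0.0178 |
| SI | insulin sensitivity | 1/min per pmol/L | 3.59e-5 |
| p2 | remote insulin-action rate constant | 1/min | 0.0425 |
| V | glucose distribution volume | L | 12.4 |

Glucose samples before 5 min are excluded from fitting (the one-compartment
model does not represent the initial mixing phase) and a subject must retain
at least 4 observations.  The glucose bolus is 0.3 g/kg, converted to mmol
with a glucose molar mass of 180.16 g/mol.

## Numerical solution

Because I(t) is piecewise linear, X(t) has a closed form on every forcing
segment; the simulator advances X exactly and integrates the scalar G
equation with classic RK4 whose sub-step is bounded by `dt_max`
(default 0.5 min) and by 0.5/(GEZI + X), with step halving on any
non-finite or non-positive intermediate value.  Disappearance rates above
50/min, or more than 5e6 steps, abort the integration (such parameter values
arise only from heavy-tailed importance-sampling proposals and are
physiologically meaningless); the likelihood then evaluates to -inf.  The
scheme is validated against the constant-insulin analytic solution
(rtol 1e-6) and against an independent fixed-step (0.001 min) RK4
integration of the coupled system (rtol 1e-4) over random parameter and
forcing draws.

A deliberate design choice: the integrator is *not* an adaptive-tolerance
solver.  With rates of order 0.1/min, bounded-step RK4 is accurate to ~1e-9
relative and an order of magnitude faster inside the EM inner loop, and it
is bitwise deterministic.

## The hierarchy and its estimation

Stage 1: observations y_ij ~ N(yhat_ij, (sigma·yhat_ij)^2) — residual SD
proportional to the prediction.  The published "proportional error 0.0706"
is read as a 7.06% CV on this SD scale; the alternative reading (variance
proportional to the prediction) was considered and not adopted because the
printed value is naturally a CV.

Stage 2: log theta_i ~ N(D_i·gamma, Sigma) with a full 4x4 covariance
(GEZI and p2 are strongly correlated in this model, r ~ 0.77).  The design
matrix D_i holds identity columns for the four log typical values plus one
column per covariate effect:

* continuous covariates enter as power functions centred at the study
  median — the column is log(cov/ref) and the coefficient is the exponent;
* categorical covariates enter as proportional shifts (1 + phi·indicator) —
  the column is the indicator and the log-scale coefficient is log(1+phi),
  so reported coefficients are exactly the phi printed in covariate
  formulas such as GEZI = 0.0210·(1 - 0.473·T2D).

Maximum likelihood is obtained by Monte-Carlo EM:

* **E-step** (per subject): Nelder-Mead finds the conditional mode of
  log theta_i (warm-started across iterations); the finite-difference
  Laplace curvature at the mode, SPD-repaired and inflated by 1.4, scales a
  multivariate-t proposal (4 df); importance weights give the conditional
  mean, covariance, the residual sum of squares, and the marginal
  likelihood.  Very peaked posteriors (near-zero residual error) trigger a
  curvature-scaled second mode search and Hessian.  Random draws come from
  per-(seed, iteration, subject) `numpy` streams, so fits are exactly
  reproducible.
* **M-step** (closed form): GLS for gamma, pooled conditional second
  moments for Sigma (eigenvalue-floored at 1e-6), and a closed-form
  proportional-error update for sigma.
* **Convergence**: because single iterations carry Monte-Carlo noise, the
  stopping rule compares the means of all estimates over the last
  `convergence_window` (default 5) iterations against the preceding window
  (relative tolerance `convergence_rtol`, default 6e-3), and the reported
  estimates are the tail-window averages.  Defaults: 300 importance
  samples, at most 50 iterations.

-2LL is estimated by importance sampling with per-subject streams that
depend only on (seed, subject), so evaluations of different models share
common random numbers.  `paired_minus2LL` goes further for nested models:
one proposal per subject, identical draws and per-sample likelihoods for
both models, reweighted under each model's stage-2 prior (per-sample
residual sums allow exact rescaling when the two sigmas differ) — the
Monte-Carlo error of the -2LL *difference* then nearly vanishes.

Standard errors come from the observed information estimated as the outer
product of per-subject observed-data scores; each score is the conditional
expectation of the complete-data score and is assembled from E-step
moments.  This is the information-identity form of the usual EM standard
errors; a subject-resampling bootstrap of the score contributions is the
fallback for ill-conditioned information matrices.  RSEs are reported as
CV%: for a typical value exp(g), RSE% = 100·SE(g); for an IIV CV%,
RSE% = 100·SE(Sigma_jj)/(2 Sigma_jj).

### Known limitation: slow EM directions

EM contracts very slowly along weakly identified covariance directions
(here the GEZI-p2 block): continuing a 40-iteration fit for another 40
iterations can still improve -2LL by ~10 units on a 60-subject cohort even
though the typical values have long stabilised.  Typical values and sigma
are robust to this; -2LL comparisons between *independently* fitted models
are not, which motivates the profile LRT below.

## Covariate selection

Candidates are screened on the empirical conditional means of a
covariate-free fit: Spearman rank correlation against log covariates
(continuous) or Wilcoxon rank-sum between levels (categorical), ranked by
p-value within parameter.  Screening is advisory only.

Forward addition tests candidates one by one in the order SI, V, GEZI, p2.
The gate for each candidate is a **profile likelihood-ratio test computed
on shared importance samples**: with all other population parameters fixed
at the current model's estimates, the candidate coefficient (jointly with a
re-profiled population mean of the affected parameter, which absorbs the
imperfect centring of the covariate column) only shifts each subject's
stage-2 prior mean, so -2LL is an exact smooth function of the coefficient
given one set of per-subject importance samples, and the LRT statistic has
no refit noise.  A candidate is retained iff the chi-square(1) p-value is
below alpha (default 0.05) *and* the coefficient's RSE (from the profile
curvature) is below 50% — the precision criterion quantified, since the
source procedure states it without a threshold.  Retained candidates then
get a full EM refit, warm-started from the current model, which becomes the
new current model.

This differs from the textbook "refit both nested models and difference
their -2LL": with Monte-Carlo EM and affordable iteration budgets, two
independently fitted nested models differ by several -2LL units of
fit-quality noise (see the slow-direction limitation above), which destroys
the chi-square(1) calibration of the naive LRT.  The profile statistic is
calibrated: simulated at the true population parameters the rejection rate
is at the nominal 5%, and after a short base fit it remains consistent with
5% across 100 null replicates.  Backward elimination is not performed.

## Disposal partitioning

The fractional disappearance rate GEZI + X(t) splits net glucose disposal
into a non-insulin-dependent part GD_NID = ∫ GEZI·G dt and an
insulin-dependent part GD_ID = ∫ X·G dt, integrated by the trapezoid rule
on a uniform grid (default 0.1 min; halving the step changes the integrals
by <0.01%) from 0 to the subject's last observation, using the continuous
model solution at the subject's conditional-mean parameters.  The basal
fraction is GEZI/(GEZI + SI·Ib).  Dynamic fractions are computed for
standard-IVGTT subjects only (exogenous insulin in IM-IVGTT distorts the
partition); an override flag includes them.  Group comparisons use the
two-sided Wilcoxon rank-sum test (exact enumeration when both groups have
n <= 10 and no cross-group ties).

## The synthetic cohort generator

No raw clinical data are distributed with the source study, so virtual
trials stand in for them.  What the generator emulates:

* **Composition**: 497 subjects by default, 154/497 T2D, 229/497 IM-IVGTT,
  sex split 239 F / 217 M / 41 missing.
* **Covariates**: age 41.4 ± 16.9 yr [9.7, 86], height 169 ± 10.1 cm
  [130, 196] and BMI 28.0 ± 6.76 kg/m² [15.9, 53.9] as truncated normals
  whose *truncated* mean and SD are moment-matched numerically (naive
  truncation would shift the BMI mean by ~+0.6).  Weight is derived as
  BMI·(height/100)², keeping the anthropometrics internally consistent
  (implied weight mean ~80 kg against the reported 79.7 ± 19.9).
* **Designs**: IVGTT 180-360 min with 12-30 samples, IM-IVGTT 180-240 min
  with 12-22 samples; dense early (≤30 min), sparse late; t=0 and the
  endpoint always sampled.
* **Parameters**: true individual parameters drawn from the published
  population model (base or final column), including the GEZI-p2
  correlation of 0.77.
* **Noise**: observations = prediction × (1 + sigma·eps), floored at
  0.1 mmol/L, sigma = 0.0706.  The recorded basal glucose is the true basal
  with 2% CV measurement noise — assay-scale error, deliberately smaller
  than sigma, which also absorbs model misspecification in real data.
  (Setting basal noise to the full 7% makes every subject's fitted model
  misspecified through its initial condition and production term, and
  biases GEZI downward by ~10-15% — a caveat for real data where basal is a
  single measured sample.)
* **Insulin forcing** is a parametric invention (no measured profiles are
  available), with shapes anchored to IVGTT physiology: a basal level (ND
  median 40 pmol/L, T2D 70 pmol/L, log-normal 35% CV); an endogenous first
  phase peaking at 3-5 min (ND ~7x basal, blunted ~2x in T2D) whose decay
  matches the 4-6 min plasma half-life of insulin — these sharp early
  transients carry most of the p2 information; a slower glucose-driven
  second phase peaking at 30-50 min and back near basal by the end of the
  test (ND ~2.5x basal; T2D ~8x basal, i.e. sustained hyperinsulinemia of
  several hundred pmol/L, which is what makes insulin-mediated disposal
  substantial in T2D despite low S_I); and for IM-IVGTT an exogenous phase
  from 20 min scaled to a 0.03-0.05 U/kg infusion (~1-2 nmol/L peak).
  Knots are spaced 2-10 min; profiles of the same subject under the two
  test types are identical before 20 min given the same stream.  Without
  the second phase the simulated T2D non-insulin-dependent disposal
  fraction is far too high (insulin exposure ~100 pmol/L instead of
  several hundred); without the fast first-phase decay p2 is so weakly
  identified that the population fit can wander into an inflated-variance
  regime.
* **Imputation operations** mirror the source study's missing-covariate
  rules: study-mean assignment, sex from reported proportions, height from
  weight and mean BMI, and — replacing the external virtual-population
  tool, of which only group-mean outputs were used — heights from
  sex-specific normals (F 162 ± 7, M 176 ± 7 cm) with weight
  back-computed from BMI.

What passing tests on these cohorts do **not** show: recovery under real
insulin kinetics, assay artefacts, inter-study heterogeneity, or real
covariate-parameter relationships.  In particular the published dynamic
disposal fractions (72.8% ND / 48.8% T2D) depend on the real measured
insulin profiles; on synthetic cohorts only the *direction* (ND > T2D) and
significance of the difference are expected to reproduce, and that is what
is tested.

## Problem sizes used in the automated checks

Parameter-recovery experiments use 150-subject cohorts (base-model truth,
one fixed seed) — large enough that sampling error of the cohort mean
(~4% for log GEZI) is well inside the 15%/25% recovery bands.  The
null-calibration study uses 100 replicates of 60 subjects with a reduced
fit budget (100 importance samples, ≤20 iterations) and one null candidate
(age on SI); its gate decisions come from the profile LRT, which is what
keeps the reduced budget honest.  Disposal-direction cohorts use 30
subjects per glucose-tolerance group.

## Degenerate inputs and tie-breaks

Subjects whose E-step fails outright are flagged and contribute their prior
moments for that iteration, never silently dropped.  Completely tied
rank-sum inputs give p = 1 with a warning.  Constant covariates are skipped
in screening with a warning.  A candidate whose refit raises is recorded as
rejected with the diagnostic and the procedure continues.  `lrt` accepts a
slightly negative -2LL difference (default tolerance 1 unit) to absorb
Monte-Carlo noise; anything worse raises.
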