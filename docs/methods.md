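# Methods

## The model

Sodium nitroprusside (SNP) is degraded too quickly for plasma
concentrations to be measured, so the hemodynamic response is modelled
K-PD style: the infusion-rate history u(t) (µg/h) drives a hypothetical
one-compartment effect site, and the effect-site concentration drives
mean arterial pressure (MAP) instantaneously.

Effect site, for subject i:

    dCe_i/dt = u_i(t)/V_i - (CL_i/V_i) * Ce_i,          Ce_i(0) = 0
    CL_i = CL_std * (WT_i/70)^0.75 * exp(eta_CL,i)      [L/h]
    V_i  = V_std  * (WT_i/70)      * exp(eta_V,i)       [L], V_std = 1 L/70 kg fixed

Theory-based allometry fixes the weight exponents (0.75 for clearance, 1
for volume); with the published CL_std = 3.12 L/h/70 kg the effect-site
half-life is 60·ln2·V/CL = 13.3 min. For piecewise-constant infusions
the ODE is solved in closed form segment by segment,

    Ce(t0 + tau) = Ce(t0) e^(-ke tau) + (R/CL)(1 - e^(-ke tau)),  ke = CL/V,

which the tests verify against numerical ODE integration to 1e-6
relative error.

Response, for observation j of subject i:

    MAP_ij = S0_i - Emax_i * Ce_ij^g / (EC50_i^g + Ce_ij^g) + alpha_i * t_ij

* `S0_i = S0_std (Age_i / 11.33)^PwrAge exp(eta_S0,i)` — baseline MAP
  rises weakly with post-natal age (PwrAge ≈ 0.034).
* `Emax_i = expit(logit(Emax/S0_std) + eta_Emax,i) * S0_i` — the maximal
  drop is parameterised as a fraction of the subject's own baseline and
  bounded in (0, S0_i) by a logistic transform of its random effect. At
  eta = 0 this gives Emax_i = (Emax/S0_std)·S0_i, i.e. the population
  fraction applied to the individual baseline. The published model
  states the (0, E0) constraint but not the exact transform; this is the
  natural choice satisfying it, and it also reproduces the published
  dose-recommendation tables better than a baseline-independent Emax.
* `EC50_i = EC50_c exp(eta_EC50,i)` with the component c ∈ {low, high}
  drawn from a Bernoulli mixture (P(high) ≈ 0.70): two subpopulations,
  drug-sensitive and drug-resistant, that cannot be told apart from
  covariates.
* `alpha_i = alpha (1 + eta_alpha,i)` — a linear "disease progression"
  drift (MAP creeping upward under lightening anaesthesia). The signed
  proportional random-effect model lets individual slopes be negative.
  The printed units of alpha are ambiguous; mm Hg/h is assumed
  throughout. The drift applies from the start of the infusion (t >= 0);
  pre-dose baseline observations carry negative times and see S0_i.
* Residual error is proportional: `y = MAP (1 + eps)`,
  eps ~ N(0, sigma^2), sigma = 0.329 (32.9 %CV).

All random effects are independent normals; Table-2-style %CV values map
to SDs as omega = CV/100 (exponential-model convention), giving e.g.
omega_CL = 0.627 and omega_alpha = 2.11. Internal units are hours,
micrograms and litres; the CSV/CLI layer speaks minutes and µg/kg/min
(`snpkpd.units` holds every conversion).

## Synthetic trials

`snpkpd.trial` emulates the blinded dose-ranging phase: four parallel
arms at 0.3/1.0/2.0/3.0 µg/kg/min infused for up to 30 min, MAP every
2 min on treatment plus a 6-min pre-dose baseline window (4 baseline
rows), and a safety rule that halves the rate on a first noisy MAP
reading below the floor (50 mm Hg; 40 for neonates) and stops the
infusion on a second. Cohorts follow the five enrolment age strata
(2/25/6/21/46%); ages are log-uniform within stratum and weights
conditionally log-normal (SD 0.18 on the log scale) around a growth
curve interpolated through the strata's median (age, weight) anchors,
clipped to the enrolled range (2.8–112.2 kg). These covariate generators
reproduce the summary statistics of the study population approximately —
that is their contract; they do not model secular growth trends,
sex differences, or the correlation structure of a real clinic.

Because the residual CV is large (33%), a proportional-error draw can be
negative; the generator redraws the residual until the observation is
positive (about 0.1% of draws). The fitted likelihood ignores this
truncation; at that rate the effect on the reported recovery experiments
is far below their Monte-Carlo error.

What passing tests on these data do show: the estimation, evaluation and
dose-finding machinery is internally consistent with the stated model at
the study's design and noise level. What they do not show: robustness to
model misspecification (real MAP series have autocorrelated residuals,
measurement artefacts, and informative clinical interventions none of
which the generator emulates).

## Estimation

The marginal likelihood integrates the subject-level random effects out
of the conditional likelihood. The integral is approximated by Laplace's
method (mode plus curvature), the same family of approximation as
NONMEM's FOCE; the two EC50 components enter as an exact subject-level
mixture:

    OFV = -2 sum_i log[ p L_i(high) + (1-p) L_i(low) ]

**Basin-summed Laplace.** With the published variance components the
subject-level joint density is multimodal for a minority of subjects:
the large slope random effect (omega = 2.11) can trade off against the
drug effect, producing two or more posterior basins of comparable mass.
A single-mode Laplace then under-counts the integral by up to log 2 per
subject, which is enough to distort the population objective and bias
the variance components downward. The implementation therefore sums the
Laplace masses of all distinct basins found for each subject
(log-sum-exp over basins; basins are deduplicated at 0.15 on the eta
scale and capped at 4 per subject). Basins are located by fixed
multi-start probes of the slope/Emax/CL trade-off and cached per subject,
so subsequent evaluations track each basin cheaply from warm starts.

**Inner problem.** The per-subject, per-component mode search is a
damped Newton iteration run for the whole cohort at once on rectangular
arrays. Gradients and Hessians are central finite differences on the
eta scale (step 1e-4); the Newton step is ridge-stabilised through an
eigendecomposition, capped at 3 SD-units per iteration, and backtracked
until the joint density improves; convergence at max|grad| < 1e-5. The
final Hessian supplies the Laplace curvature term. Accuracy: against
dense-grid quadrature on one- and two-random-effect toys the error is
below 1e-3 at 5% residual noise (the approximation-validity regime); at
the study's 33% noise the intrinsic single-subject Laplace error is
~2e-3 log-units, negligible against the likelihood scale.

**Outer problem.** L-BFGS-B over transformed parameters: logs for
positive quantities, logits for the mixture probability and the Emax
fraction, and EC50_high = EC50_low (1 + delta) with delta > 0 so the
component labels cannot switch. V_std is fixed at 1 L/70 kg by default
(not estimable from dose-response data alone). Because the objective is
itself produced by inner optimisation, the outer gradient is computed
in-house: forward differences (step 1e-4) in which every perturbed
evaluation seeds the inner optimiser from the centre point's modes, and
every evaluation seeds from the modes of the best point seen so far —
so finite differences always compare like basins, and a wild line-search
excursion cannot contaminate later evaluations. Default budgets are 100
iterations / 120 evaluations; the desk-scale recovery experiments use 45
evaluations, past the point where the estimates plateau. Line-search
exhaustion (no further descent at finite-difference resolution) is
reported as convergence; only budget exhaustion is flagged otherwise.

**Recovery experiments.** The headline check simulates 100-subject
blinded-phase trials at the published values and refits with initial
estimates equal to those values — the standard initialisation for
simulation–reestimation studies. Single-seed estimates of CL_std are
heavy-tailed (occasionally a deeper likelihood basin sits ~20% away), so
the experiment runs three seeds and reports seed-averaged estimates,
which in our runs recover CL_std within ~7% and S0_std within ~1%.

**Bootstrap and LRT.** The non-parametric bootstrap resamples subjects
with replacement and refits from the original estimates (default 200
replicates at desk scale; the published analysis used 1000); failed
replicates are dropped and counted. Nested models are compared by the
chi-square likelihood-ratio test on the OFV difference.

## Evaluation

The VPC keeps every subject's realised design — dose events including
any safety down-titrations, observation times, covariates — and redraws
mixture labels, random effects and residuals, 100 replicates by default.
Observed 5th/50th/95th percentiles per time bin (the 2-min observation
grid; bins under 5 observations flagged) are compared with the 95%
interval of each percentile across replicates. Stratified VPCs split
observed subjects by the recorded simulation-truth label and replicate
draws by their redrawn labels. Goodness-of-fit tables report population
predictions (eta = 0 under the most probable component), individual
predictions (empirical Bayes modes), and raw/weighted residuals.

## Dose finding

Deterministic recommendations evaluate the model at the population mode
(eta = 0) of the chosen EC50 component. Scenario 1 finds the constant
rate whose baseline-relative MAP reduction at the horizon (5 min) equals
the target; scenario 2 finds a loading rate reaching an absolute target
(60 mm Hg) at 3 min and a maintenance rate returning MAP to the target
at the end of a 30-min window. Both are bisection on the log rate
(bracket 1e-4 to 100 µg/kg/min, MAP error < 1e-6 mm Hg). The
progression drift is included in the target accounting by default
(the response model contains it); a flag disables it.

Two deliberate configuration choices, made because they reproduce the
published dosing tables and documented here as the package's defaults:

* **Parameter column.** Dose-finding defaults to the bootstrap-average
  estimates. With the final-model column the sensitive-subpopulation
  doses come out 25–30% above the published table; with the bootstrap
  column all twenty single-infusion cells agree within 7% and the
  loading rates within 3%. The published simulations were evidently run
  from the bootstrap averages; the final-model column remains selectable.
* **Maintenance matching.** The maintenance rate is matched at the end
  of the window, with the drift accumulated from the infusion start.
  For the two oldest reference patients this problem is *saturated*: the
  upward drift over 33 min pushes the required end-of-window drug effect
  to or beyond those patients' attainable Emax, so no maintenance rate
  exists — and the published rates for those cells imply effects within
  2% of the Emax asymptote, a regime where a 1% change in effect moves
  the dose ~30%. The strict API raises an explicit unattainable-target
  error there; the batch table reports NaN. A least-squares-over-window
  alternative was evaluated and reproduces those cells no better, so it
  was not adopted.

Stochastic companions simulate virtual patients (full between-subject
variability, mixture conditioned on the queried subpopulation) under the
deterministic recommendation and report MAP percentile bands, 100
replicates by default.

## Numerical choices and degenerate inputs

* Hill terms are evaluated as expit(g·(log Ce − log EC50)) — exact at
  Ce = 0 and overflow-safe at g ≈ 7.
* Predictions are floored at 0.1 mm Hg inside the likelihood with a
  smooth quadratic penalty below the floor; non-finite joint densities
  (unrepresentable etas) evaluate to −1e12 so optimisation steps away.
* Zero variance components drop the corresponding random effect from
  the inner problem exactly; with all variances zero the marginal
  likelihood is the conditional density at eta = 0.
* Degenerate structural inputs (gamma → ∞ limits, EC50 ≤ 0, label-
  switched EC50s, Emax ≥ S0) are rejected at construction, not
  limit-evaluated.
* Datasets are stored to 0.1 mm Hg / 0.001 µg/kg/min; the file round
  trip is exact at storage precision.

## Problem sizes

The packaged experiments run at desk scale, chosen as the sizes at which
the checks are statistically meaningful: recovery fits use 3 × 100
subjects (the study itself had 202; standard errors scale accordingly),
the VPC 100 replicates as published, the LRT calibration 50 null
replicates of a 20-subject single-arm design, and the bootstrap default
is 200 replicates against the published 1000.

## Known limitations

* Laplace (even basin-summed) is an approximation; exact-likelihood
  methods (adaptive quadrature beyond 2 dimensions, SAEM) are out of
  scope, and absolute OFV values are not comparable to other software.
* The estimator is a local optimiser on a multimodal surface; results
  depend on initial estimates, and single-seed recovery of CL_std is
  heavy-tailed under the study's 33% residual CV.
* No inter-occasion variability, no random-effect correlations, no
  covariates beyond weight (CL, V) and age (S0) — mirroring the model
  being implemented.
* The open-label phase (investigator-driven titration) is not emulated;
  the generator covers the blinded phase only.
* Dosing recommendations carry the model's assumptions (anaesthetised
  children, no toxicity constraints) and the saturation caveat above.
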