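# Methods

This note documents the statistical model, the estimators, the synthetic
cohort generator and the numerical choices behind `illdeath`.

## The illness-death model

Patients move through three states — treated, locally relapsed, dead —
with one-way transitions.  Death is a terminal (semi-competing) event: it
censors local failure, never the reverse.  Each transition g has a
proportional cause-specific hazard

    h_g(t | x, w_i) = h_0g(t) exp(x'b_g + w_ig),     w_ig ~ N(0, s_g^2),

with a hospital-level Gaussian random intercept (lognormal frailty) per
transition.  The analysis unit is the treated lesion for transition 1
(treatment → local failure) and the patient for transitions 2 (treatment
→ death without prior relapse) and 3 (relapse → death).  Clustering of
lesions within patients is deliberately ignored for transition 1: the
median patient contributes a single lesion, so a patient-level frailty is
not identifiable and would mostly absorb noise.

**Markov (clock-forward) assumption.**  After the first relapse at time
r the death hazard switches from h_2 to h_3, both evaluated at time since
first treatment — not time since relapse.  Transition 3 is therefore fit
with delayed entry (left truncation) at r on the shared clock.  A
semi-Markov (clock-reset) variant would instead index h_3 by t − r; the
clock-forward form is the one implemented and tested (the clock-reset
alternative is a different estimand, not a knob).  The ratio
h_03(t)/h_02(t), the *explanatory hazard ratio*, summarises how much
losing local control costs in survival: values above 1 mean a relapsed
patient faces a higher death hazard than a relapse-free one with the same
covariates and frailty.

**Time-dependent-covariate alternative.**  Treating relapse as a 0→1
time-dependent indicator Z(t) on a shared baseline gives
h(t) = h_0(t) exp(Z(t) b_0 + x'b + w) with a constant ratio exp(b_0).
This is implemented (`tdcov_hazard_ratio`) as a comparator for the
time-varying baseline ratio, not as the primary model.

**Tie convention.**  If a death and a relapse are recorded at the same
resolution-limited time, death is taken to have happened first and local
control is censored.  Recorded times are rounded to 0.01 month in the
generator to exercise this rule.

## Estimation

### Frailty Cox regression (`frailty.py`)

The Breslow partial log-likelihood l(b, w) treats the frailties as
cluster offsets; risk sets respect delayed entry (at risk at event time t
iff entry < t ≤ exit).  The frailties are integrated out by the Laplace
approximation around the joint mode:

    logML(s2) = l(b^, w^) − w^'w^/(2 s2) − (c/2) log s2
                − (1/2) log det(H_ww + I/s2),

with H_ww the frailty block of the observed information of l.  The inner
problem (b, w at fixed s2) is solved by damped Newton with step-halving;
the outer profile over s2 runs on the log scale over [1e-6, 4] with a
bounded Brent search (tolerance 1e-6), and the boundary fit s2 = 0 (plain
Cox) is kept whenever it dominates.  Standard errors come from the
inverse penalized information at the mode; they do not propagate s2
uncertainty, which the recovery experiments show is negligible at these
cluster counts.  Convergence: relative objective change < 1e-8, max 200
iterations; |b| > 15 triggers a separation warning rather than an error.
A Monte-Carlo importance-sampling check of the frailty integral
(`mc_refine_loglik`) is available as a diagnostic of the Laplace quality;
it is never the estimator.

Ties use the Breslow approximation throughout — the simplest choice
consistent between the partial-likelihood fit, the Breslow baseline and
the spline likelihood.

### Penalized spline hazards (`spline.py`)

Baselines are expanded as h_0(t) = Σ c_k M_k(t) on cubic M-splines
(order 4), the non-negative rescaling of B-splines that integrate to one;
c_k ≥ 0 guarantees h_0 ≥ 0 and the cumulative hazard is the matching
I-spline combination.  Default knots: 9 in total — boundaries at 0 and
the 99th percentile of exit times, 7 interior knots at event-time
quantiles ("9 knots" is read as the total count; it is a constructor
argument, not a constant).  Beyond the upper boundary the hazard is
extended at its boundary value.

The full log-likelihood (events contribute log h, every row contributes
−ΔH over its at-risk interval, frailty again by Laplace — the w-Hessian
is diagonal for the full likelihood) is penalized by κ ∫ h_0″(t)² dt; the
curvature Gram matrix is computed exactly with 2-point Gauss quadrature
per knot interval (the integrand is piecewise quadratic).  Optimisation
runs on ξ = log c plus (β, w) with analytic gradients via L-BFGS-B
(ftol 1e-12, max 500 iterations), initialised at the constant hazard
events/exposure.  The parameter covariance used for Monte-Carlo bands is
the inverse of the analytic penalized information on the (c, β) scale.

κ is selected by an approximate leave-one-out likelihood score:
l(θ̂_κ) − tr(H_pen⁻¹ H_unpen), i.e. fit likelihood minus effective
degrees of freedom, maximised over a grid (default 10²…10⁶).  No
refitting per fold is done; the score is deterministic given data and
grid.

### Predictions (`predict.py`)

All displayed predictions set the frailty to zero (the cluster-average
hazard) and use the "average" covariate profile: continuous covariates at
their mean, binaries at their mode.

* TCP(t|x) = exp(−H_01(t) e^{x'b_1}).
* Dose for a target TCP inverts this in the standardised BED covariate
  analytically, back-transforms through the stored (mean, 2·sd), and
  converts to a fractionation schedule via the quadratic BED inversion.
  Requires a protective dose effect (b_BED < 0); a required BED above a
  physical ceiling (default 1000 Gy_10) raises an infeasible-target
  error rather than reporting a clinically meaningless dose.
* Baseline hazard ratio: h_03(t)/h_02(t) on a grid that should start at
  the earliest observed relapse (the earliest time h_3 is estimable).
* Cumulative transition probabilities, with
  S(u) = exp(−H_1(u|x) − H_2(u|x)):

      P2(t) = ∫_0^t S(u) h_2(u|x) du
      P3(t) = ∫_0^t S(u) h_1(u|x) [1 − e^{−(H_3(t|x) − H_3(u|x))}] du

  evaluated by composite Gauss–Legendre quadrature (24 panels × 8 nodes
  scaled to [0, t] for every grid time, so no panel is ever truncated);
  the tests match these against closed forms for constant hazards at
  1e-6 and check conservation P2 + P3 + occupancy = 1 at 1e-4.

* 95% bands: parameters drawn from the multivariate normal at the
  penalized-likelihood mode with the fit covariance (default 500 draws);
  negative drawn spline coefficients are truncated at zero.  Bands are
  pointwise quantiles, clipped to contain the point estimate.  Transition
  fits are drawn independently — their parameters come from separate
  likelihoods, so the joint covariance is block-diagonal.  Averaging
  predictions across imputed copies, when requested, averages curves,
  not parameters.

## Cohort preparation (`prep.py`)

Continuous covariates (BED_iso, tumour volume) are standardised by
(x − mean)/(2·sd), putting their hazard ratios on a "high vs low"
scale comparable to a binary covariate's; the constants are stored for
inverse transforms.  Dichotomisation cut-points: age ≥ 66, KPS ≥ 90,
> 1 treated metastasis.  Transition 2 rows are censored at the first
observed relapse (a state transition, not loss to follow-up); each
patient's transitions 2 and 3 partition their follow-up at the relapse
time, so deaths are counted exactly once across the two.  An
events-per-covariate guard warns (never fails) when a transition's
covariate count exceeds events/15.

**Imputation.**  Chained equations: each incomplete variable is
regressed on the predictors passing a correlation-and-usability screen —
|Spearman ρ| ≥ 0.2 on pairwise-complete cases and usable-case proportion
≥ 0.25 (Spearman is a design choice; only the thresholds are fixed by
convention).  Continuous variables use predictive mean matching with 5
nearest donors and a posterior draw of the regression coefficients;
binaries use a logistic draw; a variable with no eligible predictors
falls back to marginal resampling with a warning.  Volumes are imputed
on the log scale (they are strongly right-skewed); chemotherapy is
imputed at the patient level and propagated to lesions; the per-patient
maximum volume is refreshed from completed lesion volumes.  Default 50
copies, 8 chained passes; the pipeline's fast profile uses m = 5.
Pooling follows Rubin's rules: pooled point = mean, pooled variance =
within-mean + (1 + 1/m)·between.  Frailty variances are not pooled —
their median across copies is reported.

**Descriptives.**  Fisher's exact test for 2×2 categorical comparisons
(a seeded Monte-Carlo exact test for 2×k, k > 2, where full enumeration
is infeasible) and the two-sided Wilcoxon rank-sum test for continuous
variables.

## The synthetic cohort generator (`synthetic.py`)

The generator emulates a multicentre SBRT registry: 27 hospitals with
Poisson-sized patient loads (mean 14.4, ≥ 1), 1–6 lesions per patient
with frequencies (82.7, 10.8, 3.4, 1.8, 0.5, 0.8)%, site mix 58.2% liver,
chemotherapy prevalence 84.5%/68.5% (liver/lung), KPS ≥ 90 at 65.7%,
lognormal volumes (medians ≈ 26 ccm liver, 3.1 ccm lung), BED_iso normal
around 125/141 Gy_10 clipped to [37.5, 310].  Event times are drawn by
inverse-transform sampling of each cumulative cause-specific hazard —
closed form for Weibull baselines, grid interpolation (default step
bounded by the tabulation grid) otherwise.  Death follows H_2 up to the
latent relapse (the minimum over the patient's lesion failure times) and
H_2(r) + H_3(t) − H_3(r) beyond it.  Censoring is uniform dropout on
[6, 96] months truncated at the 96-month administrative horizon.

Default Weibull baselines (scales 320/52/8 months, shapes 0.9/1.1/1.1)
were chosen so the preset reproduces the registry's outcome mix —
about 22% lesion failures, 26% relapsed patients, 53% deaths, with most
relapsed patients dying in follow-up — and default frailty SDs are 0.3
per transition (the registry analysis does not report fitted frailty
variances; 0.3 gives clusters heterogeneous enough to make the frailty
machinery testable without dominating the fixed effects).

Missingness is injected separately, MCAR by default at registry rates
(volume 31.6%, KPS 27%, chemotherapy 14%, multiplicity 21.6%); an MAR
option masks lung volumes at twice the liver probability.  When a volume
is masked, its PTV surrogate stays observed for 63% of lesions,
mirroring planning volumes usable by the imputation.

What the generator does **not** emulate: the registry's joint covariate
dependencies beyond these marginals, within-organ lesion location,
time-varying treatment practice, or measurement error in volumes and
dates.  Passing recovery tests therefore demonstrates the correctness of
the estimators under the stated model, not robustness to real-data
violations of it.

## Validation designs and problem sizes

* Oracle equivalence: with s2 = 0 the frailty fit must match a
  brute-force Newton Cox solver with row-by-row enumerated risk sets to
  1e-6 on ≤ 20-row datasets, and lifelines on larger ones.
* Parameter recovery (transition 1): 50 replicates of the 27-cluster,
  ~500-lesion preset with b_BED = −0.9 and s = 0.3, on a constant
  baseline (1/40 per month) with uniform censoring on [24, 96] months —
  an event fraction near 50%, chosen so the replicate mean has standard
  error ≈ 0.02.  Transitions 2–3 use analogous single-covariate designs
  at 100 replicates (patient-level fits are cheap and the binomial
  coverage estimate is sharper).  The time-dependent-covariate
  comparison generates h_3 = e^{0.7} h_2 on a shared Weibull baseline
  and checks exp(b_0) within 3 SE.
* Spline sanity: heavy smoothing (κ = 1e6) on constant-hazard data must
  recover the constant within 15% over the inner 80% of follow-up; the
  unpenalized fit must track the Breslow cumulative hazard.
* Prediction oracles: exactly-constant-hazard spline fixtures (the
  partition-of-unity coefficients) give closed-form TCP, hazard-ratio
  and transition-probability curves matched to 1e-6.

## Known limitations

* Standard errors condition on the estimated frailty variance and the
  selected κ.
* The Laplace approximation can be optimistic for very small clusters or
  very large s2; the MC refinement diagnostic exists to check this.
* The imputation model is fully conditional-specification without a
  joint-model guarantee; its validation here is under MCAR/MAR only.
* Transition 1 ignores within-patient lesion clustering by design.
* No interval censoring, no time-varying covariates inside the spline
  fit, no gamma-frailty alternative, no stratified baselines.
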