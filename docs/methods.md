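# Methods

## The model

`exhaz` estimates the mortality attributable to a cancer in population-based
registry data without using causes of death.  The all-cause hazard of a
patient at time `t` since diagnosis is decomposed as

    lambda_obs(t) = lambda_E(a + t, y + t) + lambda_plus(t, a, y, i | w)

where `lambda_E` is the expected (general-population) mortality rate matched
on sex, attained age, calendar year and region, read from external life
tables, and `lambda_plus` is the excess hazard.  The excess hazard is the
flexible multiplicative model

    lambda_plus(t, a, y, i | w) =
        lambda_0(t) exp( g(a) + h(t) a + j(y) + k(t) y + m(i) + n(t) i + w )

with `a` age at diagnosis, `y` year of diagnosis, `i` an ecological
deprivation index (EDI, higher = more deprived) measured on the patient's
small-area census unit (cluster), and `w ~ N(0, sigma^2)` a frailty shared by
all patients of the same cluster.  Exponentiating minus the cumulative
excess hazard gives net survival — the survival that would be observed if
the cancer were the only cause of death — which is the quantity compared
across deprivation groups.

Basis functions:

* `log lambda_0`, `h`, `k`, `n`: quadratic B-splines of time with interior
  knots at 1 and 5 years.  Boundary knots are fixed at [0, 10] years, the
  analysis horizon; follow-up beyond 10 years must be administratively
  censored beforehand (the `fit` entry point refuses longer times).
* `g`, `j`, `m`: quadratic truncated-power splines `[x, x^2, (x-k)_+^2]`
  with one knot at age 70, year 2000 and EDI 0 respectively.

Two identifiability/conditioning conventions are our own choices (the model
family itself does not fix them):

* Time-dependent coefficient functions use the B-spline basis with its
  first column dropped.  The first basis function is the only one positive
  at t = 0, so the remaining four columns vanish there: `h`, `k`, `n` are
  anchored at 0 at diagnosis and cannot be confounded with the
  time-constant linear terms.  (The equally valid alternative of dropping a
  constant from a re-parameterized basis gives the same model space.)
* Covariates are centered at their knots (70 / 2000 / 0) before basis
  expansion.  Reported hazard ratios are invariant to centering; the intent
  is purely numerical conditioning.  The absorbed terms (e.g. `h(t) * 70`)
  lie in the span of the baseline spline, so the likelihood is unchanged.

A Weibull baseline with linear, time-constant, proportional effects is
available as the deliberately simple benchmark model.  It is parameterized
internally as `log lambda_0(t) = b0 + b1 log t` (shape = `b1 + 1`, bounded
below at 0.05 during optimization), which keeps the whole design linear in
the parameters; shape and scale are exposed as derived properties and the
cumulative hazard uses the closed form.

## Estimation

The marginal likelihood integrates the cluster frailty out of the product
of individual contributions `(lambda_E + e^w lambda_plus)^delta *
exp(-e^w Lambda_plus)`; the parameter-free factor `exp(-Lambda_E)` is
dropped.  Numerical choices, each validated against a brute-force oracle in
the test suite:

* **Frailty integral**: adaptive Gauss-Hermite quadrature, 10 nodes by
  default, centered at the per-cluster posterior mode and scaled by the
  curvature there (safeguarded Newton iterations, vectorized across
  clusters).  Plain 10-node quadrature is inadequate for small clusters
  with strong data signal; the adaptive version reproduces a 100k-point
  trapezoid integral to ~1e-8 for 3-patient clusters and degrades
  gracefully to the no-frailty likelihood as sigma -> 0.
* **Cumulative excess hazard**: composite Gauss-Legendre quadrature with 64
  nodes by default, split across the knot-delimited segments of [0, t].
  The integrand exp(quadratic spline) is analytic between knots but only
  C^1 at them; splitting restores spectral accuracy (~1e-10 relative,
  versus ~1e-6 for a single panel).  32 nodes are indistinguishable at
  double precision and are used in the heavier simulation studies.
* **Gradients** are analytic.  With frailty, the score is the
  quadrature-weighted posterior expectation of the complete-data score,
  which is exact for the frozen-node objective and accurate to the
  quadrature error for the adaptive one (validated against central finite
  differences).
* **Optimizer**: two-stage L-BFGS-B — hazard parameters without frailty
  first, then all parameters including `log sigma` — on internally rescaled
  coordinates (each design column divided by its root-mean-square; the
  quadratic age column spans ~3 orders of magnitude and cripples
  quasi-Newton conditioning otherwise).  Failures restart from perturbed
  initial values and are reported, never silent.  `sigma` is estimated on
  the log scale, keeping the domain unconstrained; its Wald CI is formed on
  the log scale and back-transformed.
* **Covariance**: inverse of the observed information, obtained by central
  finite differences of the analytic gradient at the optimum; a singular
  information falls back to the pseudo-inverse and clears the `converged`
  flag.
* The expected hazard in the event factor is looked up at the event time
  (attained age/year), using floor + clamping (age 99, last table year) —
  the standard life-table convention; the exact decimal convention of other
  implementations is not documented, so this choice is ours.
* Feasibility rule: fitting refuses models with fewer than 10 events per
  parameter unless explicitly overridden, mirroring registry practice of
  excluding sparse site-sex strata.  The rule is a debated heuristic, hence
  the override.

Left truncation/delayed entry is unsupported (incident cohorts only), and
cause-of-death information is never used.

## Model building

`backward_eliminate` starts from the full model (nonlinear + time-dependent
effects of age, year and EDI: 27 parameters) and iteratively removes
spurious components by likelihood-ratio tests at level alpha = 0.05: each
round fits every one-component-simpler model, then removes the single
component with the largest p-value above alpha.  Nonlinear blocks carry
2 df, time-dependent blocks 4 df.  Linear time-constant main effects are
never candidates, so every final model retains the simplest form of each
variable.  The within-round order is not prescribed by the strategy we
follow; our single-worst-first rule is deterministic and fully recorded in
the returned trace (component, statistic, df, p, decision per test), so a
selection path can always be audited.  Candidate fits are warm-started from
the current model with the removed block zeroed.

## Indicators

* **Net survival** for a covariate profile: `exp(-Lambda_plus(t))`
  conditional on a median cluster (w = 0), or marginalized over the frailty
  by 64-node Gauss-Hermite quadrature.  Reported predictions default to the
  conditional version; goodness-of-fit comparisons use the marginal one
  because that is the estimand the nonparametric estimator targets.  Every
  table records which was used.
* **ASNS** (age-standardized net survival): ICSS-weighted mean over age
  groups [15,45), [45,55), [55,65), [65,75), 75+ (weight sets 1-3 shipped;
  a merged [15,55) variant covers sparse data).  Each group is represented
  by a configurable representative age (defaults: group midpoints, 85 for
  75+), making predictions data-free and reproducible; deprivation
  quintiles are represented by their within-data median EDI by default,
  with the French general-population cut points (-2.9, -1.4, 0, 2.1)
  shipped as a constant.
* **ASNS confidence intervals**: delta method assuming normality of
  `log(-log S)` (the log cumulative excess hazard); the gradient with
  respect to the full parameter vector is computed by central finite
  differences (relative step 1e-5) and the interval back-transformed, so it
  always lies in [0, 1].
* **EHR surface**: `EHR(i, t) = exp(m(i) - m(ref) + n(t)(i - ref))`,
  constant in `t` for proportional specs, with delta-method CIs on the log
  scale; plotting clips the EDI axis to the 5th-95th data percentiles.
* **MEHR** (median excess hazard ratio): `exp(sqrt(2) sigma Phi^-1(0.75))`,
  the median factor separating the excess hazards of identical patients in
  two randomly chosen clusters ordered by risk.  Computed from the
  deprivation-adjusted and unadjusted fits side by side: the drop measures
  how much of the general contextual effect the deprivation index explains.

## Pohar-Perme estimator

The nonparametric cross-check weights each subject's counting process by
the inverse of their expected survival, `w_j(u) = exp(Lambda_E,j(u))`.  The
cumulative excess hazard accumulates event increments
`sum w_j dN_j / sum w_j Y_j` on the event-time grid and subtracts the
expected-hazard integral `int sum(w Y lambda_E) / sum(w Y) du`, stepped at
daily resolution (1/365.25 years) on a grid that also contains every
event/censoring time — the exact piecewise integration of the life-table
module bounds the residual stepping error far below sampling noise.
Variance uses the counting-process formula `sum w_j^2 dN_j / (sum w Y)^2`.
Estimates may exceed 1 in noisy strata; raw values are kept and flagged
because silent truncation would bias the model comparison.  In the
age-standardized version, empty age groups are dropped with weights
renormalized and a flag recorded (how sparse strata should be treated is
not prescribed; this is our documented choice).  Evaluation times beyond
the last observed follow-up carry the last value forward, flagged.

## Synthetic registry generator

No registry extract ships with the package; all validation runs on
synthetic cohorts whose structure mirrors the analysis assumptions:

* clusters analogous to ~2000-inhabitant census areas, contributing
  Poisson-distributed (truncated >= 1) patient counts;
* a cluster-level deprivation index `loc + scale * exp(shape Z)`
  (defaults -4.7 + 3.9 exp(0.7 Z)), giving quintile cut points near
  (-2.4, -1.4, 0.2, 2.8) and a long right tail reaching ~+15 over a few
  hundred clusters — close to the French general-population cut points
  (-2.9, -1.4, 0, 2.1), though the extreme tails of the real index
  (-17.3 to 51.1) are only reached in very large draws.  All patients of a
  cluster share its EDI (ecological design); optional within-cluster
  jitter exists for robustness experiments and defaults off;
* age at diagnosis truncated-normal (mean 68, SD 12, support (15, 99]);
  diagnosis years uniform on 1997-2010.5; administrative censoring at
  mid-2013 and at the 10-year horizon;
* background mortality from a synthetic Gompertz life table
  (2e-5 * exp(0.10 * age) by default) or a constant table;
* excess event times invert `e^w Lambda_plus(t) = -log U` by bracketed
  bisection on the quadrature-evaluated cumulative hazard (tolerance 1e-8
  in cumulative-hazard units); background death times invert the exact
  piecewise-linear expected cumulative hazard analytically.  The observed
  time is the minimum of the two with censoring; the true cause and
  frailty values are retained only behind `return_latents` and never reach
  estimators.

Preset scenarios fix the generating parameters of the validation studies:
`null` (no covariate effects, sigma = 0.2), `linear_ph` (per-unit EDI
log-EHR 0.05, sigma = 0.3, 200 clusters x 25 patients), `nonlinear_plateau`
(slope flattening among the most deprived), `late_td` (effect emerging
after the first year) and `reversing_td` (log-EHR +0.15 per unit at
diagnosis crossing zero near 1 year and settling at -0.08, the pattern
where a deprivation gap in 1-year survival vanishes by 5 years).  The
default baseline declines from ~0.5 to ~0.05 per person-year, giving
5-year net survival around 0.5 — a mid-prognosis cancer.

What the generator does not emulate: spatial correlation between clusters,
deprivation-specific background mortality (real general-population tables
ignore deprivation, a known source of bias discussed in the literature),
incidence dynamics, loss to follow-up other than administrative censoring,
and EDI measurement error.  Passing tests therefore demonstrate internal
correctness and frequentist calibration under the stated mechanism, not
robustness to these real-data features.

## Validation problem sizes

The test suite validates operating characteristics at sizes chosen to keep
the full run in minutes on one CPU: parameter recovery over 50 replicates
of 200 clusters x 25 patients; CI coverage over 100 replicates of 60
clusters x 20; selection type-I behaviour pooled over 20 replicates x 6
spurious components (binomial band), with power against the reversing
time-dependent effect checked on 3 replicates of ~5000 patients; the
heavier simulation fits use 32 quadrature nodes (shown equivalent to 64 at
double precision).

## Known limitations

* The frailty enters at one level only; nested or crossed clustering and
  intraclass-correlation summaries are out of scope.
* Interactions between covariates (beyond each variable's own
  time-dependence) are not modeled, matching the additive log-hazard form.
* The delta-method ASNS interval ignores uncertainty in the choice of
  representative profiles and quintile representative EDIs.
* Sparse strata: the EPV-10 refusal is a blunt guard; penalized or
  Bayesian alternatives are not provided.
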