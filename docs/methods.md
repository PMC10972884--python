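# Methods

This note documents the model, the estimation machinery, the synthetic
cohort generator and the numerical/design choices behind `pedpk`, in the
order a reader would meet them.

## Structural model and its assumptions

A one-compartment disposition model with first-order absorption describes
oral cetirizine in children aged 0.5–14 y. Because sparse TDM sampling
cannot identify absorption separately, the absorption rate constant is
tied to elimination by a flip-flop construction, `ka = θ_ka + CL/V`, with
`θ_ka > 0`; this guarantees `ka − ke = θ_ka` exactly for every covariate
and random-effect combination, so absorption is always the slower-looking
phase never collapses onto elimination. The assumptions that matter:

* linear (dose-proportional) PK — superposition is used for arbitrary
  dosing histories and the steady-state profile is the closed-form
  geometric accumulation of the single-dose curve;
* covariates enter as centered linear multipliers,
  `CL/F = tvcl·(1 + cl_age·(age − age_ref))·(1 + cl_sex·I[female])` and
  `V/F = tvv·(1 + v_age·(age − age_ref))`; the constructor rejects any
  parameter set whose multipliers are not strictly positive over the full
  supported age range, so no valid object can produce a negative
  clearance or volume;
* inter-individual variability is lognormal on CL/F and V/F only
  (`η ~ N(0, ω²)`, diagonal Ω); none on `ka`, whose typical value is
  conventionally fixed;
* residual error is proportional plus additive,
  `y = f·(1+ε₁) + ε₂`, with the additive part defaulting to zero.

Weight deliberately does **not** enter the structural model (it is kept
for mg/kg dose accounting only): a weight-based alternative was compared
against the reference exposure table during calibration and fits clearly
worse than the age-linear form (the comparison is kept as a test in
`tests/test_reference.py`), and adding weight on top of age bought no
meaningful improvement.

## Units

Internally doses are mg, volumes L and times h, so model concentrations
are mg/L; all reported concentrations are scaled ×1000 and labelled µg/L
(= ng/mL). With single doses of 2.5–10 mg and pediatric volumes of
10–50 L this puts steady-state peaks at 150–600 µg/L, the range TDM
assays report for this drug. Reference tables printing "µg/mL" at these
magnitudes are read as µg/L.

## Default parameters: a calibrated reconstruction

The package's defaults (`pedpk.reference`) are **not** fitted clinical
estimates — no raw pediatric dataset ships with the package. They are
reconstructed by deterministic least squares so that the model's *median*
steady-state peak and trough over lognormal IIV (computed with a fixed
2000-draw eta matrix, making the objective smooth and reproducible)
reproduce a reference exposure table of 12 virtual girls aged 1–12 y on
label doses. Calibrated values:

| parameter | value | unit | role |
|---|---|---|---|
| `tvcl` | 0.752 | L/h | CL/F of a male at age 0 (extrapolated intercept) |
| `cl_age` | 0.407 | 1/yr | fractional CL/F increase per year |
| `cl_sex` | −0.05 | — | assumed slight CL/F reduction in girls |
| `tvv` | 27.3 | L | V/F intercept |
| `v_age` | 0.035 | 1/yr | fractional V/F increase per year |
| `tvka` | 1.08 | 1/h | flip-flop absorption offset (fixed, not estimable from sparse data) |
| `omega2_cl` | 0.10 | — | IIV variance on CL/F (~32% CV) |
| `omega2_v` | 0.15 | — | IIV variance on V/F (~40% CV) |
| `sigma2_prop` | 0.03 | — | proportional residual variance (~17% CV) |
| `sigma2_add` | 0 | (µg/L)² | additive residual variance |

Two consistency checks support the reconstruction: the implied absolute
age slope of CL/F for girls is ≈0.29 L/h/yr, matching the ~0.28 reported
for this population independently of any table, and the age-linear
covariate form beats weight-based alternatives on the same data (above).
The sex effect's magnitude is **not** identifiable from the all-female
reference table; −0.05 encodes the reported direction (slightly lower
CL/F in girls) as a configurable choice. The variance components are
likewise not printed anywhere and are field-plausible values for
pediatric sparse TDM, chosen once. Residual calibration error is real:
simulated medians track the reference peaks to ~3–10% and the troughs to
~5–20%, a pattern consistent with the reference values themselves being
Monte-Carlo medians of 1000 replicates (trough log-sensitivity to η is
~3× the peak's). The off-label reference table was generated by
posterior-conditioned (POSTHOC) simulation of real patients, so
population-typical simulation sits systematically ~10–20% below it; it is
therefore not used in calibration.

## Estimation

**MAP / POSTHOC.** For each subject the empirical-Bayes objective
`Σ_j[(y_j − f_j(η))²/g_j(η) + ln g_j(η)] + ηᵀΩ⁻¹η` (residual variance `g`
evaluated at η — the "interaction") is minimized by a damped Gauss-Newton
descent with an exact analytic gradient assembled from a batched
finite-difference Jacobian of `f`, Armijo backtracking and Levenberg
regularization. Standalone calls start from η = 0 plus one deterministic
jittered restart; inside the outer optimizer the previous mode is reused
as a warm start (with a prior-mode fallback if the warm run diverges).
Components with ω² = 0 are pinned at zero. A subject without observations
returns the prior mode, flagged `prior_only`.

**FOCE-I objective.** The per-subject −2 log marginal likelihood is the
Laplacian expansion about the MAP mode using the Gauss-Newton curvature
`GᵀWG + Ω⁻¹` (`G = ∂f/∂η` at the mode, `W = 1/g`), i.e. the
first-derivative linearization the method is named for. Two reasons: this
matrix is always positive definite (no fallback path), and on sparse
lognormal designs it tracks adaptive Gauss-Hermite quadrature of the true
marginal likelihood markedly better than the exact Hessian — the
validation suite holds the total discrepancy on a 10-subject, 3-obs
fixture below 0.5, which the exact-Hessian flavor did not meet (the
discrepancy of either flavor → 0 as ω² → 0, which validated the constant
bookkeeping). The OFV is additive over subjects; with Ω = 0 it degrades
exactly to the fixed-effects weighted least-squares deviance.

**Population fit.** The outer minimization over a user-chosen free subset
runs Nelder-Mead on a transformed scale (log for positivity-constrained
parameters, identity for covariate slopes), with per-subject warm-started
inner modes. Derivative-free was chosen deliberately: the inner
optimization makes the objective mildly noisy at the 1e-8 level, which
finite-difference outer gradients amplify. Convergence: `|ΔOFV| < 1e-4`
and relative simplex size `< 1e-4`; the best-so-far estimate is returned
(flagged) on hitting the evaluation budget. Fixed parameters are carried
through bit-for-bit. Parameter recovery on simulated cohorts (200
subjects × 3 observations, the problem size the recovery suite uses)
returns the covariate slope and `tvv` well inside 15% of truth and the
variance components inside 30%, in a few minutes on one CPU.

**Bootstrap.** Subjects are resampled with replacement (optionally
stratified by label/off-label dose group), each replicate refit with the
point fit's free set from the point estimates; summaries (median, SD,
percentile CI, % difference of median from the point estimate) use
converged replicates only, and the result is flagged unreliable if more
than half fail.

## Diagnostics

**CWRES** follows the FOCE convention: residuals are linearized about the
MAP mode, `r = y − f(η̂) + G η̂`, and whitened by the Cholesky factor of
`G Ω Gᵀ + diag(g(η̂))`. Observations are put in a canonical (time, value)
order before whitening — sequential Cholesky decorrelation is
order-dependent, and the canonical order makes CWRES invariant to how the
data file happened to be sorted.

**NPDE** simulates K replicates of each subject's exact design (doses,
times, covariates), decorrelates observed and simulated vectors with the
empirical mean and Cholesky factor of the simulated covariance, and maps
the half-count-corrected rank `(#{sims < obs} + 0.5)/K` through Φ⁻¹;
extreme ranks are clipped to `[1/(2K), 1 − 1/(2K)]` so the transform
stays finite. Global adequacy combines a t-test (mean 0), a χ² test
(variance 1) and Shapiro-Wilk (normality, d'Agostino above 5000
observations) at α = 0.05 with Bonferroni correction over the three.
Under the generating model the NPDE sample is standard normal (checked by
a self-consistency suite); a doubled clearance is reliably rejected.

## Simulation and the overdose workflow

Exposure metrics exclude residual (assay) error: they summarize the
model-predicted concentration, which is what a "median predicted
exposure" table means. Per virtual patient, `n_reps` eta pairs are drawn
as one `(n_reps, 2)` matrix — so a 1000-rep run is a prefix of a
10000-rep run at the same seed, making medians stable across replicate
counts — and the closed-form steady-state metrics are summarized by
medians and 5th–95th percentile bands. `T_max,ss` solves `dC_ss/dt = 0`
analytically (`t* = ln[(ka·b)/(ke·a)]/(ka − ke)` with `a`, `b` the
accumulation factors, clipped to the interval and verified against a
1e-4 h grid search); the trough is the pre-dose value `C_ss(τ)`; `AUC_τ =
dose/CL` exactly.

Dose flagging uses strict `>` against 0.25 mg/kg per administration and
0.5 mg/kg/day, plus the age-band label dose (2.5 mg bid under 6 y,
5 mg bid for 6–14 y; qd encodes as τ = 24 h, bid as τ = 12 h); a missing
weight yields an undetermined flag, never a silent pass.

The overdose forecast superposes the full dosing history including the
flagged error dose, optionally conditions on TDM observations through the
MAP mode, and scans a 0.1 h grid from the error dose for the earliest
*post-peak* time below a threshold — by default the typical steady-state
peak the intended reference regimen would itself produce (an exposure the
prescriber has already accepted). The washout is rounded up to the next
scheduled dosing slot to give a restart time; if the threshold is never
crossed within the horizon (96 h default) the forecast is flagged rather
than extrapolated.

## Synthetic cohorts

The generator emulates the study design the model targets: 63 children,
age bands occupied 10/22/33 (ages drawn log-uniform within the band),
~40% girls, label regimens by band with per-band off-label escalation
probabilities (5/10, 17/22, 2/33) and multipliers uniform on [1, 2] (all
escalations within a two-fold range), bid/qd dosing maintained past 144 h
(steady state by ~5 half-lives), and 1–3 samples per child. Weight
follows the pediatric rule of thumb `2·age + 8` kg with 15% lognormal
noise — adequate because weight is bookkeeping, not a model covariate.
Sampling times are uniform at 1–24 h after the *final* dose (the stated
TAD window exceeds the 12 h bid interval, so sampling is modeled as
occurring after dosing pauses; this keeps TAD ≡ time − last dose exact).
True etas are stored in dataset metadata for recovery testing, and
`truth_report` refuses non-synthetic data.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: assay quantification limits and BQL
censoring, adherence gaps and irregular dosing times, covariate
correlations beyond the weight-age rule, age-varying residual error, and
any absorption-phase sampling (the design samples ≥1 h post-dose at
steady state, which is exactly why absorption parameters stay fixed).

## Numerical choices

* Single-dose and steady-state profiles are written with `expm1`
  (`e^{−ke·t} − e^{−ka·t} = −e^{−ke·t}·expm1(−(ka−ke)·t)`), removing the
  catastrophic cancellation near `ka ≈ ke`; the explicit L'Hôpital limit
  form only engages below a relative gap of 1e-12, where its first-order
  truncation error is far below 1e-8.
* Residual variances are floored at 1e-12 to keep zero-prediction corner
  cases finite.
* The pde → npde transform's extreme-rank clipping and the Bonferroni
  α-split are stated above; tie probability is zero for continuous
  simulators, so no further tie-breaking is needed.
* Superposition rejects unsorted dose histories instead of silently
  sorting, and the dataset reader reports the offending file row for
  every dialect violation.

## Known limitations

* The defaults are a reconstruction conditional on a published summary
  table, not a refit of raw data; absolute exposure predictions inherit
  that table's Monte-Carlo noise (see calibration section).
* Diagonal Ω only; no SAEM/importance sampling; no covariance-step
  standard errors (the bootstrap is the intended uncertainty tool).
* One compartment, linear elimination, no covariates on `ka`, no
  weight-based dosing optimization.
* The FOCE-I approximation degrades for very large ω² combined with very
  few observations per subject, as for any linearized method.
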