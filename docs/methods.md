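# Methods

This note documents the models, algorithms and design choices behind
`vancomipd`, in the order data flows through the engine: population PK
models → concentration dynamics → Bayesian individualization → dose
decision support → evaluation and simulation.

## Population pharmacokinetic models

Three published vancomycin models are shipped in the registry
(`src/vancomipd/models.yaml`); constants live in data, equations in code.

**Neonatal one-compartment model** (`frymoyer_neonatal`), for patients
under 52 weeks postmenstrual age (PMA):

    CL (L/h) = 0.345 · (Wt / 2.9 kg)^0.75 · (1 / SCr)^0.267 · Fmat(PMA)
    Fmat     = 1 / (1 + (PMA / 34.8)^-4.53)
    V (L)    = 1.75 · (Wt / 2.9 kg)

The maturation sigmoid is half-maximal at 34.8 weeks PMA and approaches 1
as PMA grows; interindividual variability (IIV) is 21.6% on CL and 10.9%
on V; residual error combines 20.5% proportional with 1.3 mg/L additive.

**Pediatric one-compartment model** (`le_pediatric`), the default for the
≥52-week tier:

    CL (L/h) = 0.248 · Wt^0.75 · (0.48 / SCr)^0.361 · (ln(Age_d) / 7.8)^0.995
    V (L)    = 0.636 · Wt

IIV 35% (CL) and 18% (V); residual 29% proportional, no additive term.

**Adult/adolescent two-compartment model** (`thomson`), selectable for the
pediatric tier by configuration (`pediatric_model="thomson"`):

    CL (L/h) = 2.99 · (1 + 0.0154 · (CrCl − 66))
    V1 = 0.675 L/kg,  V2 = 0.732 L/kg,  Q = 2.28 L/h

V1 and V2 scale linearly with body weight as published (L/kg); CL and Q
are used as printed without weight scaling. CrCl is taken from the bedside
Schwartz eGFR (0.413·height/SCr, ml/min/1.73 m²) used directly as ml/min;
setting `crcl_denormalize_bsa=True` instead de-normalizes by Mosteller
body surface area. IIV is 27/15/130/149% on CL/V1/V2/Q — the very wide
V2 and Q variances are used as printed.

Model selection: PMA < 52 weeks → neonatal model; PMA ≥ 52 weeks (with
gestational age known) or chronological age ≥ 3 months (gestational age
unknown) → pediatric tier. A patient under 3 months with unknown
gestational age is refused with an explicit "model undetermined" error
rather than silently guessed. PMA of exactly 52 weeks goes to the
pediatric tier.

Conventions and guards:

* **CV% → ω.** IIV percentages map to log-normal standard deviations as
  ω = CV/100, the convention under which these models' variances were
  reported; `cv_to_omega="exact"` switches to ω = √ln(1+CV²) for users who
  prefer the exact log-normal relation.
* **Creatinine floor** of 0.1 mg/dL before any covariate equation, so
  assay-low values cannot blow up the renal term.
* **Time-varying covariates** are carried forward (LOCF): each dose's
  contribution is evaluated with the parameters implied by the covariates
  in effect at that dose's start, keeping the superposition closed-form
  while letting a mid-course creatinine change alter subsequent kinetics.
  Values before the first record use the first record.

## Concentration dynamics

Both structures are linear, so every dose contributes a sum of
exponentials and histories superpose. The two-compartment macro-constants
come from the micro-constants k10 = CL/V1, k12 = Q/V1, k21 = Q/V2 through
the standard quadratic eigen-decomposition (α+β = k10+k12+k21,
αβ = k10·k21). Infusions are zero-order over their duration (default 1 h
when the record does not say, configurable per dose); concentrations,
troughs and AUCs all use exact closed forms — the 0.1 h plotting grid is
display-only.

Steady-state metrics for a regimen (dose D every τ, infused over T):

* AUC24,ss = (24/τ)·D/CL, exact for any linear model.
* Trough,ss is the closed-form concentration at exactly t = τ after a dose
  start (immediately pre-dose), the convention matching trough-based TDM;
  each exponential term accumulates by the geometric factor 1/(1−e^{−λτ}).

The analytic solutions are verified in the test suite against an
independent ODE integration (piecewise RK45 at rtol 1e-10) to 0.1%
relative error over randomized parameters, dose histories and times.

## MAP estimation and uncertainty

Individual random effects η (log-scale, one per variable parameter) are
estimated by maximizing the posterior under the population prior
η ~ N(0, diag(ω²)) and the combined residual model. The objective, on the
−2·log scale, is extended least squares:

    OFV(η) = Σ_j [ (y_j − f_j(η))² / g_j² + ln g_j² ] + Σ_i η_i²/ω_i²
    g_j²   = (prop · f_j)² + add²

with g evaluated at the individual prediction f_j. Minimization runs a
Nelder–Mead start followed by BFGS refinement from η = 0 (tolerance 1e-8
on the objective); the search is unbounded because the log-normal
parameterization keeps parameters positive. The posterior is summarized by
a Laplace approximation: covariance = 2·H⁻¹ with H the central
finite-difference Hessian (step 1e-4) of the OFV — the factor 2 converts
from the −2·log scale. With no usable observations the fit returns the
prior exactly (η = 0, covariance diag(ω²)). Observations flagged
"excluded", or timed before the first dose, never enter the fit (the
latter with a warning).

A property worth knowing: because g depends on f, the objective's ln g²
term has nonzero gradient even where the residual vanishes. Fitting
noise-free data therefore leaves a small systematic offset of order
prop² (≈0.04 for the neonatal model) in the recovered η that no amount of
sampling removes — it is a feature of extended least squares, not an
optimizer defect, and the test suite pins the optimizer separately against
an exhaustive η-grid search. Signed biases of individual-CL estimates
across simulated cohorts stay within a few percent.

Probability of target attainment propagates the remaining uncertainty:
N = 10,000 (default, configurable) η samples from N(η_mode, covariance)
(seeded; default seed 12345), closed-form AUC24,ss/MIC and trough,ss per
draw, exceedance fractions for AUC24 > 400 mg·h/L and trough > 20 mg/L. A
covariance that is not positive semi-definite is repaired by clipping its
eigenvalues at 1e-10, with a warning.

## Dose decision support

* **Reference table**: the current regimen and doses scaled by ±15% and
  ±30% (interval unchanged), each with steady-state metrics and attainment
  probabilities.
* **Custom regimen**: any dose/interval/infusion combination evaluated on
  the same path; infusion longer than the interval is rejected.
* **Regimen search** (`find_regimen`): exhaustive over an interval set
  (default {6, 8, 12, 24} h) × a rounded dose grid; feasible regimens must
  place the predicted metric (AUC24/MIC at the posterior mode, or trough)
  inside the target band; the winner minimizes distance to the band
  midpoint, with ties resolved to the longer interval and then the smaller
  dose. An empty feasible set raises an explicit no-feasible-regimen
  error. Because the AUC metric depends only on daily dose, fine rounding
  grids let every interval hit the midpoint and the tie-break then prefers
  q24h; trough-based bands discriminate between intervals.
* **Empiric start**: children receive 15 mg/kg per dose, q6h under
  12 years and q8h above, rounded to 1/25/50 mg grids (neonates, <40 kg,
  ≥40 kg — the grids are a package choice, configurable); a Schwartz eGFR
  below 75 ml/min/1.73 m² extends the interval to q12h with a
  reduced-renal-function flag (the guideline's "lower dosing" is not
  quantified, so the per-dose amount is kept and exposure reduced via the
  interval, always flagged for review); missing height yields a "renal
  function unverified" flag. Neonates get a model-based start: the dose
  grid searched against the configured target (default AUC24/MIC 400–600)
  under the neonatal prior alone.
* **TDM advice**: a trough before the fourth dose, or earlier when renal
  function is impaired or unstable — operationalized as eGFR < 75 or a
  creatinine rise > 0.3 mg/dL between consecutive values (a package
  operationalization; the clinical rule names the condition, not a
  threshold).
* **MIC** defaults to 1 mg/L and is overridden per course when an isolate
  MIC is available.

## Evaluation statistics

Prediction error is predicted − observed (mg/L); bias and precision are
the median PE and median |PE| with distribution-free 95% confidence
intervals from binomial order statistics of the sorted errors (below six
pairs the CI degrades to the data range, with a warning). The
percentage-within-25% uses the observed concentration as denominator,
boundary inclusive (|PE|/obs ≤ 0.25). Evaluation defaults to population
(a-priori, η = 0) predictions — the external-validation convention — with
an a-posteriori leave-latest-out mode (each observation predicted from a
fit to the observations before it) available.

## Synthetic cohorts

`generate_cohort` emulates a children's-hospital vancomycin population:

* Covariates are log-normal, pinned to published median/IQR summaries via
  σ = (ln q3 − ln q1)/(2·0.6745), truncated to plausible ranges by
  resampling. Neonatal: weight median 3.1 kg (IQR 2.2–3.9), age 44 days
  (21–76), creatinine 0.3 mg/dL (0.2–0.6), height 49 cm; gestational age
  is left-skewed and sampled as 42 − lognormal to match 39.3 (35.4–40.0)
  weeks; patients are resampled into the under-52-week PMA tier.
  Pediatric: age 6.0 years (1.7–13.4), weight 19.1 kg (9.7–42.6), height
  105 cm (73–148), creatinine 0.4 (0.2–0.6). Treatment duration is
  log-normal with median ~1 week.
* True individual PK: η ~ N(0, diag(ω²)) from the selected model.
* Dosing follows the empiric starting-dose rules; the first TDM is a
  trough drawn immediately before the fourth dose, with the model's
  combined residual error (or noise-free when toggled off; concentrations
  are floored at 0.01 mg/L as an assay floor).
* `attainment_report` runs the closed MIPD loop: per round, three doses of
  the current regimen, a trough before the fourth scheduled dose, a MAP
  refit on all data so far, the predicted steady-state exposure of the
  regimen in effect, then adjustment via the regimen search (effective at
  the next scheduled dose). Cumulative attainment at round r is the share
  of patients whose predicted exposure hit the criterion at any round ≤ r.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: covariates are sampled independently (no
age–weight–height growth correlation), every patient follows protocolized
dosing and sampling times exactly, there are no missed doses, charting
errors, non-trough levels, concomitant renal insults, or clinician
behavior; the residual and between-subject variability are exactly the
model's own. Attainment percentages from the simulator characterize the
engine under its own assumptions, not any clinical population.

* **Course splitting**: a new course starts when the gap since the
  previous dose strictly exceeds 14 days; a gap of exactly 14 days does
  not split.

## Numerical choices and problem sizes

Optimizer tolerances: Nelder–Mead fatol 1e-8/xatol 1e-6, BFGS gtol 1e-9;
Hessian step 1e-4; covariance eigenvalue clip 1e-10; trough/AUC closed
forms are exact. Monte-Carlo N defaults to 10,000 (standard error ≤ 0.005
on a probability), raised to 100,000 where a test compares against a
closed form at 0.01 absolute. The test suite uses 50 randomized
profile-oracle cases at 100 time points, 5 grid-oracle MAP cases at step
0.001 on [−1,1]², 200-patient recovery and 500-pair self-consistency
cohorts — sizes at which every Monte-Carlo tolerance is comfortably
resolved while the full suite runs in about a minute.

## Known limitations

* No nonlinear elimination, continuous infusions, dialysis, loading-dose
  logic, or AKI/toxicity prediction.
* No re-estimation of the population models; the registry is fixed data.
* The Laplace-plus-sampling posterior is an approximation; no full MCMC.
* Albumin/unbound-fraction effects are out of scope.
* Within the pediatric tier the one-compartment model is the default for
  all ages; the two-compartment adult model is a configuration choice, not
  an automatic switch at a specific age.
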