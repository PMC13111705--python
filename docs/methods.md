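# Methods

## The paradigm and the Bayesian benchmark

Every scenario pairs one private signal (the patient's symptom) with 1–3
advisor diagnoses, each signal pointing to appendicitis (A) or sigmoid
diverticulitis (S) with validity `Acc ∈ (0.5, 1)` — the probability the
signal points to the true disease.  With conditionally independent
signals and a uniform prior, Bayes' rule reduces on the log-odds scale to

```
logit p(A | signals) = Σ_i d_i · ln(Acc_i / (1 − Acc_i)),   d_i = ±1.
```

`bsim.design.posterior_prob` implements this log-odds form; the test
suite checks it against an explicit likelihood-product oracle to 1e-12
over random scenarios, plus direction-flip symmetry, monotonicity in
added evidence, and the equal-validity closed form
`1 / (1 + ((1−v)/v)^Δ)` in the net evidence margin Δ.

`evidence_signals` splits the same sum by source type into
`(x_PI, x_H, x_AI)`, the predictors of the social influence model.  The
convention is A-positive throughout: a signal toward A contributes
`+ln(Acc/(1−Acc))`.  On equal-validity data each component is an integer
multiple of ln 2, so the count-based and accuracy-weighted formulations
of the model are the same matrix — asserted exactly in the tests.

## Scenario rosters (synthetic reconstructions)

The original studies list their 52- and 72-scenario rosters in
supplementary material that is not available to this package, so the
shipped rosters are *synthetic reconstructions*, labelled as such in
their filenames and docstrings.  They match every structural property the
studies report:

- **Equal-validity design (52 scenarios).**  Full factorial over 1–3
  advisors × (type, direction) multisets × private-signal direction at
  validity 2/3 gives 68 scenarios.  The stated four posterior levels
  {0.5, 0.67, 0.80, 0.89} correspond to net-evidence margins 0–3; the
  only factorial cells outside those levels are 3-advisor teams whose
  advisors are unanimous (margin 4, level 0.94).  Excluding exactly those
  leaves 52 scenarios at exactly the four printed levels — the unique
  single-rule exclusion consistent with both the count and the levels.
  The generator exposes the exclusion predicate, so alternative rosters
  are one lambda away.
- **Varying-accuracy design (72 scenarios).**  3-vs-1 majority/minority
  teams; within a scenario all advisors of a type share an accuracy and
  the two types differ.  Eighteen accuracy geometries — three per
  posterior level, grid-searched once over 1% accuracy steps so the
  favored-disease posterior rounds to the six printed levels
  {0.56, 0.65, 0.75, 0.81, 0.89, 0.99}, balanced three HIGH (majority
  more accurate) vs three LOW — are crossed with the majority's type and
  direction.  The worked 0.81 geometry (majority 3 × 65% vs minority 55%,
  symptom with the minority) and the "majority 70% vs minority 55%"
  HIGH example anchor the set.  The minority always opposes the majority
  and the symptom sides with the minority; posterior levels are matched
  after half-up rounding to 2 dp to tolerate float drift.

## The generative model

`bsim.simulate` turns the measurement model into a generator.  Per
participant, weights are drawn as fixed effect + independent mean-zero
normal deviations (diagonal random-effects covariance — the studies
report variances only, never covariances, so none are invented).  Per
trial, perceived log-odds `η = bias + Σ β_k x_k + ε`, `ε ~ N(0, σ_ε²)`;
the choice is the argmax of `expit(η)` (a fair coin at exactly 0.5), and
confidence is `round(100 · max(p, 1−p))` clamped to the 50–100 integer
response scale.  An optional probability-matching choice rule exists but
is off by default: the studies specify no choice-noise mechanism beyond
the confidence readout.

Default cohort parameters are the published cohort-level estimates:
equal-validity profile β = (0.14, 1.41, 1.00, 0.87) with variances
(0.09, 1.95, 0.71, 0.53) over 60 participants; varying-accuracy profile
β = (0.20, 0.72, 0.302, 0.30), variances (0.33, 1.55, 0.11, 0.10) over
50.  The weight-model residual SD is not reported anywhere, so σ_ε
defaults borrow the only printed noise magnitudes — the
informational-influence residual SDs 0.24 / 0.25 — and are configurable.

What the generator does *not* emulate: response-time structure, order and
fatigue effects, payment incentives, and any systematic miscalibration of
the confidence scale beyond rounding/clamping.  Passing tests therefore
validate the estimation machinery on data from the model's own family,
not the behavioural claims on real data.

## Estimation

- **Social influence weights** (`fit_social_influence`): Gaussian linear
  mixed model of the perceived log-odds on `(x_PI, x_H, x_AI)` with
  per-participant random intercept and independent random slopes
  (statsmodels MixedLM with variance components).  REML by default for
  variance reporting; ML available for model comparison; the choice is
  recorded on the result.  The response is the logit of the implied p(A),
  clipped to [0.005, 0.995] before transform — 100% ratings are common on
  the integer scale and the original handling is unstated; 1% and 0.1%
  clips are a keyword away.  A 50% rating maps to log-odds 0 regardless
  of the recorded choice.  Fixed-effect inference uses the normal (z)
  approximation by default (the source analyses mix t(59)/t(49) and z
  reporting and never state a df method); residual-df t is an option.
  Non-convergence flags the result instead of raising; variance
  components at the zero boundary stay pinned at 0.
- **Weight contrasts** (`contrast_weights`): Wald contrasts from the
  fixed-effect covariance, `z = Δβ / √(var_a + var_b − 2 cov_ab)`.
- **Informational influence** (`fit_confidence_vs_posterior`): mixed
  model of logit-transformed confidence in the most likely diagnosis on
  its posterior probability (random intercept + slope), optionally with
  the advisor-type proportion and its interaction.  The original used a
  beta-family GLMM in SPSS; exact beta-GLMM point estimates are not a
  reproduction surface here (the real data are external), so the default
  engine is the Gaussian-on-logit model and parameter recovery validates
  it; a beta-likelihood engine is left unimplemented and raises.  Note
  the residual SD this model exposes lives on the logit scale, so TOST
  bounds derived from it are logit-scale bounds.
- **Normative comparison** (`normative_comparison`): trials kept when
  exactly one advisor type corroborates the private information (teams
  uniformly contradicting the symptom, and teams where humans and AI
  share a diagnosis, are excluded).  Binary follow-the-symptom outcome →
  population-averaged logistic GEE with participant clusters, exchangeable
  working correlation (the original states only "robust standard
  errors"; independence is an option) and sandwich SEs; confidence
  outcome → mixed model with random participant intercept.  Complete
  separation falls back to continuity-corrected cell log-odds with a
  flag rather than failing.
- **Majority models** (`majority_models`): binomial GLMM (logit link,
  random participant intercepts, variational Bayes fit via statsmodels
  BinomialBayesMixedGLM) for following the majority, and a linear mixed
  model for confidence in the majority's diagnosis, with advisor type
  (AI reference) × majority-accuracy condition (HIGH reference).  Cell
  means aggregate participant-first, as does every descriptive summary;
  a constructed unbalanced fixture in the tests pins the aggregation
  order.

## SESOI and TOST

The smallest effect of interest is d = 0.425 on the standardized scale,
doubled to 0.85 for interaction terms, then mapped to raw bounds
±0.85·σ_ε using the model residual SD.  The TOST runs two one-sided
tests of H0: β ≤ −Δ and H0: β ≥ +Δ (normal reference by default, t(df)
optional) and reports the 90% CI; the verdict satisfies exactly
`equivalent ⇔ max(p) < α ⇔ CI strictly inside (−Δ, Δ)` — the duality,
monotonicity in bounds and SE, and calibration against the closed-form
TOST power are all property-tested.

## Problem sizes and numerical choices

Stochastic guarantees run at the sizes the design implies: parameter
recovery at 200 participants × the 52-scenario roster over 100
replicates (mean fixed-effect error ≤ 0.1, 95% CI coverage within
[90%, 99%]); null calibration of the advisor-type GEE at 60 participants
over 100 replicates; TOST calibration at 500 analytic replicates.
Posterior "levels" are always matched after half-up 2-dp rounding.  TIE
scenarios (posterior exactly 0.5) keep a TIE label; descriptive analyses
use the A side as the most-likely reference there and record the policy.

## Interfaces

Rosters and cohorts are flat CSVs (confidence stored as integer percent
in files, fractions in memory; conversion only at the I/O boundary), with
JSON sidecars and reports carrying seeds, parameters, roster hashes and
engine names sufficient to regenerate any output.  The package is driven
as a library plus the numbered `analysis/` scripts and
`pipeline.run_pipeline`; no console-script CLI is installed, as the
intended users run the analysis drivers or import the functions.

## Known limitations

- The shipped rosters are reconstructions; real-roster idiosyncrasies
  (if the supplementary lists different accuracy triples or additional
  exclusions) would change descriptive cell compositions, though not the
  estimators.
- The integer confidence scale censors extreme perceived posteriors at
  100% (logit 5.29 after clipping); at the default generative parameters
  this attenuates recovered weights by well under the 0.1 tolerance, but
  heavier-tailed weight distributions would bias harder.
- The variational binomial GLMM understates posterior SDs somewhat
  relative to a full Laplace/quadrature fit; its coefficients are used
  for pattern-level conclusions, not precise interval claims.
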