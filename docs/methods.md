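# Methods

This note documents the statistical procedures implemented by `chdval`,
the assumptions behind them, and the design choices made where the
procedures admit more than one reasonable reading.

## Risk equations

Four absolute-risk models are implemented from their published
coefficient sets (`src/chdval/equation_constants.json`, version 1.0):

**UKPDS engine.** The annual hazard for a first CHD event is
q·d^(k−1) in year k of diabetes, with d = 1.078 and

    ln q = −4.4918 + 0.0573(age−55) − 0.6444·female − 0.9416·afro_caribbean
           + 0.3001·smoker + 0.1681(HbA1c−6.72) + 0.0843(SBP−135.7)/10
           + 1.3468(ln(TC/HDL) − 1.59)

so the t-year risk from diagnosis is 1 − exp(−q(dᵗ−1)/(d−1)); the
duration form multiplies q by d^T for attained duration T years, and
reduces bit-identically to the incident form at T = 0. Units are fixed
(mg/dL lipids, mmHg pressures, percent HbA1c); no auto-conversion. The
Afro-Caribbean adjustment is applied to African-American subjects and 0
to everyone else; the per-10-mmHg SBP coefficient is reported per mmHg
(exp(β/10)) when hazard ratios are derived.

**Framingham initial** (sex-specific): risk = 1 − S₀(t)^exp(m). The
linear predictor m includes the published intercept and steps over
total-cholesterol (<160, 160–199 ref, 200–239, 240–279, ≥280 mg/dL), HDL
(<35, 35–44, 45–49, 50–59, ≥60; reference 45–49 for men, 50–59 for
women — the two sexes were published with different reference cells) and
blood-pressure category. Blood-pressure stages follow the JNC
conventions used with these equations: optimal SBP<120 and DBP<80;
normal 120–129 or 80–84; high-normal 130–139 or 85–89; stage 1 140–159
or 90–99; stage 2–4 ≥160 or ≥100, the higher of the SBP- and DBP-implied
categories winning. Baseline survivals are published only at integer
t = 1..5; fractional horizons (needed at the default evaluation horizon
of 3.5 years) use linear interpolation of ln(−ln S₀) in t, with linear
cumulative-hazard scaling below t = 1. The `diabetes` indicator defaults
to 1 — every subject in the target population has diabetes — but is
configurable.

**Framingham secondary** (sex-specific, prior-CHD population): a
log-Weibull AFT model, risk = 1 − exp(−exp((ln t − m)/σ)) with
σ = 0.9994 (men) / 1.0313 (women). A coefficient β inside m implies the
hazard ratio exp(−β/σ).

## Synthetic cohorts

The generator emulates a managed-care type-2-diabetes cohort followed at
most 3.5 years, in two CHD-history strata with stratum-specific
covariate moments (e.g. no-history: age 59.8 ± 12.3, 56.7% female, HbA1c
8.0 ± 1.9, TC 200.8 ± 42.1, HDL 47.5 ± 12.9, duration 10.6 ± 9.1;
history: age 66.1 ± 10.4, 44.9% female). Continuous covariates are
truncated normals (gamma for diabetes duration, which is skewed and
non-negative) coupled by a Gaussian copula; DBP, which the summary
tables omit, defaults to N(78, 10) with correlation 0.6 to SBP, and a
mild 0.1 correlation links lipids and pressures; binaries are
independent Bernoulli draws. Truncation floors sit ≥2.6 SD below the
means, so realised moments match the targets to well within sampling
error.

Event times are generated by inverting a chosen true cumulative-risk
model at a uniform draw (closed form for every supported model), so the
analytic risk function doubles as a Monte-Carlo oracle. One latent
uniform drives two coupled event streams: the narrow (MI-only) stream
uses the model hazard directly, the broad composite stream scales it by
`fram_event_scale` (default 1.7, matching the observed excess of
broad-definition over narrow-definition event rates). Censoring is the
minimum of a 3.5-year administrative horizon and exponential dropout
with rate ln2/2.7, giving a median follow-up near 2.7 years. Covariate
missingness is injected completely at random; smoking (1.3%) and HDL
(20.7%) anchor the range, intermediate rates (TC 18%, HbA1c 6%,
pressures 3%, duration 2%) are fixed plausible medical-record gap rates
inside it.

What the generator does **not** emulate: the joint covariate structure
of any real health-plan population (correlations are stylised),
informative censoring, competing mortality risks, measurement error, and
non-random missingness. Tests passing on these cohorts therefore
demonstrate the correctness of the statistical machinery under its own
assumptions, not the field behaviour of the equations on real data.

## Discrimination

Harrell's c counts all usable pairs — the shorter observed time carries
an event, or times are tied with exactly one event (the censored subject
is then known to survive longer); pairs of tied event times are
unusable. Concordance means the shorter-lived subject has the higher
score; score ties count ½. The implementation counts pairs exactly in
O(n log n) with a Fenwick tree over score ranks and is tested for exact
agreement with O(n²) enumeration. The default 95% CI is a subject-level
bootstrap (1000 resamples, seeded); a crude Noether-type SE
√(c(1−c)/usable) is available where speed matters, e.g. when pooling
across imputations.

## Calibration

Subjects are ranked by predicted risk (stable ties) and cut into G = 10
near-equal groups. Observed group risk is the within-group Kaplan–Meier
cumulative incidence at a common horizon t\* (default 3.5 years, always
logged); predicted group risk is the group mean. The statistic
Σ n_d(O_d − p̄_d)²/(p̄_d(1−p̄_d)) is compared with a fixed cutoff of 23.2
— the 99th percentile of chi-square with 10 df — regardless of G,
matching the convention this package validates. Kaplan–Meier CIs use the
Greenwood variance on the survival scale.

The statistic's binomial variance reference assumes every subject is
observed to t\*; random dropout before t\* inflates the Kaplan–Meier
variance above binomial and pushes the null mean above 10 (measured ≈30
vs ≈9.5 at the default dropout). Null-level experiments therefore use
administrative censoring only, under which the measured exceedance of
the 23.2 cutoff is ≈1% as designed; on cohorts with dropout the verdict
is conservative in the direction of declaring miscalibration.

## Recalibration

**Means and rates** (Framingham-initial): replace the derivation
cohort's average risk profile and event-free rate with the target
cohort's: risk′ = 1 − S̄(t\*)^exp(m − m̄), with S̄ the Kaplan–Meier
event-free probability. The average m̄ is taken on the hazard scale,
m̄ = ln mean(exp m). This choice makes the procedure exactly
self-consistent (a cohort whose event-free rate equals the equation's
own average-hazard survival gets its predictions back unchanged) and
makes the mean recalibrated prediction reproduce the Kaplan–Meier risk;
the arithmetic-mean variant (available as `lp_average="mean"`) instead
over-predicts systematically by the Jensen factor E[e^m]/e^mean(m),
about 1.4 at the default covariate spread.

**Intercept/slope** (parametric UKPDS and secondary equations): with
model cumulative hazard H(t|x), fit H′ = exp(α + γ ln H) by maximising
the censored-data log likelihood
Σ_events [α + (γ−1)ln Hᵢ + ln γ] − Σ e^α Hᵢ^γ. α = 0, γ = 1 recovers the
original model; a k-fold proportional hazard shift maps to α = ln k.
Optimisation runs in (α, ln γ) — BFGS followed by analytic-Hessian
Newton polish to a 1e−8 gradient norm, from (0, 1); with γ constrained
to 1 the score has the closed-form root α = ln(events/ΣH). SEs come from
the observed information. Both procedures are rank-preserving for γ > 0,
so recalibration never changes the c-index.

Note on recovery experiments: α is the intercept at H = 1, while
3.5-year cumulative hazards sit near e⁻³, so under the default censoring
its sampling SD is ≈0.09 at n = 10,000. Recovery runs therefore use
light censoring (25-year horizon, no dropout), where H reaches order one
and the SD drops to ≈0.014; estimates are unbiased under both designs.

## Cox refits and goodness of fit

Each equation's predictor set is refitted as a Cox model via lifelines
(Efron ties — the data are continuous-time with few ties): continuous
HbA1c/SBP/ln(TC/HDL) plus female/ethnicity/smoking indicators for the
UKPDS sets (the duration refit adds the duration term and differs in
nothing else), category indicators for the initial sets, the reduced
sets for the secondary equations. Refit vs published coefficients are
compared by z = (b_new − b_orig)/√(se²_new + se²_orig); the sources
publish no SEs for these coefficient sets, so comparisons fall back to
se_new alone and are flagged anti-conservative.

Goodness of fit is a Grønnesby–Borgan-type score test: G−1 indicators
for deciles of the fitted prognostic index are added to the model and
their joint nullity is score-tested (chi-square, G−1 df). The score and
information use an in-package Efron partial-likelihood implementation
(validated against finite differences and against lifelines'
log-likelihood); the fitted coefficients are Newton-polished before the
test so the parameter block of the score is zero.

## Multiple imputation

Chained equations over the baseline covariates: Bayesian Gaussian linear
models for continuous variables (posterior draws of σ² and β, then a
noise draw; draws clipped to validity bounds so completed data always
satisfy the profile invariants), perturbed-MLE logistic models for
binaries, mean/mode initialisation, default m = 5 chains × 10 cycles
(the number of imputations is not dictated by the procedure; 5 is the
conventional default). Predictive-mean matching is available but off by
default. Observed values are never altered. Downstream estimates are
pooled by Rubin's rules, T = W̄ + (1+1/m)B, with the classic
small-sample df (m−1)(1 + W̄/((1+1/m)B))².

## Pipeline

`run_pipeline` stratifies by CHD history (first-event equations on the
no-history stratum, the secondary equation on the history stratum, the
Framingham equations per sex), evaluates each unit on every imputed
dataset, pools c-indexes by Rubin's rules (Noether SEs by default for
speed; bootstrap optional), averages GOF statistics across imputations
(a chi-square statistic has no exact Rubin pooling; per-imputation
values are retained in the logs), recalibrates each equation with the
procedure matching its form, and refits each predictor set with
Rubin-pooled coefficients. Every run writes a manifest with the seed,
horizon, grouping and constants-file version. Default problem sizes
(4000 + 1600 subjects, m = 5) keep a full run around a minute on one
core; all sizes are configuration.

## Known limitations

* The decile GOF verdict is conservative under heavy dropout (see
  above); a Greenwood-variance-based statistic would restore the nominal
  level but would no longer match the convention being validated.
* The imputation models are linear/logistic in the raw covariates and do
  not use the survival outcome; under strong covariate-outcome
  missingness dependence this under-states between-imputation variance.
* Framingham-initial horizons beyond 5 years are unsupported (no
  published baseline survival anchors).
* No competing-risks treatment: non-CHD death is censoring.
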