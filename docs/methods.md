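# Methods

This note documents the models and procedures `shadowharm` implements, the
synthetic world they are exercised on, the numerical choices, and what
passing tests do and do not establish.

## The estimation problem

Self-harm in US claims data is an under-coded outcome: only a small fraction
of true events carry an intentional-self-harm diagnosis code, and that
fraction is far too small for per-regimen comparative-effectiveness analysis.
The pipeline treats the coded events as a *thinned sample* of the true event
process and rebuilds the outcome in two steps: a probabilistic classifier
over care episodes, then a threshold that turns probabilities into outcome
flags, swept as a sensitivity analysis. Everything downstream (staging,
exposure, hazard models, covariate screening) is conditional on that
reconstructed outcome.

## Meta-visits

Visits are merged into meta-visits when the next visit starts no more than
`merge_gap` days after the current one ends. The default `merge_gap = 1`
merges overlapping, same-day and adjacent-day visits; adjacent-day merging is
deliberate — ER-to-admission transfers often bill on consecutive days — and
is configurable because "no gap" admits both readings. The merge is
order-independent and idempotent; codes and settings are unions.

## Imputation

**Features.** Age at meta-visit start, a male-sex indicator, calendar start
year, and one binary indicator per non-self-harm code present, expanded to
all vocabulary ancestors (the hierarchy is what lets a model generalize from
"laceration of wrist" to "open wound"). Self-harm codes and ancestors
reachable *only* from self-harm codes are excluded — they define the label.
Indicators with fewer than `min_support = 10` occurrences are dropped for
tractability; age and year are standardized so the penalty treats them on the
indicator scale.

**Model.** The default classifier is L2-penalized logistic regression
(`C = 0.03`, liblinear) with **class-balanced weights**, behind a pluggable
factory — any estimator with `fit`/`predict_proba` drops in. Balanced
weighting is a modelling commitment, not a convenience: when only ~5% of true
events are labeled, a calibrated model's probabilities are capped near the
coding fraction and a 0.5 threshold would recover nothing. Balanced weights
rescale the positive class so that episodes carrying the self-harm signature
score near 1 and ordinary hospitalizations near 0, which is the regime in
which a 0.5 threshold recovers an order of magnitude more events than were
coded. The rather strong penalty (C = 0.03) reflects the very small positive
class: with tens of positives, weaker penalties overfit idiosyncratic noise
codes and out-of-fold discrimination drops measurably.

**Cross-fitting.** Five stratified folds (class prevalence is a fraction of a
percent; unstratified folds risk positive-free training sets); every score is
produced by a model that never saw the episode. Fold assignment is at the
meta-visit level by default, matching the unit of analysis; patient-level
folds (`fold_unit="patient"`, stratified-group splits) are supported for
users worried about within-patient leakage.

**Metrics.** Sensitivity, specificity and MCC are computed from the confusion
cells *treating the coded label as truth* — which means "false positives" are
dominated by genuinely uncoded events and specificity/MCC understate the
classifier. AUC (rank statistic) against coded labels inherits the same
ceiling: if a fraction f of the negative class is actually positive, AUC
cannot exceed roughly 1 − f/2 no matter how good the classifier. Empty
classes yield NaN, never 0.

## Staging

Eligibility: ≥ 2 BD diagnosis codes, no major-mental-illness exclusion code
anywhere in the record. Index visit: first BD-coded meta-visit whose last day
has ≥ 365 days of *continuous enrollment* behind it (the 12-month lookback is
interpreted as continuous enrollment; day-granular time, 12 months = 365
days). Time zero is the last day of the index visit. Follow-up ends at the
earliest of: first post-index outcome meta-visit; first post-index
inpatient/ER meta-visit that is not an outcome (drug exposure is unobservable
in hospital, and hospitalization itself shifts risk); onset of a censoring
condition or an anti-dementia drug fill; enrollment end. On a tied day the
outcome takes precedence. Prior coded self-harm is a baseline covariate, not
an exclusion. "Newly observed" means strictly after time zero.

Baseline covariates come from the 365-day lookback (arbitrary code-set
covariates are configurable) plus index-visit characteristics (outpatient
setting present, polarity/psychotic-feature code sets when configured,
otherwise unknown-polarity defaults to 1), prior hospitalization, prior coded
self-harm, sex, and age at index.

## Exposure construction

Per agent, coverage is the union of `[fill_day, fill_day + days_supply)`
spans with gaps ≤ `grace_days` bridged. When a new agent starts while an old
one has < `grace_days` of residual coverage, the old agent is truncated at
the new start (a switch); otherwise the overlap is a combination. The default
`grace_days = 30` is the conventional pharmacoepidemiology grace period and
governs both rules; both are configurable. Uncovered time is "no drug".

Labels: monotherapies use agent names; combinations use one token per drug
class, sorted; ≥ 2 agents of the same class become MULTI_MSA / MULTI_SGA
(these two classes are the only ones with enough within-class polypharmacy).
Cohort-wide, regimens failing the requisites (`min_intervals`, `min_events`)
collapse to POLYPHARMACY_2/3/4 by class count (a lone MULTI_* label counts as
two), monotherapies to UNCOMMON_MONOTHERAPY; NO_DRUG never collapses, and a
`keep` set protects the model's reference regimen from collapsing in small
cohorts. Collapsing preserves interval and event totals exactly.

Counting-process rows are half-open `(start, stop]` relative to time zero;
the event sits on the terminal interval; `prior_unique_bd_drugs` counts
unique study drugs filled in the lookback year plus the agents of all earlier
exposure intervals (non-decreasing within a patient); the psychotherapy flag
is 1 when any psychotherapy procedure day falls in the interval.

## Hazard models

Fitting is Efron-tie partial-likelihood maximization via
`lifelines.CoxTimeVaryingFitter` (day-granular data produce many ties; Efron
is the accepted default). Convergence: Newton steps to relative precision
1e-9, max 100 iterations. Wald CIs, exp(β ± 1.96·SE). Constant terms raise a
named non-identifiability error; separation surfaces as an error with a ridge
`penalizer` as the documented fallback. Model 1 drops regimens with zero
events (their intervals excluded, logged on the fit object); in worlds
without psychotherapy the constant psychotherapy term is omitted. Model 2
requires a non-empty "no treatment" reference and includes only the
categories present.

**Splines.** Age and prior-unique-drugs enter as natural cubic splines
(patsy `cr`, df = 4 by default — enough for one interior mode while keeping
the linear/nonlinear decomposition readable). The basis is decomposed into a
pure linear column (x − reference) plus nonlinear columns: the basis is
residualized against [1, x] and projected onto its principal directions
(rank df − 2), which keeps the design well conditioned and makes "linear
component HR" and "joint nonlinear p" (Wald chi-square) directly reportable.
HR curves are anchored at exactly 1 with zero CI width at the reference value
(age 50; zero prior drugs). With too few distinct values, or when quantile
knots collide on heavily discrete data, the term degrades to linear with a
warning.

**Multiplicity.** Benjamini–Yekutieli step-up at q = 0.05 with the
c(m) = Σ 1/i correction, valid under the arbitrary dependence of 60+ mutually
exclusive regimen contrasts; the realized p cutoff is reported. BY rejections
are a subset of Benjamini–Hochberg's at the same q (tested).

## Factorial covariate screening

The screening asks which pretreatment covariates *move the treatment
estimates*, not which predict the outcome. A saturated resolution-III
two-level design on `n_base_runs/2` runs (full-factorial generator columns of
an order-m Hadamard matrix) is folded over (sign-reversed runs appended),
which lifts it to resolution IV: main effects orthogonal to all two-factor
interactions — verified programmatically at construction (exhaustively at
small scale, sampled at the 78-covariate/512-run scale, which reproduces the
513 × 78 geometry including the all-exclude reference run). One Cox fit per
run (treatments always in; covariate j in iff X[run, j] = +1) yields Y; OLS
of each Y column on X gives per-covariate significance counts at
α = 0.05/n_treatments; never-significant covariates are discarded; backward
elimination drops the candidate with the fewest significant appearances
(ties broken toward the larger minimum p) and stops when the next candidate's
minimum p is below `stop_p = 1e-3` — the operationalization of "highly
significant", configurable because no quantitative definition exists. The
bias diagnostic Y′ is the Euclidean distance of each run's *coefficient
vector* from the reference run's vector, regressed on X. (Distances between
±1 design rows carry no information about the estimates; the distance is
taken in coefficient space.)

Desk-scale defaults in the tests use 7 candidate covariates on 16 base runs
with 2–3 treatment terms; the full 78/512 configuration is available and its
construction is tested.

## The synthetic world

The generator emulates what the downstream stages consume: enrollment spans;
BD diagnosis streams (a configurable fraction with ≥ 2 codes); background
outpatient visits; *ordinary hospitalizations* (0.30/year) — the
true-negative class for the classifier and the censoring mechanism; treatment
episodes in 30-day units realized as fills with 30-day supplies; optional
psychotherapy procedure streams; and a true self-harm event process with
piecewise-constant hazard λ = λ₀·exp(regimen log-HR + confounder effects +
psychotherapy effect), sampled by exponential waiting times — exactly the
model fitted downstream, so parameter recovery is a clean test. Each true
event emits an inpatient/ER visit that always carries 3–8 injury-proxy codes
(which share a dedicated "injury" ancestor, as real injury subtrees do) and a
self-harm code with probability `coding_fraction`.

Default conditions: coding fraction 1/19; baseline hazard 4e-5/day (a true
event rate near 1,600 per 100,000 person-years, consistent with a coded rate
near 83 per 100,000 when 1 in 19 is coded); two confounders (prevalence 0.20)
that both push treatment assignment toward combination regimens (logistic
shift +0.9/+0.6) and raise the hazard (log-HR +0.65/+0.50) — the indication
bias the screening must find; planted regimen effects spanning
protective-to-harmful (−0.58 to +0.30 vs lithium). Fixed seed ⇒ byte-identical
tables.

What the generator does **not** emulate: dose/route/release mechanism,
realistic code-frequency distributions, state of residence or plan types,
seasonality, care-seeking correlation beyond the planted confounders, or
informative enrollment gaps. Passing recovery tests therefore shows the
*procedures* are correct and unbiased under the stated generating model, not
that real-data estimates are unconfounded.

## Problem sizes in the tests and acceptance script

Simulation-backed checks use sizes chosen to give stable pass/fail behaviour
at desk scale: regimen log-HR CI coverage at n = 5,000 patients × 50
replicates (≥ 90% must cover); confounder recovery by the screening at
n = 2,000 × 20 replicates (≥ 90%); threshold sign stability at n = 1,500 × 20
replicates across t ∈ {0.2, …, 0.7} (≥ 80%); the imputation world uses 6,000
patients over 8 years so the coded positive class is large enough to train
on. `scripts/acceptance.py` re-measures the same quantities with 12–30
replicates. The worked-example arithmetic (confusion-cell metrics, incidence
rates per 100,000 person-years, ratio arithmetic) runs on published cells and
denominators as inputs.

## Known limitations

* The switch-vs-combination rule is a declared stand-in (grace-period based);
  the field has several variants and the thresholds are configurable rather
  than canonical.
* The outcome model is classifier-agnostic but the shipped default is linear;
  worlds with strongly interacting code signatures would need a different
  plug-in.
* Probabilities from the balanced classifier are deliberately *not*
  calibrated to coded prevalence (see above); users who need calibrated
  absolute risks must recalibrate.
* `assemble_model` fits one shared covariance; stratified baselines,
  frailty/random effects, and competing risks are out of scope, as is
  propensity matching (infeasible with dozens of time-varying comparators —
  the factorial screening exists precisely to replace it).
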