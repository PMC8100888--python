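# shadowharm

Comparative-effectiveness analysis of self-harm risk under bipolar-disorder
(BD) treatment regimens in administrative claims data, built around one hard
fact: most self-harm events never receive a self-harm billing code (roughly
1 in 19 do). `shadowharm` implements the full pipeline for studying a
systematically under-coded outcome — machine-learning imputation of the
missing events, time-varying exposure construction, counting-process Cox
models, and a fractional-factorial procedure for selecting the covariates
that actually bias the treatment estimates — and ships a synthetic claims
generator with planted ground truth so every stage is testable end to end
without any proprietary data.

It is written for pharmacoepidemiologists and biostatisticians who work with
claims/EHR data and want either (a) reusable implementations of these
methods, or (b) a fully specified synthetic test bed for them.

## The method

1. **Meta-visits.** Consecutive outpatient/inpatient/ER visits with no gap
   between them are merged into one care episode carrying the union of codes;
   an episode is *coded self-harm* (class 1) if it contains an intentional
   self-harm / suicide-attempt code.
2. **Imputation.** A cross-validated classifier (default: class-balanced
   penalized logistic regression) scores every inpatient/ER meta-visit with
   the probability p that self-harm occurred, using age, sex, start year, and
   ancestor-expanded code indicators — never the self-harm codes themselves.
   All scores are out-of-fold. The outcome at threshold t is
   *coded OR (inpatient/ER AND p > t)*; t = 0.5 for the main analysis,
   t ∈ {0.20, …, 0.95, 1.0} in sensitivity analyses.
3. **Staging.** Eligibility needs ≥ 2 BD diagnosis codes and no major
   depressive disorder / schizophrenia / schizoaffective code at any time.
   The index visit is the first BD meta-visit with 365 days of enrollment
   behind it; follow-up runs from its last day to the first outcome
   meta-visit, a self-harm-unrelated hospitalization, onset of a censoring
   condition (or anti-dementia fill), or enrollment end.
4. **Exposure.** Drug fills become per-agent coverage (gaps ≤ 30 days
   bridged); overlaps resolve into combinations or switches by a residual-
   coverage rule; regimens failing the power requisites (≥ 1000 intervals,
   ≥ 5 events, both configurable) collapse into polypharmacy-by-class-count,
   multi-MSA/multi-SGA, or uncommon-monotherapy buckets.
5. **Models.** Counting-process Cox regression (Efron ties, via lifelines):
   model 1 compares every retained regimen to lithium monotherapy with a
   binary time-varying psychotherapy covariate and natural-spline terms for
   age and prior unique BD drugs, λ(t|x) = λ₀(t)·exp(xᵀβ); model 2 compares
   pharmacotherapy / psychotherapy / both / neither. Multiplicity is
   controlled with Benjamini–Yekutieli FDR (valid under arbitrary
   dependence): reject the k smallest p-values where k is the largest index
   with p(k) ≤ k·q / (m·Σᵢ1/i).
6. **Covariate screening.** Pretreatment covariates are toggled according to
   a resolution-IV (fold-over) two-level factorial design; one Cox fit per
   run yields a runs × treatments coefficient matrix Y, each column of which
   is regressed on the ±1 design matrix X. Covariates are ranked by how many
   treatment estimates they shift (P < .05/n_treatments), never-significant
   ones are discarded, and backward elimination stops at the first highly
   significant candidate. A per-run L2 distance of the coefficient vector
   from the no-covariate reference run (Y′), regressed on X, ranks the
   largest bias sources.

## Worked example

`examples/03_hazard_models.py` generates 4,000 synthetic patients (planted
regimen effects, two confounders that drive both treatment intensification
and hazard, 1-in-19 outcome coding), imputes the outcome, and fits both
models adjusted for the two confounders:

```
staged patients: 3724, outcomes: 285, person-years: 6628

model 1 — hazard ratios vs lithium monotherapy (sorted by HR):
                term    hr  lower95  upper95     p
     substance_abuse 2.047    1.593    2.629 0.000
regimen[LITHIUM+MSA] 1.678    1.058    2.661 0.028
        prior_injury 1.552    1.193    2.018 0.001
regimen[LITHIUM+SGA] 1.478    0.925    2.359 0.102
regimen[LAMOTRIGINE] 0.955    0.545    1.674 0.873
 regimen[QUETIAPINE] 0.900    0.517    1.567 0.710
  regimen[VALPROATE] 0.870    0.494    1.534 0.631
 regimen[FLUOXETINE] 0.777    0.435    1.388 0.394
    regimen[NO_DRUG] 0.678    0.400    1.148 0.148
       psychotherapy 0.528    0.405    0.689 0.000

model 2 — treatment categories vs no treatment:
                 term    hr  lower95  upper95     p
treatment[pharm_only] 1.832    1.166    2.878 0.009
 treatment[pharm_psy] 0.940    0.573    1.541 0.806
  treatment[psy_only] 0.674    0.317    1.431 0.304

Benjamini-Yekutieli at FDR 5%: 3 regimen terms significant (realized p cutoff 0.001038)
```

Reading it: the planted lithium+MSA combination effect was log-HR +0.30
(HR 1.35) and is estimated at 1.68 (CI 1.06–2.66); the planted psychotherapy
effect exp(−0.5) = 0.61 is estimated at 0.53; the drug-free state (planted
HR 0.56) at 0.68. The confounders carry their planted hazard effects
(exp(0.65) ≈ 1.9, exp(0.5) ≈ 1.65). Model 2 shows the same structure the
method produces on real data: psychotherapy-alone protective, drug-alone
intervals riskier than no treatment.

The other examples cover the generator (`01`), the imputation stage and its
classification metrics (`02`), the factorial covariate screening (`04`), and
the threshold sensitivity sweep (`05`). A thin CLI wraps the shell-level
uses:

```bash
shadowharm simulate --out world/ --seed 7        # write claims tables + ground truth
shadowharm run --out results/ --seed 7           # full pipeline at one threshold
shadowharm sweep --out results/ --seed 7         # threshold sensitivity analysis
```

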