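"""Screen pretreatment covariates with a resolution-IV fractional factorial.

Instead of asking whether a covariate predicts the outcome, the screening
asks whether its inclusion/exclusion *shifts the treatment hazard-ratio
estimates* — the signature of a confounder.  Covariates are toggled according
to a fold-over (resolution IV) design; the treatment-coefficient matrix Y is
regressed on the design matrix X, and significance counts rank the bias
sources.
"""

import numpy as np

import shadowharm as sh

gt = sh.GroundTruth(
    regimen_log_hr={"LITHIUM": 0.0, "VALPROATE": -0.4, "LITHIUM+MSA": 0.3},
    confounder_effects={"substance_abuse": (0.9, 0.65), "prior_injury": (0.6, 0.5)},
    coding_fraction=1.0, baseline_hazard=1e-4, seed=0)
sim = sh.generate_population(gt, 2000, 1825, seed=7,
                             background_visit_rate_per_year=1.0,
                             hospitalization_rate_per_year=0.0)

rows = sim.oracle_counting_process()
treat = []
for r in ("VALPROATE", "LITHIUM+MSA"):
    rows[f"regimen[{r}]"] = (rows["regimen"] == r).astype(float)
    treat.append(f"regimen[{r}]")

# candidate covariates: the two planted confounders plus five noise covariates
cv = sim.confounder_values.set_index("patient_id")
rng = np.random.default_rng(3)
names = list(cv.columns)
for j in range(5):
    cv[f"noise{j}"] = (rng.random(len(cv)) < 0.25).astype(int)
    names.append(f"noise{j}")
rows = rows.merge(cv.reset_index(), on="patient_id", how="left")

design = sh.build_design(len(names), n_base_runs=16)
print(f"design: {design.n_runs} runs x {design.n_covariates} covariates "
      f"(resolution {design.resolution}, reference run appended)")

res = sh.run_factorial(rows, design, treat, names)
res = sh.score_covariates(res, design)
print("\nsignificance counts (how many treatment estimates each covariate shifts):")
for n, c, p in zip(names, res.significance_counts, res.min_p):
    print(f"  {n:16s} count={c}  min p={p:.2e}")

res = sh.backward_eliminate(rows, res, names)
print("\nsurviving covariate set:", res.final_covariates)

res = sh.bias_norm(res, design)
top = res.bias_regression.head(3)
print("\nlargest bias sources by the Y' (distance-from-reference) regression:")
for _, r in top.iterrows():
    print(f"  {names[int(r['covariate_index'])]:16s} coef={r['coef']:.4f} p={r['p']:.2e}")
print("\nThe two planted confounders should dominate both rankings; the noise")
print("covariates are discarded or dropped early.")
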