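"""Fit the two time-varying Cox models on a synthetic cohort.

Model 1 compares each retained regimen to lithium monotherapy with
psychotherapy as a binary time-varying covariate and natural-spline terms for
age and prior unique study drugs.  Model 2 collapses treatment into four
categories (pharmacotherapy / psychotherapy / both / neither) against "no
treatment".
"""

import warnings

import shadowharm as sh

gt = sh.GroundTruth(
    regimen_log_hr=sh.default_ground_truth(0).regimen_log_hr,
    confounder_effects=sh.default_ground_truth(0).confounder_effects,
    coding_fraction=1 / 19, baseline_hazard=1.5e-4,
    psychotherapy_log_hr=-0.5, seed=0)
sim = sh.generate_population(gt, 4000, 2555, seed=21, psychotherapy_fraction=0.35)

# adjust for the two planted confounders (extracted from the 1-year lookback)
cfg = sh.PipelineConfig(threshold=0.5, min_intervals=50, min_events=3, seed=3,
                        covariates=("substance_abuse", "prior_injury"))
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    res = sh.run_pipeline(sim, cfg)

print(f"staged patients: {len(res.staged)}, outcomes: {res.n_outcomes}, "
      f"person-years: {res.person_years:.0f}")

print("\nmodel 1 — hazard ratios vs lithium monotherapy (sorted by HR):")
t1 = res.fit1.summary
mask = (t1["term"].str.startswith("regimen[") | (t1["term"] == "psychotherapy")
        | t1["term"].isin(["substance_abuse", "prior_injury"]))
print(t1[mask][["term", "hr", "lower95", "upper95", "p"]]
      .to_string(index=False, float_format=lambda x: f"{x:.3f}"))

print("\nmodel 2 — treatment categories vs no treatment:")
t2 = res.fit2.summary
print(t2[t2["term"].str.startswith("treatment[")]
      [["term", "hr", "lower95", "upper95", "p"]]
      .to_string(index=False, float_format=lambda x: f"{x:.3f}"))

rejected, cutoff = sh.benjamini_yekutieli(t1[mask]["p"].to_numpy(), q=0.05)
print(f"\nBenjamini-Yekutieli at FDR 5%: {int(rejected.sum())} regimen terms "
      f"significant (realized p cutoff {cutoff:.4g})")
print("HR < 1 means lower self-harm hazard than lithium; compare against the")
print("planted log-HRs in the ground truth (e.g. NO_DRUG was planted at -0.58).")
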