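"""Partial-likelihood fitting vs an independent grid-search oracle, spline
reporting, and Benjamini–Yekutieli correction."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

import shadowharm as sh
from shadowharm.errors import ConfigurationError, DataError


# ---------------------------------------------------------------------------
# 4-subject fixture and grid-search oracle


@pytest.fixture(scope="module")
def four_subjects():
    """{(z=1, event t=1), (z=0, event t=3), (z=1, censored t=2),
    (z=0, event t=2)} as counting-process rows."""
    return pd.DataFrame({
        "patient_id": [1, 2, 3, 4],
        "start": [0, 0, 0, 0],
        "stop": [1, 3, 2, 2],
        "event": [True, True, False, True],
        "z": [1.0, 0.0, 1.0, 0.0],
    })


def _oracle_log_partial_likelihood(beta, df):
    """Brute-force Breslow/Efron partial likelihood (no event-time ties in
    the fixture, so tie handling is irrelevant); independent of the fitter."""
    ll = 0.0
    events = df[df["event"]].sort_values("stop")
    for _, ev in events.iterrows():
        t = ev["stop"]
        at_risk = df[(df["start"] < t) & (df["stop"] >= t)]
        ll += beta * ev["z"] - np.log(np.exp(beta * at_risk["z"]).sum())
    return ll


def test_fixture_coefficient_is_half_log_two(four_subjects):
    """The partial-likelihood maximum is at beta = ln(2)/2, i.e. HR = sqrt 2."""
    fit = sh.fit_cox(four_subjects, ["z"])
    beta = fit.params["z"]
    assert beta == pytest.approx(0.5 * np.log(2.0), abs=1e-4)
    assert fit.summary.iloc[0]["hr"] == pytest.approx(np.sqrt(2.0), abs=2e-4)


def test_fixture_matches_grid_search_oracle(four_subjects):
    grid = np.linspace(-2, 2, 4001)
    lls = [_oracle_log_partial_likelihood(b, four_subjects) for b in grid]
    coarse = grid[int(np.argmax(lls))]
    fine = np.linspace(coarse - 2e-3, coarse + 2e-3, 401)
    oracle_beta = fine[int(np.argmax([_oracle_log_partial_likelihood(b, four_subjects)
                                      for b in fine]))]
    fit = sh.fit_cox(four_subjects, ["z"])
    assert fit.params["z"] == pytest.approx(oracle_beta, abs=1e-4)
    # fitted likelihood beats the null
    assert fit.log_likelihood >= _oracle_log_partial_likelihood(0.0, four_subjects)
    assert fit.log_likelihood == pytest.approx(
        _oracle_log_partial_likelihood(fit.params["z"], four_subjects), abs=1e-8)


def test_constant_covariate_is_nonidentifiable(four_subjects):
    df = four_subjects.assign(w=1.0)
    with pytest.raises(DataError, match="constant"):
        sh.fit_cox(df, ["w"])


def test_no_events_is_an_error(four_subjects):
    df = four_subjects.assign(event=False)
    with pytest.raises(DataError, match="no events"):
        sh.fit_cox(df, ["z"])


def test_wald_ci_definition(four_subjects):
    fit = sh.fit_cox(four_subjects, ["z"])
    row = fit.summary.iloc[0]
    z = float(__import__("scipy.stats", fromlist=["norm"]).norm.ppf(0.975))
    assert row["lower95"] == pytest.approx(np.exp(row["coef"] - z * row["se"]), rel=1e-9)
    assert row["upper95"] == pytest.approx(np.exp(row["coef"] + z * row["se"]), rel=1e-9)


# ---------------------------------------------------------------------------
# splines


def test_spline_reference_hr_is_exactly_one():
    rng = np.random.default_rng(0)
    x = rng.uniform(10, 80, 600)
    term = sh.NaturalSplineTerm(x, df=4, reference_value=50.0, name="age")
    # a fake fit: any coefficients — HR at the reference must still be 1
    cols = term.column_names
    fit = sh.CoxFit(
        summary=pd.DataFrame({"term": cols, "coef": [0.03, 0.4, -0.2],
                              "se": [0.01, 0.1, 0.1], "hr": 1.0,
                              "lower95": 1.0, "upper95": 1.0, "p": 0.5}),
        log_likelihood=0.0, null_log_likelihood=0.0, converged=True,
        covariance=pd.DataFrame(np.eye(len(cols)) * 1e-2, index=cols, columns=cols),
        n_rows=600, n_events=60)
    curve = term.curve(fit, [50.0, 30.0])
    assert curve.iloc[0]["hr"] == pytest.approx(1.0, abs=1e-12)
    assert curve.iloc[0]["upper95"] - curve.iloc[0]["lower95"] == pytest.approx(0.0, abs=1e-12)
    assert curve.iloc[1]["hr"] != 1.0


def test_spline_degrades_to_linear_with_few_values():
    with pytest.warns(UserWarning, match="degrading"):
        term = sh.NaturalSplineTerm([0, 1, 0, 1, 0], df=4, reference_value=0, name="x")
    assert term.column_names == ["x_lin"]


def test_u_shaped_age_effect_recovered():
    """A planted U-shaped log-hazard in age is recovered: the fitted curve's
    minimum lands within +-10 years of the planted minimum."""
    rng = np.random.default_rng(4)
    n = 4000
    age = rng.uniform(15, 85, n)
    lp = 0.0012 * (age - 45.0) ** 2
    # exponential survival with per-subject hazard, administrative censoring
    t = rng.exponential(1.0 / (0.01 * np.exp(lp)))
    cens = 80.0
    df = pd.DataFrame({
        "patient_id": np.arange(n), "start": 0.0,
        "stop": np.minimum(t, cens) + 1e-3,
        "event": t < cens, "age": age,
    })
    term = sh.NaturalSplineTerm(df["age"], df=4, reference_value=45.0, name="age")
    df = pd.concat([df, term.columns(df["age"])], axis=1)
    fit = sh.fit_cox(df, term.column_names)
    grid = np.linspace(20, 80, 121)
    curve = term.curve(fit, grid)
    minimum = grid[int(np.argmin(curve["hr"]))]
    assert abs(minimum - 45.0) <= 10.0
    # the nonlinear components are jointly significant
    assert fit.wald_joint_p(term.nonlinear_names) < 1e-4


def test_linear_hazard_gives_null_nonlinear_p():
    """With a purely linear planted effect the joint nonlinear p-value is
    approximately uniform: type-I rate ~ 0.05 over 40 replicates."""
    rng = np.random.default_rng(7)
    rejections = 0
    n_rep = 40
    for _ in range(n_rep):
        n = 500
        x = rng.uniform(0, 10, n)
        t = rng.exponential(1.0 / (0.05 * np.exp(0.08 * x)))
        cens = 30.0
        df = pd.DataFrame({
            "patient_id": np.arange(n), "start": 0.0,
            "stop": np.minimum(t, cens) + 1e-3, "event": t < cens, "x": x,
        })
        term = sh.NaturalSplineTerm(df["x"], df=4, reference_value=0.0, name="x")
        df = pd.concat([df, term.columns(df["x"])], axis=1)
        fit = sh.fit_cox(df, term.column_names)
        rejections += fit.wald_joint_p(term.nonlinear_names) < 0.05
    assert rejections / n_rep <= 0.15


# ---------------------------------------------------------------------------
# Benjamini–Yekutieli


def test_by_worked_example():
    """p = {0.001, 0.02, 0.04, 0.5} at q=0.05: thresholds are
    (0.006, 0.012, 0.018, 0.024), so only 0.001 is rejected."""
    p = [0.001, 0.02, 0.04, 0.5]
    mask, cutoff = sh.benjamini_yekutieli(p, q=0.05)
    assert list(mask) == [True, False, False, False]
    assert cutoff == pytest.approx(0.001)
    c4 = 1 + 1 / 2 + 1 / 3 + 1 / 4
    thresholds = [k * 0.05 / (4 * c4) for k in (1, 2, 3, 4)]
    assert thresholds == pytest.approx([0.006, 0.012, 0.018, 0.024])


def test_by_degenerate_inputs():
    mask, cutoff = sh.benjamini_yekutieli([], q=0.05)
    assert mask.size == 0 and cutoff == 0.0
    mask, cutoff = sh.benjamini_yekutieli([1.0, 1.0, 1.0], q=0.05)
    assert not mask.any()
    mask, cutoff = sh.benjamini_yekutieli([0.001, 0.2], q=0.0)
    assert not mask.any()


def test_by_matches_statsmodels_and_is_subset_of_bh():
    rng = np.random.default_rng(12)
    for _ in range(20):
        p = np.concatenate([rng.uniform(0, 0.01, 5), rng.uniform(0, 1, 30)])
        mask, _ = sh.benjamini_yekutieli(p, q=0.05)
        sm_mask = multipletests(p, alpha=0.05, method="fdr_by")[0]
        assert np.array_equal(mask, sm_mask)
        bh_mask = multipletests(p, alpha=0.05, method="fdr_bh")[0]
        assert not np.any(mask & ~bh_mask)  # BY ⊆ BH


def test_by_rejects_range_validated():
    with pytest.raises(ConfigurationError):
        sh.benjamini_yekutieli([0.5, 1.2])


# ---------------------------------------------------------------------------
# model assembly


def test_model2_category_mapping():
    assert sh.model2_category("LITHIUM", 1) == "pharm_psy"
    assert sh.model2_category("LITHIUM", 0) == "pharm_only"
    assert sh.model2_category(sh.NO_DRUG, 1) == "psy_only"
    assert sh.model2_category(sh.NO_DRUG, 0) == "no_treatment"


def _toy_rows(seed=5, n=800):
    rng = np.random.default_rng(seed)
    regs = rng.choice(["LITHIUM", "VALPROATE", sh.NO_DRUG], n)
    psy = rng.integers(0, 2, n)
    rows = pd.DataFrame({
        "patient_id": np.arange(n), "start": 0.0,
        "stop": rng.exponential(100, n) + 1.0,
        "event": rng.random(n) < 0.25,
        "regimen": regs, "psychotherapy": psy,
        "age_at_index": rng.uniform(15, 80, n),
        "prior_unique_bd_drugs": rng.integers(0, 9, n),
    })
    return rows


def test_model2_categories_partition_person_time():
    rows = _toy_rows()
    fit = sh.assemble_model(rows, "model2", spline_age=False, spline_prior_drugs=False)
    cats = [sh.model2_category(r, p) for r, p in zip(rows["regimen"], rows["psychotherapy"])]
    total = (rows["stop"] - rows["start"]).sum()
    by_cat = (rows["stop"] - rows["start"]).groupby(pd.Series(cats)).sum()
    assert by_cat.sum() == pytest.approx(total)
    assert len(by_cat) == 4
    terms = set(fit.summary["term"])
    assert {"treatment[pharm_only]", "treatment[psy_only]", "treatment[pharm_psy]"} <= terms


def test_model1_reference_missing_is_an_error():
    rows = _toy_rows()
    rows["regimen"] = sh.NO_DRUG
    with pytest.raises(ConfigurationError, match="reference"):
        sh.assemble_model(rows, "model1", spline_age=False, spline_prior_drugs=False)


def test_model1_drops_zero_event_regimen():
    rows = _toy_rows()
    rows.loc[rows["regimen"] == "VALPROATE", "event"] = False
    fit = sh.assemble_model(rows, "model1", spline_age=False, spline_prior_drugs=False)
    assert fit.dropped_regimens == ["VALPROATE"]
    assert "regimen[VALPROATE]" not in set(fit.summary["term"])


def test_output_sorted_by_hazard_ratio():
    fit = sh.assemble_model(_toy_rows(), "model1",
                            spline_age=False, spline_prior_drugs=False)
    hrs = fit.summary["hr"].to_numpy()
    assert (hrs[:-1] >= hrs[1:]).all()


def test_planted_log_hr_recovery_single_world():
    """Confounders off, two regimens at n=5000: the fitted CI covers the
    planted effect (one world; the replicated version is an acceptance
    check)."""
    beta = -0.5
    gt = sh.GroundTruth(
        regimen_log_hr={"LITHIUM": 0.0, "VALPROATE": beta},
        confounder_effects={}, coding_fraction=1.0, baseline_hazard=4e-5, seed=0)
    sim = sh.generate_population(gt, 5000, 2555, seed=42,
                                 background_visit_rate_per_year=1.0,
                                 hospitalization_rate_per_year=0.0)
    rows = sim.oracle_counting_process()
    rows["z"] = (rows["regimen"] == "VALPROATE").astype(float)
    fit = sh.fit_cox(rows, ["z"])
    row = fit.summary.iloc[0]
    assert np.log(row["lower95"]) <= beta <= np.log(row["upper95"])
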