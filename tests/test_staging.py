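"""Eligibility, index-visit location, censoring, and baseline covariates."""

import pandas as pd
import pytest

import shadowharm as sh


def _patients(rows):
    return pd.DataFrame(rows, columns=[
        "patient_id", "sex", "birth_year", "enroll_start_day", "enroll_end_day"])


def _mv(rows, vocab):
    df = pd.DataFrame(rows, columns=[
        "patient_id", "start_day", "end_day", "settings", "codes"])
    df["n_visits"] = 1
    df["has_inpatient_or_er"] = df["settings"].str.contains("inpatient|ER")
    df = sh.label_coded_selfharm(df, vocab)
    df["selfharm_prob"] = 0.0
    return df


@pytest.fixture()
def codes(vocab):
    return {
        "bd": sorted(vocab.bd_codes)[0],
        "bd2": sorted(vocab.bd_codes)[1],
        "mmi": sorted(vocab.exclusion_codes)[0],
        "cens": sorted(vocab.censoring_codes)[0],
        "sh": sorted(vocab.self_harm_codes)[0],
        "bg": sorted(vocab.role_codes("background"))[5],
    }


EMPTY_FILLS = pd.DataFrame(columns=["patient_id", "drug_id", "fill_day", "days_supply"])


def test_one_bd_code_is_insufficient(vocab, codes):
    mv = _mv([(1, 400, 400, "outpatient", codes["bd"])], vocab)
    e = sh.check_eligibility(mv, vocab)
    assert not e.iloc[0]["eligible"]
    assert e.iloc[0]["reason"] == "insufficient_bd_codes"


def test_mmi_code_anywhere_excludes(vocab, codes):
    mv = _mv([
        (1, 400, 400, "outpatient", f"{codes['bd']};{codes['bd2']};{codes['bd']}"),
        (1, 900, 900, "outpatient", codes["bd"]),
        (1, 2000, 2000, "outpatient", codes["mmi"]),
    ], vocab)
    e = sh.check_eligibility(mv, vocab)
    assert e.iloc[0]["reason"] == "exclusion_mmi"


def test_two_bd_codes_eligible(vocab, codes):
    mv = _mv([(1, 400, 400, "outpatient", f"{codes['bd']};{codes['bd2']}")], vocab)
    assert sh.check_eligibility(mv, vocab).iloc[0]["eligible"]


def test_index_requires_365_days_of_prior_enrollment(vocab, codes):
    """First BD meta-visit with only 200 prior enrollment days is skipped;
    the next one with a full lookback becomes the index."""
    patients = _patients([(1, "F", 1990, 0, 2000)])
    mv = _mv([
        (1, 200, 200, "outpatient", codes["bd"]),
        (1, 430, 430, "outpatient", codes["bd2"]),
    ], vocab)
    staged, reasons = sh.locate_sequence(mv, patients, EMPTY_FILLS, vocab, threshold=0.5)
    assert len(staged) == 1
    assert staged.iloc[0]["index_exposure_day"] == 430
    assert staged.iloc[0]["end_reason"] == "end_of_observation"
    assert staged.iloc[0]["observation_end_day"] == 2000


def test_no_qualifying_index_reported(vocab, codes):
    patients = _patients([(1, "F", 1990, 0, 700)])
    mv = _mv([(1, 100, 100, "outpatient", f"{codes['bd']};{codes['bd2']}")], vocab)
    staged, reasons = sh.locate_sequence(mv, patients, EMPTY_FILLS, vocab, threshold=0.5)
    assert len(staged) == 0
    assert reasons.iloc[0]["reason"] == "no_index"


def test_nonoutcome_hospitalization_censors(vocab, codes):
    patients = _patients([(1, "F", 1990, 0, 2000)])
    mv = _mv([
        (1, 400, 400, "outpatient", f"{codes['bd']};{codes['bd2']}"),
        (1, 800, 805, "inpatient", codes["bg"]),
    ], vocab)
    staged, _ = sh.locate_sequence(mv, patients, EMPTY_FILLS, vocab, threshold=0.5)
    assert staged.iloc[0]["end_reason"] == "censor_hospitalization"
    assert staged.iloc[0]["observation_end_day"] == 800


def test_outcome_ends_observation(vocab, codes):
    patients = _patients([(1, "F", 1990, 0, 2000)])
    mv = _mv([
        (1, 400, 400, "outpatient", f"{codes['bd']};{codes['bd2']}"),
        (1, 900, 901, "ER", codes["sh"]),
    ], vocab)
    staged, _ = sh.locate_sequence(mv, patients, EMPTY_FILLS, vocab, threshold=0.5)
    assert staged.iloc[0]["end_reason"] == "outcome"
    assert staged.iloc[0]["observation_end_day"] == 900


def test_antidementia_fill_censors(vocab, codes):
    patients = _patients([(1, "F", 1990, 0, 2000)])
    mv = _mv([
        (1, 400, 400, "outpatient", f"{codes['bd']};{codes['bd2']}"),
        (1, 1500, 1501, "ER", codes["sh"]),
    ], vocab)
    drug = sorted(vocab.censoring_drug_ids)[0]
    fills = pd.DataFrame([{"patient_id": 1, "drug_id": drug,
                           "fill_day": 700, "days_supply": 30}])
    staged, _ = sh.locate_sequence(mv, patients, fills, vocab, threshold=0.5)
    assert staged.iloc[0]["end_reason"] == "censor_condition"
    assert staged.iloc[0]["observation_end_day"] == 700


def test_censoring_condition_code_censors(vocab, codes):
    patients = _patients([(1, "F", 1990, 0, 2000)])
    mv = _mv([
        (1, 400, 400, "outpatient", f"{codes['bd']};{codes['bd2']}"),
        (1, 600, 600, "outpatient", codes["cens"]),
        (1, 900, 901, "ER", codes["sh"]),
    ], vocab)
    staged, _ = sh.locate_sequence(mv, patients, EMPTY_FILLS, vocab, threshold=0.5)
    assert staged.iloc[0]["end_reason"] == "censor_condition"
    assert staged.iloc[0]["observation_end_day"] == 600


def test_imputed_outcome_respects_threshold(vocab, codes):
    patients = _patients([(1, "F", 1990, 0, 2000)])
    mv = _mv([
        (1, 400, 400, "outpatient", f"{codes['bd']};{codes['bd2']}"),
        (1, 900, 901, "ER", codes["bg"]),
    ], vocab)
    mv.loc[1, "selfharm_prob"] = 0.7
    lo, _ = sh.locate_sequence(mv, patients, EMPTY_FILLS, vocab, threshold=0.5)
    hi, _ = sh.locate_sequence(mv, patients, EMPTY_FILLS, vocab, threshold=0.9)
    assert lo.iloc[0]["end_reason"] == "outcome"
    assert hi.iloc[0]["end_reason"] == "censor_hospitalization"


def test_staging_invariants_on_synthetic_world(small_sim):
    """Ordering invariance, lookback guarantee, and threshold monotonicity of
    outcome counts on a generated cohort."""
    mv = sh.label_coded_selfharm(sh.build_meta_visits(small_sim.visits), small_sim.vocab)
    mv["selfharm_prob"] = 0.0
    staged, _ = sh.locate_sequence(mv, small_sim.patients, small_sim.fills,
                                   small_sim.vocab, threshold=0.5)
    assert len(staged) > 0
    p = small_sim.patients.set_index("patient_id")
    lookback = staged["index_exposure_day"].to_numpy() - p.loc[
        staged["patient_id"], "enroll_start_day"].to_numpy()
    assert (lookback >= 365).all()
    assert (staged["observation_end_day"] > staged["index_exposure_day"]).all()
    # input order does not matter
    staged2, _ = sh.locate_sequence(
        mv.sample(frac=1.0, random_state=5), small_sim.patients, small_sim.fills,
        small_sim.vocab, threshold=0.5)
    pd.testing.assert_frame_equal(
        staged.sort_values("patient_id").reset_index(drop=True),
        staged2.sort_values("patient_id").reset_index(drop=True))
    # raising the threshold never increases outcome-ended patients
    n_outcome = {}
    for t in (0.2, 0.5, 1.0):
        s, _ = sh.locate_sequence(mv, small_sim.patients, small_sim.fills,
                                  small_sim.vocab, threshold=t)
        n_outcome[t] = (s["end_reason"] == "outcome").sum()
    assert n_outcome[0.2] >= n_outcome[0.5] >= n_outcome[1.0]


def test_baseline_covariates(vocab, codes):
    patients = _patients([(1, "M", 1980, 0, 2000)])
    mv = _mv([
        (1, 330, 330, "ER", codes["sh"]),            # prior self-harm, 100d pre-index
        (1, 380, 380, "outpatient", codes["bg"]),    # lookback condition code
        (1, 430, 431, "outpatient;inpatient", f"{codes['bd']};{codes['bd2']}"),
        (1, 900, 900, "outpatient", codes["bg"]),
    ], vocab)
    staged, _ = sh.locate_sequence(mv, patients, EMPTY_FILLS, vocab, threshold=0.5)
    assert staged.iloc[0]["index_exposure_day"] == 431
    cov = sh.extract_baseline_covariates(
        staged, mv, EMPTY_FILLS, patients, vocab,
        covariate_codesets={"some_condition": frozenset({codes["bg"]})})
    row = cov.iloc[0]
    assert row["prior_self_harm"] == 1
    assert row["prior_hospitalization"] == 1     # the ER meta-visit in lookback
    assert row["some_condition"] == 1
    assert row["outpatient_visit_present"] == 1
    assert row["male_sex"] == 1
    assert row["unknown_polarity"] == 1          # no polarity code sets configured
    assert row["age_at_index"] == (2003 + 431 // 365) - 1980


def test_absent_lookback_codes_default_to_zero(vocab, codes):
    patients = _patients([(1, "F", 1995, 0, 1200)])
    mv = _mv([(1, 400, 400, "outpatient", f"{codes['bd']};{codes['bd2']}")], vocab)
    staged, _ = sh.locate_sequence(mv, patients, EMPTY_FILLS, vocab, threshold=0.5)
    cov = sh.extract_baseline_covariates(
        staged, mv, EMPTY_FILLS, patients, vocab,
        covariate_codesets={"cond": frozenset({codes["bg"]})})
    row = cov.iloc[0]
    assert row["cond"] == 0
    assert row["prior_self_harm"] == 0
    assert row["prior_hospitalization"] == 0
    assert row["unknown_polarity"] == 1
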