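"""Feature construction, out-of-fold scoring, thresholding, and metrics."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

import shadowharm as sh
from shadowharm.errors import ConfigurationError
from shadowharm.imputation import default_classifier
from shadowharm.vocabulary import CodeVocabulary


# ---------------------------------------------------------------------------
# features


def _chain_vocab():
    return CodeVocabulary(
        parents={"A": ("B",), "B": ("C",), "C": (), "SH0": ()},
        roles={"A": "background", "B": "background", "C": "background",
               "SH0": "self_harm"},
        drug_class_map={"lithium": "LITHIUM"},
    )


def test_features_expand_to_all_ancestors():
    vocab = _chain_vocab()
    mv = pd.Series({"start_day": 400, "codes": "A"})
    patient = pd.Series({"birth_year": 1990, "sex": "F"})
    feats = sh.build_features(mv, patient, vocab)
    assert feats["code:A"] == feats["code:B"] == feats["code:C"] == 1.0


def test_self_harm_codes_never_appear_as_features():
    vocab = _chain_vocab()
    mv = pd.Series({"start_day": 400, "codes": "A;SH0"})
    patient = pd.Series({"birth_year": 1990, "sex": "M"})
    feats = sh.build_features(mv, patient, vocab)
    assert "code:SH0" not in feats
    assert feats["male_sex"] == 1.0


def test_identical_metavisits_get_identical_vectors():
    vocab = _chain_vocab()
    mv = pd.Series({"start_day": 800, "codes": "B;A"})
    patient = pd.Series({"birth_year": 1975, "sex": "F"})
    assert sh.build_features(mv, patient, vocab) == sh.build_features(mv, patient, vocab)


def test_min_support_drops_rare_codes(imputation_sim, labeled_metavisits):
    mv = labeled_metavisits[labeled_metavisits["has_inpatient_or_er"]]
    X_all, names_all = sh.build_feature_matrix(
        mv, imputation_sim.patients, imputation_sim.vocab, min_support=1)
    X_10, names_10 = sh.build_feature_matrix(
        mv, imputation_sim.patients, imputation_sim.vocab, min_support=10)
    assert set(names_10) <= set(names_all)
    assert len(names_10) < len(names_all)


# ---------------------------------------------------------------------------
# cross-fitted probabilities


def test_outpatient_only_gets_probability_zero(scored_metavisits):
    outp = scored_metavisits[~scored_metavisits["has_inpatient_or_er"]]
    assert (outp["selfharm_prob"] == 0.0).all()


def test_probabilities_in_unit_interval_and_deterministic(
    imputation_sim, labeled_metavisits, scored_metavisits
):
    p = scored_metavisits["selfharm_prob"]
    assert ((p >= 0) & (p <= 1)).all()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        again = sh.crossfit_probabilities(
            labeled_metavisits, imputation_sim.patients, imputation_sim.vocab,
            k=5, seed=1)
    assert np.array_equal(again["selfharm_prob"].to_numpy(), p.to_numpy())


def test_strong_proxy_bundle_gives_high_cv_auc(scored_metavisits):
    """The under-coded world carries a near-deterministic injury-code
    signature, so cross-validated AUC against the coded labels is high."""
    ip = scored_metavisits[scored_metavisits["has_inpatient_or_er"]]
    auc = roc_auc_score(ip["coded_selfharm"], ip["selfharm_prob"])
    assert auc >= 0.95


def test_permuted_labels_give_null_auc(imputation_sim, labeled_metavisits):
    """Shuffling the coded labels destroys the signal: AUC ~ 0.5."""
    mv = labeled_metavisits.copy()
    rng = np.random.default_rng(0)
    ip_mask = mv["has_inpatient_or_er"].to_numpy()
    labels = mv.loc[ip_mask, "coded_selfharm"].to_numpy().copy()
    rng.shuffle(labels)
    mv.loc[ip_mask, "coded_selfharm"] = labels
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = sh.crossfit_probabilities(mv, imputation_sim.patients,
                                        imputation_sim.vocab, k=5, seed=1)
    ip = out[out["has_inpatient_or_er"]]
    auc = roc_auc_score(ip["coded_selfharm"], ip["selfharm_prob"])
    assert abs(auc - 0.5) < 0.12


def test_patient_level_folds_supported(imputation_sim, labeled_metavisits):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = sh.crossfit_probabilities(
            labeled_metavisits, imputation_sim.patients, imputation_sim.vocab,
            k=3, seed=1, fold_unit="patient")
    ip = out[out["has_inpatient_or_er"]]
    assert roc_auc_score(ip["coded_selfharm"], ip["selfharm_prob"]) > 0.8


def test_out_of_fold_discipline(imputation_sim, labeled_metavisits):
    """Fold-assignment audit: the fold that scores a meta-visit never
    contains it in training."""
    from sklearn.model_selection import StratifiedKFold

    sub = labeled_metavisits[labeled_metavisits["has_inpatient_or_er"]]
    y = sub["coded_selfharm"].to_numpy(bool)
    splitter = StratifiedKFold(n_splits=5, shuffle=True, random_state=1)
    seen = np.zeros(len(sub), int)
    for train_idx, test_idx in splitter.split(np.zeros(len(sub)), y):
        assert not set(train_idx) & set(test_idx)
        seen[test_idx] += 1
    assert (seen == 1).all()


def test_too_few_positives_is_an_error(small_sim):
    mv = sh.label_coded_selfharm(sh.build_meta_visits(small_sim.visits), small_sim.vocab)
    with pytest.raises(ConfigurationError, match="coded self-harm"):
        sh.crossfit_probabilities(mv, small_sim.patients, small_sim.vocab, k=5, seed=0)


# ---------------------------------------------------------------------------
# thresholding


def _mv_frame():
    return pd.DataFrame({
        "coded_selfharm": [False, True, False, False],
        "has_inpatient_or_er": [True, True, True, False],
        "selfharm_prob": [0.5, 0.1, 0.9, 0.0],
    })


def test_threshold_boundary_is_strict():
    out = sh.apply_threshold(_mv_frame(), 0.5)
    # p=0.5 not coded at t=0.5: not an outcome (strict >)
    assert not out.iloc[0]


def test_coded_is_outcome_at_any_threshold():
    out = sh.apply_threshold(_mv_frame(), 0.9)
    assert out.iloc[1]  # coded, p=0.1, t=0.9


def test_threshold_one_reduces_to_coded_set():
    mv = _mv_frame()
    out = sh.apply_threshold(mv, 1.0)
    assert list(out) == list(mv["coded_selfharm"])


def test_threshold_monotone(scored_metavisits):
    prev = None
    for t in sh.DEFAULT_THRESHOLDS:
        cur = set(np.nonzero(sh.apply_threshold(scored_metavisits, t).to_numpy())[0])
        if prev is not None:
            assert cur <= prev
        prev = cur


@pytest.mark.parametrize("t", [-0.1, 1.1])
def test_threshold_range_validated(t):
    with pytest.raises(ConfigurationError):
        sh.apply_threshold(_mv_frame(), t)


# ---------------------------------------------------------------------------
# metrics


def test_bd_cohort_worked_example():
    """Printed BD-cohort confusion cells give sensitivity 0.930,
    specificity 0.984, MCC 0.225 (3 d.p.)."""
    counts = sh.ClassificationCounts(488, 37, 8288, 520546, threshold=0.5)
    m = sh.classification_metrics(counts)
    assert round(m["sensitivity"], 3) == 0.930
    assert round(m["specificity"], 3) == 0.984
    assert round(m["mcc"], 3) == 0.225


def test_mmi_cohort_worked_example():
    """Printed MMI-cohort cells: sensitivity 0.962, MCC 0.28 (2 d.p.)."""
    counts = sh.ClassificationCounts(93311, 3717, 1029058, 25266150, threshold=0.5)
    m = sh.classification_metrics(counts)
    assert round(m["sensitivity"], 3) == 0.962
    assert round(m["mcc"], 2) == 0.28


def test_perfect_classifier_metrics():
    m = sh.classification_metrics(sh.ClassificationCounts(10, 0, 0, 90))
    assert m["sensitivity"] == m["specificity"] == m["mcc"] == 1.0


def test_empty_class_is_undefined_not_zero():
    m = sh.classification_metrics(sh.ClassificationCounts(0, 0, 5, 95))
    assert math.isnan(m["sensitivity"])
    assert not math.isnan(m["specificity"])


def test_mcc_matches_brute_force_on_random_tables():
    """MCC from counts equals the direct confusion-table formula computed
    independently on 20 random tables."""
    rng = np.random.default_rng(42)
    for _ in range(20):
        tp, fn, fp, tn = (int(x) for x in rng.integers(1, 500, 4))
        m = sh.classification_metrics(sh.ClassificationCounts(tp, fn, fp, tn))
        num = tp * tn - fp * fn
        den = math.sqrt(float((tp + fp)) * (tp + fn) * (tn + fp) * (tn + fn))
        assert m["mcc"] == pytest.approx(num / den, abs=1e-12)
        assert m["sensitivity"] == pytest.approx(tp / (tp + fn), abs=1e-12)
        assert m["specificity"] == pytest.approx(tn / (tn + fp), abs=1e-12)


def test_counts_from_scores_consistency():
    labels = [True, True, False, False, False]
    probs = [0.9, 0.2, 0.8, 0.4, 0.1]
    c = sh.counts_from_scores(labels, probs, 0.5)
    assert (c.n_coded_imputed, c.n_coded_not_imputed,
            c.n_imputed_not_coded, c.n_neither) == (1, 1, 1, 2)
    assert c.total == 5
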