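"""Cross-validated probabilistic imputation of under-coded self-harm.

Most true self-harm events never receive an explicit self-harm billing code,
but the surrounding care does emit correlated codes (injury, poisoning,
observation, ...).  A probabilistic classifier trained on the *coded* events
(treated as labels) can therefore score every inpatient/ER meta-visit with a
probability that self-harm occurred, and thresholding those probabilities
recovers a large share of the uncoded events.

Scoring is strictly out-of-fold: each meta-visit is scored by a model that
never saw it during training (k-fold cross-validation, folds stratified by
class because coded prevalence is a fraction of a percent).  Purely
outpatient meta-visits are not scored — coded self-harm essentially never
occurs there — and receive probability 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .errors import ConfigurationError, DataError
from .simulate import YEAR_ZERO
from .vocabulary import CodeVocabulary


# ---------------------------------------------------------------------------
# features


def _codes_of(s: str) -> set:
    return {c for c in str(s).split(";") if c}


def build_features(metavisit: pd.Series, patient: pd.Series, vocab: CodeVocabulary) -> dict:
    """Feature vector for a single meta-visit.

    Age at meta-visit start, a male-sex indicator, the calendar start year,
    and a 0/1 indicator for every non-self-harm code present in the
    meta-visit expanded to all of its vocabulary ancestors.  Self-harm codes
    (and ancestors reachable only from them) are excluded: they define the
    label and must not leak into the features.
    """
    excl = vocab.self_harm_feature_exclusions()
    year = YEAR_ZERO + int(metavisit["start_day"]) // 365
    feats: dict = {
        "age_years": float(year - int(patient["birth_year"])),
        "male_sex": 1.0 if patient["sex"] == "M" else 0.0,
        "start_year": float(year),
    }
    expanded: set = set()
    for c in _codes_of(metavisit["codes"]):
        if c in vocab.codes:
            expanded |= vocab.ancestor_closure(c)
    for c in sorted(expanded - excl):
        feats[f"code:{c}"] = 1.0
    return feats


def build_feature_matrix(
    metavisits: pd.DataFrame,
    patients: pd.DataFrame,
    vocab: CodeVocabulary,
    *,
    min_support: int = 10,
) -> tuple[sp.csr_matrix, list[str]]:
    """Sparse design matrix for a meta-visit table.

    Code indicator columns with fewer than ``min_support`` occurrences are
    dropped.  Age and start-year columns are standardized so the penalized
    logistic model treats them on the same scale as the indicators.
    """
    pat = patients.set_index("patient_id")
    missing = set(metavisits["patient_id"]) - set(pat.index)
    if missing:
        raise DataError(f"meta-visits reference unknown patients {sorted(missing)[:5]}")
    excl = vocab.self_harm_feature_exclusions()
    known = vocab.codes

    birth = pat.loc[metavisits["patient_id"], "birth_year"].to_numpy()
    male = (pat.loc[metavisits["patient_id"], "sex"] == "M").to_numpy(float)
    year = YEAR_ZERO + metavisits["start_day"].to_numpy() // 365
    age = (year - birth).astype(float)

    # expand codes to ancestors, count support, then build the sparse matrix
    per_row: list[list[str]] = []
    support: dict[str, int] = {}
    for s in metavisits["codes"]:
        expanded: set = set()
        for c in _codes_of(s):
            if c in known:
                expanded |= vocab.ancestor_closure(c)
        kept = sorted(expanded - excl)
        per_row.append(kept)
        for c in kept:
            support[c] = support.get(c, 0) + 1
    vocab_cols = sorted(c for c, n in support.items() if n >= min_support)
    col_of = {c: j for j, c in enumerate(vocab_cols)}

    indptr = [0]
    indices: list[int] = []
    for kept in per_row:
        idx = sorted(col_of[c] for c in kept if c in col_of)
        indices.extend(idx)
        indptr.append(len(indices))
    codes_mat = sp.csr_matrix(
        (np.ones(len(indices)), indices, indptr),
        shape=(len(metavisits), len(vocab_cols)),
    )

    def standardize(x: np.ndarray) -> np.ndarray:
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    dense = np.column_stack([standardize(age), male, standardize(year.astype(float))])
    X = sp.hstack([sp.csr_matrix(dense), codes_mat], format="csr")
    names = ["age_years", "male_sex", "start_year"] + [f"code:{c}" for c in vocab_cols]
    return X, names


# ---------------------------------------------------------------------------
# cross-fitted probabilities


def default_classifier() -> LogisticRegression:
    """L2-penalized logistic regression on sparse binary features; any
    estimator with fit/predict_proba is accepted in its place.

    Class-balanced weighting is essential here: coded self-harm labels a
    small, thinned sample of the true events, so an unweighted model's
    probabilities would be capped near the coding fraction and a 0.5
    threshold would recover nothing.  Balanced weights put the
    self-harm-signature visits above high thresholds while ordinary
    hospitalizations stay near 0.
    """
    return LogisticRegression(C=0.03, solver="liblinear", max_iter=2000,
                              class_weight="balanced")


def crossfit_probabilities(
    metavisits: pd.DataFrame,
    patients: pd.DataFrame,
    vocab: CodeVocabulary,
    *,
    k: int = 5,
    seed: int = 0,
    classifier_factory=default_classifier,
    min_support: int = 10,
    fold_unit: str = "metavisit",
) -> pd.DataFrame:
    """Attach an out-of-fold ``selfharm_prob`` to every meta-visit.

    Only meta-visits with an inpatient/ER component are scored (and used in
    training); outpatient-only meta-visits get probability 0.  Folds are
    stratified by the coded label; ``fold_unit="patient"`` switches to
    patient-level folds (no within-patient leakage) while keeping
    stratification by whether the patient has any coded meta-visit.
    """
    if "coded_selfharm" not in metavisits.columns:
        raise DataError("meta-visits must be labeled before imputation")
    out = metavisits.copy()
    out["selfharm_prob"] = 0.0
    mask = out["has_inpatient_or_er"].to_numpy(bool)
    sub = out.loc[mask]
    y = sub["coded_selfharm"].to_numpy(bool)
    if y.sum() < k:
        raise ConfigurationError(
            f"need at least k={k} coded self-harm meta-visits, found {int(y.sum())}"
        )
    X, _ = build_feature_matrix(sub, patients, vocab, min_support=min_support)

    probs = np.zeros(len(sub))
    if fold_unit == "patient":
        groups = sub["patient_id"].to_numpy()
        has_pos = pd.Series(y).groupby(groups).transform("max").to_numpy()
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(X, has_pos, groups=groups)
    elif fold_unit == "metavisit":
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(X, y)
    else:
        raise ConfigurationError(f"unknown fold_unit {fold_unit!r}")

    for train_idx, test_idx in split:
        if y[train_idx].sum() == 0 or y[train_idx].sum() == len(train_idx):
            raise ConfigurationError("a fold has a single class; reduce k or add data")
        model = classifier_factory()
        model.fit(X[train_idx], y[train_idx])
        probs[test_idx] = model.predict_proba(X[test_idx])[:, 1]

    out.loc[mask, "selfharm_prob"] = probs
    return out


def apply_threshold(metavisits: pd.DataFrame, t: float) -> pd.Series:
    """Outcome flag: coded self-harm OR (inpatient/ER AND probability > t).

    The inequality is strict, so t = 1.0 reduces the outcome set to coded
    meta-visits exactly, and coded meta-visits are outcomes at every t
    ("coded and/or imputed").
    """
    if not (0.0 <= t <= 1.0):
        raise ConfigurationError(f"threshold must lie in [0, 1], got {t}")
    coded = metavisits["coded_selfharm"].astype(bool)
    imputed = metavisits["has_inpatient_or_er"].astype(bool) & (
        metavisits["selfharm_prob"] > t
    )
    return (coded | imputed).rename("outcome")


# ---------------------------------------------------------------------------
# metrics


@dataclass(frozen=True)
class ClassificationCounts:
    """Confusion cells treating the coded label as truth and "imputed"
    (probability > threshold) as the prediction."""

    n_coded_imputed: int       # TP
    n_coded_not_imputed: int   # FN
    n_imputed_not_coded: int   # FP
    n_neither: int             # TN
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if min(self.n_coded_imputed, self.n_coded_not_imputed,
               self.n_imputed_not_coded, self.n_neither) < 0:
            raise ConfigurationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return (self.n_coded_imputed + self.n_coded_not_imputed
                + self.n_imputed_not_coded + self.n_neither)


def counts_from_scores(labels, probabilities, t: float = 0.5) -> ClassificationCounts:
    labels = np.asarray(labels, bool)
    pred = np.asarray(probabilities, float) > t
    return ClassificationCounts(
        n_coded_imputed=int((labels & pred).sum()),
        n_coded_not_imputed=int((labels & ~pred).sum()),
        n_imputed_not_coded=int((~labels & pred).sum()),
        n_neither=int((~labels & ~pred).sum()),
        threshold=t,
    )


def classification_metrics(
    counts: ClassificationCounts,
    probabilities=None,
    labels=None,
) -> dict:
    """Sensitivity, specificity, MCC from the confusion cells; AUC by the
    rank statistic over probabilities vs the coded labels when provided.

    Empty classes yield NaN ("undefined"), never 0.
    """
    tp, fn = counts.n_coded_imputed, counts.n_coded_not_imputed
    fp, tn = counts.n_imputed_not_coded, counts.n_neither
    sens = tp / (tp + fn) if (tp + fn) > 0 else math.nan
    spec = tn / (tn + fp) if (tn + fp) > 0 else math.nan
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom2) if denom2 > 0 else math.nan
    auc = math.nan
    if probabilities is not None and labels is not None:
        labels = np.asarray(labels, bool)
        if 0 < labels.sum() < len(labels):
            auc = float(roc_auc_score(labels, np.asarray(probabilities, float)))
    return {"sensitivity": sens, "specificity": spec, "mcc": mcc, "auc": auc}
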