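"""Cohort staging: eligibility, the prespecified sequence of events, and
baseline covariates.

A patient enters the analysis when the prespecified sequence can be located:
(1) at least 365 days of enrollment (the covariate lookback), (2) an *index
visit* — the first meta-visit carrying a bipolar-disorder code with a full
lookback behind it, (3) the *index exposure* starting on the last day of the
index visit (time zero), (4) the time-varying exposure period, and (5) either
the outcome (first post-index meta-visit with coded-and/or-imputed self-harm
at the active threshold) or right censoring.  Censoring events are: the first
post-index inpatient/ER meta-visit that is not an outcome, onset of a
censoring condition (intellectual disability, autism, organic mental illness,
Parkinson disease — role ``censoring_condition``), an anti-dementia drug
fill, or the end of enrollment, whichever comes first (an outcome wins a
tied day).

Eligibility requires two or more bipolar-disorder diagnosis codes and no
major-mental-illness exclusion code (major depressive disorder,
schizophrenia, schizoaffective disorder) anywhere in the observation period.
Prior coded self-harm is a baseline covariate, not an exclusion.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DataError
from .vocabulary import CodeVocabulary

LOOKBACK_DAYS = 365

END_REASONS = ("outcome", "censor_hospitalization", "censor_condition", "end_of_observation")

STAGED_COLUMNS = [
    "patient_id", "index_start_day", "index_exposure_day",
    "observation_end_day", "end_reason",
]


def _codes_of(s: str) -> set:
    return {c for c in str(s).split(";") if c}


def _tokenized(metavisits: pd.DataFrame) -> list[set]:
    return [_codes_of(s) for s in metavisits["codes"]]


def check_eligibility(metavisits: pd.DataFrame, vocab: CodeVocabulary) -> pd.DataFrame:
    """Per-patient eligibility decision with a machine-readable reason.

    Counts distinct (meta-visit, BD code) occurrences; the exclusion scan
    covers the entire observation period.
    """
    bd = vocab.bd_codes
    excl = vocab.exclusion_codes
    tokens = _tokenized(metavisits)
    pids = metavisits["patient_id"].to_numpy()
    n_bd: dict = {}
    has_excl: dict = {}
    for pid, cs in zip(pids, tokens):
        n_bd[pid] = n_bd.get(pid, 0) + len(cs & bd)
        has_excl[pid] = has_excl.get(pid, False) or bool(cs & excl)
    rows = []
    for pid in sorted(n_bd):
        if has_excl[pid]:
            rows.append((pid, False, "exclusion_mmi"))
        elif n_bd[pid] < 2:
            rows.append((pid, False, "insufficient_bd_codes"))
        else:
            rows.append((pid, True, ""))
    return pd.DataFrame(rows, columns=["patient_id", "eligible", "reason"])


def locate_sequence(
    metavisits: pd.DataFrame,
    patients: pd.DataFrame,
    fills: pd.DataFrame,
    vocab: CodeVocabulary,
    threshold: float | None = None,
    *,
    outcome: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Locate the prespecified sequence for every eligible patient.

    ``outcome`` is the per-meta-visit outcome flag (from
    :func:`shadowharm.imputation.apply_threshold`); if absent it is computed
    from ``threshold``.  Returns ``(staged, reasons)`` where ``staged`` has
    one row per staged patient and ``reasons`` logs every non-staged patient.
    """
    from .imputation import apply_threshold

    if outcome is None:
        if threshold is None:
            raise DataError("either an outcome flag or a threshold is required")
        outcome = apply_threshold(metavisits, threshold)

    order = np.lexsort((
        metavisits["end_day"].to_numpy(), metavisits["start_day"].to_numpy(),
        metavisits["patient_id"].to_numpy(),
    ))
    mv = metavisits.iloc[order]
    out_flag = outcome.to_numpy(bool)[order]

    bd, excl, cens = vocab.bd_codes, vocab.exclusion_codes, vocab.censoring_codes
    tokens = _tokenized(mv)
    pids = mv["patient_id"].to_numpy()
    starts = mv["start_day"].to_numpy()
    ends = mv["end_day"].to_numpy()
    ip_er = mv["has_inpatient_or_er"].to_numpy(bool)
    n_bd = np.fromiter((len(cs & bd) for cs in tokens), int, len(tokens))
    is_excl = np.fromiter((bool(cs & excl) for cs in tokens), bool, len(tokens))
    is_cens = np.fromiter((bool(cs & cens) for cs in tokens), bool, len(tokens))

    pat = patients.set_index("patient_id")
    unknown = set(pids) - set(pat.index)
    if unknown:
        raise DataError(f"meta-visits for unknown patients {sorted(unknown)[:5]}")
    e_start = pat["enroll_start_day"].to_dict()
    e_end = pat["enroll_end_day"].to_dict()

    dem_first: dict = {}
    if len(fills) and vocab.censoring_drug_ids:
        dem = fills[fills["drug_id"].isin(vocab.censoring_drug_ids)]
        dem_first = dem.groupby("patient_id")["fill_day"].min().to_dict()

    prec = {r: i for i, r in enumerate(END_REASONS)}
    staged_rows: list[tuple] = []
    reason_rows: list[tuple] = []
    bounds = np.flatnonzero(np.r_[True, pids[1:] != pids[:-1], True])
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        pid = pids[b0]
        sl = slice(b0, b1)
        if is_excl[sl].any():
            reason_rows.append((pid, "exclusion_mmi"))
            continue
        if int(n_bd[sl].sum()) < 2:
            reason_rows.append((pid, "insufficient_bd_codes"))
            continue
        es = int(e_start[pid])
        idx = None
        for i in range(b0, b1):
            if n_bd[i] > 0 and int(ends[i]) - es >= LOOKBACK_DAYS:
                idx = i
                break
        if idx is None:
            reason_rows.append((pid, "no_index"))
            continue
        t0 = int(ends[idx])

        candidates: list[tuple[int, str]] = [(int(e_end[pid]), "end_of_observation")]
        for i in range(b0, b1):
            d = int(starts[i])
            if d <= t0:
                continue
            if out_flag[i]:
                candidates.append((d, "outcome"))
            elif ip_er[i]:
                candidates.append((d, "censor_hospitalization"))
            if is_cens[i]:
                candidates.append((d, "censor_condition"))
        dem_day = dem_first.get(pid)
        if dem_day is not None and dem_day > t0:
            candidates.append((int(dem_day), "censor_condition"))
        day, reason = min(candidates, key=lambda c: (c[0], prec[c[1]]))
        if day <= t0:
            reason_rows.append((pid, "no_followup"))
            continue
        staged_rows.append((pid, int(starts[idx]), t0, day, reason))

    staged = pd.DataFrame(staged_rows, columns=STAGED_COLUMNS)
    reasons = pd.DataFrame(reason_rows, columns=["patient_id", "reason"])
    return staged, reasons


def extract_baseline_covariates(
    staged: pd.DataFrame,
    metavisits: pd.DataFrame,
    fills: pd.DataFrame,
    patients: pd.DataFrame,
    vocab: CodeVocabulary,
    *,
    covariate_codesets: Mapping[str, frozenset] | None = None,
    depression_codes: frozenset | None = None,
    mania_codes: frozenset | None = None,
    psychosis_codes: frozenset | None = None,
) -> pd.DataFrame:
    """Baseline (pretreatment) covariates per staged patient.

    Binary presence of each configured code set within the 365-day lookback
    ``[t0-365, t0-1]`` (t0 = index exposure day), prior hospitalization,
    prior coded self-harm, sex, age at index, and index-visit
    characteristics: outpatient setting present, mood polarity
    (depression / mania / unknown) and psychotic features when the
    corresponding code sets are configured.
    """
    from .simulate import YEAR_ZERO

    covariate_codesets = dict(covariate_codesets or {})
    pat = patients.set_index("patient_id")
    sh = vocab.self_harm_codes
    tokens = _tokenized(metavisits)
    pids = metavisits["patient_id"].to_numpy()
    starts = metavisits["start_day"].to_numpy()
    ends = metavisits["end_day"].to_numpy()
    ip_er = metavisits["has_inpatient_or_er"].to_numpy(bool)
    settings = metavisits["settings"].to_numpy()
    row_idx: dict = {}
    for i, pid in enumerate(pids):
        row_idx.setdefault(pid, []).append(i)

    rows = []
    for srow in staged.itertuples(index=False):
        pid = srow.patient_id
        t0 = int(srow.index_exposure_day)
        lo, hi = t0 - LOOKBACK_DAYS, t0 - 1
        idxs = row_idx.get(pid)
        if idxs is None:
            raise DataError(f"no meta-visits for staged patient {pid}")
        rec: dict = {"patient_id": pid}
        rec["male_sex"] = 1 if pat.loc[pid, "sex"] == "M" else 0
        year0 = YEAR_ZERO + t0 // 365
        rec["age_at_index"] = int(year0 - pat.loc[pid, "birth_year"])

        prior_hosp = prior_sh = 0
        lookback_codes: set = set()
        index_codes: set = set()
        index_settings: set = set()
        for i in idxs:
            cs = tokens[i]
            if starts[i] <= hi and ends[i] >= lo:  # overlaps lookback window
                lookback_codes |= cs
                if ip_er[i]:
                    prior_hosp = 1
                if cs & sh:
                    prior_sh = 1
            if starts[i] == int(srow.index_start_day) and ends[i] == t0:
                index_codes = cs
                index_settings = set(str(settings[i]).split(";"))
        rec["prior_hospitalization"] = prior_hosp
        rec["prior_self_harm"] = prior_sh
        rec["outpatient_visit_present"] = 1 if "outpatient" in index_settings else 0
        for name, codeset in covariate_codesets.items():
            rec[name] = 1 if lookback_codes & set(codeset) else 0

        dep = 1 if depression_codes and index_codes & set(depression_codes) else 0
        man = 1 if mania_codes and index_codes & set(mania_codes) else 0
        rec["depression_index"] = dep
        rec["mania_index"] = man
        rec["unknown_polarity"] = 0 if (dep or man) else 1
        rec["psychotic_features"] = (
            1 if psychosis_codes and index_codes & set(psychosis_codes) else 0
        )
        rows.append(rec)
    return pd.DataFrame(rows)
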