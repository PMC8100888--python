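"""Meta-visit construction and coded self-harm labeling.

A self-harm event usually touches several points of care in quick succession
(ER, admission, follow-up).  To treat that activity as one care episode,
consecutive outpatient/inpatient/ER visits with no gap between them are merged
into a single "meta-visit" carrying the union of codes and settings.  A
meta-visit is labeled class 1 (coded self-harm) when it contains at least one
code from the vocabulary's self-harm set, else class 0.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import DataError
from .vocabulary import CodeVocabulary

METAVISIT_COLUMNS = [
    "patient_id", "start_day", "end_day", "settings", "codes",
    "n_visits", "has_inpatient_or_er",
]


def build_meta_visits(visits: pd.DataFrame, *, merge_gap: int = 1,
                      patients: pd.DataFrame | None = None) -> pd.DataFrame:
    """Merge each patient's visits into disjoint, non-abutting meta-visits.

    Two visits merge when the later one starts no more than ``merge_gap``
    days after the earlier one ends (default 1: overlapping, same-day, and
    adjacent-day visits merge — adjacent days capture transfers between care
    settings).  Input order is irrelevant: visits are sorted internally.

    Parameters
    ----------
    visits : DataFrame with columns patient_id, setting, start_day, end_day,
        codes (";"-separated code identifiers).
    merge_gap : maximum day gap closed by the merge (0 merges only
        overlapping/same-day visits).
    patients : optional patient table; when given, visits outside a patient's
        enrollment raise a DataError naming the offending rows.
    """
    bad = visits.index[visits["start_day"] > visits["end_day"]]
    if len(bad):
        raise DataError(f"visits with start_day > end_day at rows {list(bad[:5])}")
    if patients is not None:
        p = patients.set_index("patient_id")
        unknown = set(visits["patient_id"]) - set(p.index)
        if unknown:
            raise DataError(f"visits for unknown patients {sorted(unknown)[:5]}")
        es = p.loc[visits["patient_id"], "enroll_start_day"].to_numpy()
        ee = p.loc[visits["patient_id"], "enroll_end_day"].to_numpy()
        viol = visits.index[(visits["start_day"].to_numpy() < es)
                            | (visits["end_day"].to_numpy() > ee)]
        if len(viol):
            raise DataError(f"visits outside enrollment at rows {list(viol[:5])}")

    if len(visits) == 0:
        return pd.DataFrame(columns=METAVISIT_COLUMNS)

    v = visits.sort_values(["patient_id", "start_day", "end_day"], kind="mergesort")
    pids = v["patient_id"].to_numpy()
    starts = v["start_day"].to_numpy()
    ends = v["end_day"].to_numpy()
    settings = v["setting"].to_numpy()
    codes = v["codes"].to_numpy()

    rows: list[tuple] = []
    cur_pid = None
    cur_start = cur_end = 0
    cur_codes: set = set()
    cur_settings: set = set()
    cur_n = 0

    def flush() -> None:
        rows.append((
            cur_pid, cur_start, cur_end,
            ";".join(sorted(cur_settings)),
            ";".join(sorted(cur_codes)),
            cur_n,
            bool(cur_settings & {"inpatient", "ER"}),
        ))

    for i in range(len(v)):
        if cur_pid is not None and pids[i] == cur_pid and starts[i] <= cur_end + merge_gap:
            cur_end = max(cur_end, int(ends[i]))
            cur_settings.add(settings[i])
            cur_codes.update(c for c in str(codes[i]).split(";") if c)
            cur_n += 1
        else:
            if cur_pid is not None:
                flush()
            cur_pid = pids[i]
            cur_start, cur_end = int(starts[i]), int(ends[i])
            cur_settings = {settings[i]}
            cur_codes = {c for c in str(codes[i]).split(";") if c}
            cur_n = 1
    flush()
    return pd.DataFrame(rows, columns=METAVISIT_COLUMNS)


def label_coded_selfharm(metavisits: pd.DataFrame, vocab: CodeVocabulary) -> pd.DataFrame:
    """Attach the class-0/1 ``coded_selfharm`` label.

    Codes absent from the vocabulary trigger a warning and count as
    background (they can never label a meta-visit class 1).
    """
    sh = vocab.self_harm_codes
    known = vocab.codes
    out = metavisits.copy()
    labels = np.zeros(len(out), dtype=bool)
    unknown: set = set()
    code_col = out["codes"].to_numpy()
    for i in range(len(out)):
        cs = {c for c in str(code_col[i]).split(";") if c}
        unknown |= cs - known
        labels[i] = bool(cs & sh)
    if unknown:
        warnings.warn(
            f"{len(unknown)} codes not in vocabulary treated as background "
            f"(e.g. {sorted(unknown)[:3]})",
            stacklevel=2,
        )
    out["coded_selfharm"] = labels
    return out


def metavisits_as_visits(metavisits: pd.DataFrame) -> pd.DataFrame:
    """Re-express meta-visits as a visit table (used for idempotence checks)."""
    return pd.DataFrame({
        "patient_id": metavisits["patient_id"],
        "setting": [s.split(";")[0] for s in metavisits["settings"]],
        "start_day": metavisits["start_day"],
        "end_day": metavisits["end_day"],
        "codes": metavisits["codes"],
    })
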