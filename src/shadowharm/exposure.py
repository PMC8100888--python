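"""Time-varying regimen exposure construction.

Drug fills (fill day + days supply) are turned into per-agent coverage
spans, gaps of at most ``grace_days`` are bridged, and overlapping agents are
resolved into either a combination regimen or a switch: when a new agent
starts and a previously active agent has less than ``grace_days`` of residual
coverage, the old agent is treated as switched away (truncated at the new
start) rather than combined.  At every day the active agent set defines the
regimen; uncovered spans are "no drug".

Regimen labels: monotherapies carry the agent name; combinations carry one
token per drug class (sorted); two or more agents of the same class collapse
to MULTI_MSA / MULTI_SGA for those two classes.  Regimens that fail the
power requisites (>= ``min_intervals`` treatment intervals and >=
``min_events`` outcomes cohort-wide) collapse to POLYPHARMACY_2/3/4 by class
count, or to UNCOMMON_MONOTHERAPY; NO_DRUG never collapses.

The final product is a counting-process table: half-open (start, stop] rows
relative to the index exposure day with the event flag on the terminal
interval of patients whose observation ended in an outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .staging import LOOKBACK_DAYS
from .vocabulary import CodeVocabulary

NO_DRUG = "NO_DRUG"

POLY_LABELS = {2: "POLYPHARMACY_2", 3: "POLYPHARMACY_3", 4: "POLYPHARMACY_4"}
UNCOMMON = "UNCOMMON_MONOTHERAPY"


# ---------------------------------------------------------------------------
# per-patient timeline


def _agent_coverage(fill_days: np.ndarray, supplies: np.ndarray, grace_days: int) -> list[list[int]]:
    """Union of [fill, fill+supply) spans, bridging gaps <= grace_days."""
    order = np.argsort(fill_days, kind="mergesort")
    spans: list[list[int]] = []
    for i in order:
        s, e = int(fill_days[i]), int(fill_days[i] + supplies[i])
        if spans and s <= spans[-1][1] + grace_days:
            spans[-1][1] = max(spans[-1][1], e)
        else:
            spans.append([s, e])
    return spans


def assign_regimen_timeline(
    fills: pd.DataFrame,
    vocab: CodeVocabulary,
    window: tuple[int, int],
    grace_days: int = 30,
) -> list[tuple[int, int, frozenset]]:
    """Raw regimen timeline for one patient over half-open ``window``.

    Returns ``[(start, stop, agents), ...]`` partitioning the window;
    ``agents`` is a frozenset of drug ids (empty = no drug).
    """
    return _timeline(
        fills["drug_id"].to_numpy(), fills["fill_day"].to_numpy(),
        fills["days_supply"].to_numpy(), vocab, window, grace_days,
    )


def _timeline(drug_ids, fill_days, supplies, vocab, window, grace_days):
    w0, w1 = window
    if w0 >= w1:
        raise ConfigurationError(f"empty window {window}")

    cov: dict[str, list[list[int]]] = {}
    for j in range(len(drug_ids)):
        d = drug_ids[j]
        if d in vocab.drug_class_map:
            cov.setdefault(d, []).append(j)
    for drug, idx in cov.items():
        cov[drug] = _agent_coverage(
            np.asarray([fill_days[j] for j in idx]),
            np.asarray([supplies[j] for j in idx]), grace_days,
        )

    # switch rule: at each span start, truncate other agents with < grace
    # residual coverage
    starts = sorted(
        (span[0], drug, span) for drug, spans in cov.items() for span in spans
    )
    for s, drug, _span in starts:
        for other, spans in cov.items():
            if other == drug:
                continue
            for sp in spans:
                if sp[0] < s < sp[1] and (sp[1] - s) < grace_days:
                    sp[1] = s

    points = {w0, w1}
    for spans in cov.values():
        for s, e in spans:
            if w0 < s < w1:
                points.add(s)
            if w0 < e < w1:
                points.add(e)
    cuts = sorted(points)
    out: list[tuple[int, int, frozenset]] = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        active = frozenset(
            drug for drug, spans in cov.items()
            if any(s <= a and b <= e for s, e in spans)
        )
        if out and out[-1][2] == active:
            out[-1] = (out[-1][0], b, active)
        else:
            out.append((a, b, active))
    return out


def label_for_agents(agents: frozenset, vocab: CodeVocabulary) -> str:
    """Canonical regimen label for an agent set."""
    if not agents:
        return NO_DRUG
    if len(agents) == 1:
        return next(iter(agents)).upper()
    by_class: dict[str, list[str]] = {}
    for a in sorted(agents):
        by_class.setdefault(vocab.drug_class_map[a], []).append(a)
    tokens = []
    for cls, members in by_class.items():
        if len(members) >= 2 and cls in ("MSA", "SGA"):
            tokens.append(f"MULTI_{cls}")
        else:
            tokens.append(cls)
    if len(tokens) == 1:
        return tokens[0]  # pure within-class polypharmacy
    return "+".join(sorted(tokens))


def _n_classes(label: str) -> int:
    return len(label.split("+"))


def _is_monotherapy(label: str, vocab: CodeVocabulary) -> bool:
    return "+" not in label and label.lower() in vocab.drug_class_map


# ---------------------------------------------------------------------------
# cohort-level interval construction


def build_intervals(
    staged: pd.DataFrame,
    fills: pd.DataFrame,
    vocab: CodeVocabulary,
    *,
    grace_days: int = 30,
) -> pd.DataFrame:
    """Raw labeled exposure intervals for every staged patient.

    One row per interval partitioning ``(index_exposure_day,
    observation_end_day]``; the terminal interval carries ``event=True`` iff
    the patient's end reason is "outcome".
    """
    unknown = (set(fills["drug_id"]) - set(vocab.drug_class_map)
               - set(vocab.censoring_drug_ids)) if len(fills) else set()
    if unknown:
        raise ConfigurationError(f"unknown drug ids {sorted(unknown)[:5]}")
    fills_by_pid: dict = {}
    if len(fills):
        for pid, grp in fills.groupby("patient_id", sort=False):
            fills_by_pid[pid] = (
                grp["drug_id"].to_numpy(), grp["fill_day"].to_numpy(),
                grp["days_supply"].to_numpy(),
            )
    empty = (np.empty(0, object), np.empty(0, int), np.empty(0, int))
    rows = []
    label_cache: dict[frozenset, str] = {}
    for srow in staged.itertuples(index=False):
        pid = srow.patient_id
        t0 = int(srow.index_exposure_day)
        t1 = int(srow.observation_end_day)
        di, fd, ds = fills_by_pid.get(pid, empty)
        timeline = _timeline(di, fd, ds, vocab, (t0, t1), grace_days)
        is_outcome = srow.end_reason == "outcome"
        for i, (s, e, agents) in enumerate(timeline):
            lab = label_cache.get(agents)
            if lab is None:
                lab = label_cache[agents] = label_for_agents(agents, vocab)
            rows.append((
                pid, s, e, ";".join(sorted(agents)), lab,
                bool(is_outcome and i == len(timeline) - 1),
            ))
    return pd.DataFrame(
        rows, columns=["patient_id", "start_day", "stop_day", "agents", "regimen", "event"]
    )


@dataclass
class RegimenCatalog:
    """Per-label interval/event tallies and the collapse map."""

    counts: pd.DataFrame  # label, n_intervals, n_events, collapsed_to
    min_intervals: int
    min_events: int

    @property
    def retained(self) -> list[str]:
        c = self.counts
        return sorted(c.loc[c["label"] == c["collapsed_to"], "label"])


def collapse_regimens(
    intervals: pd.DataFrame,
    vocab: CodeVocabulary,
    *,
    min_intervals: int = 1000,
    min_events: int = 5,
    keep: frozenset = frozenset(),
) -> tuple[pd.DataFrame, RegimenCatalog]:
    """Collapse regimens failing the power requisites into pooled buckets.

    Labels in ``keep`` (e.g. the model's reference regimen) are retained
    regardless of the requisites; NO_DRUG never collapses.
    """
    if min_intervals < 1 or min_events < 1:
        raise ConfigurationError("requisite thresholds must be >= 1")
    tally = (
        intervals.groupby("regimen")
        .agg(n_intervals=("regimen", "size"), n_events=("event", "sum"))
        .reset_index()
        .rename(columns={"regimen": "label"})
    )
    mapping: dict[str, str] = {}
    for row in tally.itertuples(index=False):
        lab = row.label
        if lab == NO_DRUG or lab in keep:
            mapping[lab] = lab
        elif row.n_intervals >= min_intervals and row.n_events >= min_events:
            mapping[lab] = lab
        elif _is_monotherapy(lab, vocab):
            mapping[lab] = UNCOMMON
        else:
            # class count; a lone MULTI_* token is within-class polypharmacy
            # of two agents
            n = _n_classes(lab)
            if n == 1:
                n = 2
            mapping[lab] = POLY_LABELS[min(4, n)]
    out = intervals.copy()
    out["regimen"] = out["regimen"].map(mapping)
    tally["collapsed_to"] = tally["label"].map(mapping)
    catalog = RegimenCatalog(counts=tally, min_intervals=min_intervals, min_events=min_events)
    return out, catalog


# ---------------------------------------------------------------------------
# counting-process rows


def emit_counting_process(
    staged: pd.DataFrame,
    intervals: pd.DataFrame,
    fills: pd.DataFrame,
    vocab: CodeVocabulary,
    *,
    psychotherapy_days: pd.DataFrame | None = None,
    baseline_covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Counting-process rows: (start, stop] relative to the index exposure.

    ``psychotherapy_days`` has columns (patient_id, day) listing days on
    which a psychotherapy procedure code was billed; an interval's
    psychotherapy flag is 1 when any such day falls inside it.
    ``prior_unique_bd_drugs`` counts unique study drugs filled in the
    365-day lookback plus agents of all earlier exposure intervals.
    """
    t0_of = staged.set_index("patient_id")["index_exposure_day"].to_dict()
    t1_of = staged.set_index("patient_id")["observation_end_day"].to_dict()
    psy_by_pid: dict = {}
    if psychotherapy_days is not None and len(psychotherapy_days):
        for pid, grp in psychotherapy_days.groupby("patient_id", sort=False):
            psy_by_pid[pid] = np.sort(grp["day"].to_numpy())
    lb_drugs: dict = {}
    if len(fills):
        lb = fills[fills["drug_id"].isin(vocab.drug_class_map)]
        for pid, grp in lb.groupby("patient_id", sort=False):
            lb_drugs[pid] = (grp["fill_day"].to_numpy(), grp["drug_id"].to_numpy())

    order = np.lexsort((intervals["start_day"].to_numpy(),
                        intervals["patient_id"].to_numpy()))
    iv = intervals.iloc[order]
    pids = iv["patient_id"].to_numpy()
    i_start = iv["start_day"].to_numpy()
    i_stop = iv["stop_day"].to_numpy()
    i_agents = iv["agents"].to_numpy()
    i_regimen = iv["regimen"].to_numpy()
    i_event = iv["event"].to_numpy(bool)

    rows = []
    bounds = np.flatnonzero(np.r_[True, pids[1:] != pids[:-1], True])
    empty_days = np.empty(0, int)
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        pid = pids[b0]
        t0, t1 = int(t0_of[pid]), int(t1_of[pid])
        if int(i_start[b0]) < t0 or int(i_stop[b1 - 1]) > t1:
            raise DataError(f"intervals outside observation window for patient {pid}")

        prior: set = set()
        pf = lb_drugs.get(pid)
        if pf is not None:
            days, drugs = pf
            m = (days >= t0 - LOOKBACK_DAYS) & (days < t0)
            prior = set(drugs[m])
        psy_days = psy_by_pid.get(pid, empty_days)

        for i in range(b0, b1):
            s, e = int(i_start[i]), int(i_stop[i])
            j0, j1 = np.searchsorted(psy_days, [s, e])
            rows.append((
                pid, s - t0, e - t0, i_regimen[i], bool(i_event[i]),
                int(j1 > j0), len(prior),
            ))
            prior |= {a for a in str(i_agents[i]).split(";") if a}

    out = pd.DataFrame(rows, columns=[
        "patient_id", "start", "stop", "regimen", "event",
        "psychotherapy", "prior_unique_bd_drugs",
    ])
    if baseline_covariates is not None:
        out = out.merge(baseline_covariates, on="patient_id", how="left", validate="m:1")
    return out


def psychotherapy_day_table(visits: pd.DataFrame, vocab: CodeVocabulary) -> pd.DataFrame:
    """(patient_id, day) rows for visits carrying a psychotherapy code."""
    pt = vocab.psychotherapy_codes
    rows = []
    for row in visits.itertuples(index=False):
        cs = {c for c in str(row.codes).split(";") if c}
        if cs & pt:
            rows.append((row.patient_id, int(row.start_day)))
    return pd.DataFrame(rows, columns=["patient_id", "day"])
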