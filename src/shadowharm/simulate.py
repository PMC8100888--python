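"""Synthetic longitudinal claims generator with planted ground truth.

The pipeline's target data (US commercial-claims-style enrollment spans, visit streams
with day-resolved diagnosis/procedure code sets, and outpatient drug fills
with days supply) is proprietary, so every downstream stage is exercised on a
generator whose data-generating process is fully known:

* each patient gets an enrollment span, a bipolar-disorder (BD) diagnosis
  stream, and a sequence of treatment episodes whose regimen is drawn from a
  logistic model on planted patient-level confounders (sicker patients are
  pushed toward combination regimens — indication bias);
* true self-harm events arise from a piecewise-constant-hazard exponential
  process, hazard = baseline x exp(planted regimen log-HR + confounder and
  psychotherapy effects), matching the proportional-hazards model fitted
  downstream;
* every true event produces an inpatient-or-ER visit that always carries a
  bundle of proxy injury codes, but carries an explicit self-harm code only
  with probability ``coding_fraction`` — the under-recording phenomenon
  (roughly 1 in 19 events coded in US claims) that motivates the imputation
  stage.

Time is day-indexed (day 0 = simulation start, calendar year
``YEAR_ZERO + day // 365``); visit intervals are closed on both ends.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, StateError
from .vocabulary import CodeVocabulary, generate_vocabulary

YEAR_ZERO = 2003

PATIENT_COLUMNS = ["patient_id", "sex", "birth_year", "enroll_start_day", "enroll_end_day"]
VISIT_COLUMNS = ["patient_id", "setting", "start_day", "end_day", "codes"]
FILL_COLUMNS = ["patient_id", "drug_id", "fill_day", "days_supply"]


@dataclass
class GroundTruth:
    """Planted parameters of the synthetic world.

    ``regimen_log_hr`` maps regimen labels to log hazard ratios versus
    lithium monotherapy (label "LITHIUM" is the reference and must map to 0
    if present).  ``confounder_effects`` maps confounder names to
    ``(effect_on_treatment, effect_on_log_hazard)`` pairs: the first shifts
    the assignment logits of combination regimens, the second multiplies the
    self-harm hazard.
    """

    regimen_log_hr: dict[str, float]
    confounder_effects: dict[str, tuple[float, float]] = field(default_factory=dict)
    coding_fraction: float = 1.0 / 19.0
    baseline_hazard: float = 4e-5
    psychotherapy_log_hr: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.coding_fraction <= 1.0):
            raise ConfigurationError("coding_fraction must lie in (0, 1]")
        if self.baseline_hazard < 0:
            raise ConfigurationError("baseline_hazard must be non-negative")
        if not self.regimen_log_hr:
            raise ConfigurationError("at least one regimen is required")


def default_ground_truth(seed: int = 0) -> GroundTruth:
    """Study-shaped defaults: a protective drug-free state, protective MSA /
    SSRI monotherapies, modestly harmful lithium combinations, under-recording
    of 1 in 19 events, and two confounders that drive both treatment
    intensification and self-harm hazard."""
    return GroundTruth(
        regimen_log_hr={
            "LITHIUM": 0.0,
            "VALPROATE": -0.34,
            "LAMOTRIGINE": -0.30,
            "QUETIAPINE": -0.05,
            "FLUOXETINE": -0.49,
            "LITHIUM+MSA": 0.30,
            "LITHIUM+SGA": 0.29,
            "NO_DRUG": -0.58,
        },
        confounder_effects={
            "substance_abuse": (0.9, 0.65),
            "prior_injury": (0.6, 0.50),
        },
        coding_fraction=1.0 / 19.0,
        baseline_hazard=4e-5,
        psychotherapy_log_hr=-0.5,
        seed=seed,
    )


def agents_for_label(label: str, vocab: CodeVocabulary) -> tuple[str, ...]:
    """Resolve a regimen label to a concrete agent tuple.

    Tokens separated by "+" are either agent names (monotherapy components),
    drug-class names (resolved to the class's first agent not already used),
    or the within-class labels MULTI_MSA / MULTI_SGA (two agents of the
    class).  "NO_DRUG" resolves to the empty tuple.
    """
    if label == "NO_DRUG":
        return ()
    by_class: dict[str, list[str]] = {}
    for agent, cls in vocab.drug_class_map.items():
        by_class.setdefault(cls, []).append(agent)
    for cls in by_class:
        by_class[cls].sort()
    agents: list[str] = []
    for token in label.split("+"):
        token = token.strip()
        if token in ("MULTI_MSA", "MULTI_SGA"):
            cls = token.split("_")[1]
            agents.extend(by_class[cls][:2])
            continue
        lower = token.lower()
        if lower in vocab.drug_class_map:
            agents.append(lower)
            continue
        if token in by_class:
            pick = next(a for a in by_class[token] if a not in agents)
            agents.append(pick)
            continue
        raise ConfigurationError(f"cannot resolve regimen token {token!r}")
    return tuple(agents)


@dataclass
class SimulatedClaims:
    """Generated tables plus the oracle state needed for recovery tests."""

    patients: pd.DataFrame
    visits: pd.DataFrame
    fills: pd.DataFrame
    vocab: CodeVocabulary
    ground_truth: GroundTruth
    confounder_codes: dict[str, str]
    confounder_values: pd.DataFrame
    index_days: dict[int, int]
    _events: pd.DataFrame | None = None
    _exposure: pd.DataFrame | None = None

    def oracle_event_table(self) -> pd.DataFrame:
        """Exhaustive table of true self-harm events: (patient_id,
        true_event_day, was_coded, regimen)."""
        if self._events is None:
            raise StateError("population not generated")
        return self._events.copy()

    def true_exposure(self) -> pd.DataFrame:
        """Ground-truth regimen spans (patient_id, start_day, end_day,
        regimen, psychotherapy, pre_index); half-open [start_day, end_day)."""
        if self._exposure is None:
            raise StateError("population not generated")
        return self._exposure.copy()

    def oracle_counting_process(self) -> pd.DataFrame:
        """Counting-process rows built from the ground-truth exposure spans
        and true events (follow-up from the first BD visit to the first
        post-index true event or enrollment end).

        This bypasses visit/fill reconstruction entirely; it is the oracle
        side of parameter-recovery checks, not a pipeline stage.
        """
        if self._exposure is None or self._events is None:
            raise StateError("population not generated")
        first_event: dict[int, int] = {}
        for pid, day in zip(self._events["patient_id"], self._events["true_event_day"]):
            t0 = self.index_days[pid]
            if day >= t0 and (pid not in first_event or day < first_event[pid]):
                first_event[pid] = int(day)

        ex = self._exposure[~self._exposure["pre_index"]]
        order = np.lexsort((ex["start_day"].to_numpy(), ex["patient_id"].to_numpy()))
        pids = ex["patient_id"].to_numpy()[order]
        starts = ex["start_day"].to_numpy()[order]
        ends = ex["end_day"].to_numpy()[order]
        regs = ex["regimen"].to_numpy()[order]
        psy = ex["psychotherapy"].to_numpy()[order]

        rows = []
        bounds = np.flatnonzero(np.r_[True, pids[1:] != pids[:-1], True])
        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            pid = pids[b0]
            t0 = self.index_days[pid]
            end_day = first_event.get(pid)
            stop_at = end_day + 1 if end_day is not None else None
            for i in range(b0, b1):
                s, e = int(starts[i]), int(ends[i])
                if stop_at is not None:
                    e = min(e, stop_at)
                if e <= s:
                    continue
                event = stop_at is not None and e == stop_at
                rows.append((pid, s - t0, e - t0, regs[i], bool(event), int(psy[i])))
                if event:
                    break
        return pd.DataFrame(rows, columns=[
            "patient_id", "start", "stop", "regimen", "event", "psychotherapy",
        ])

    def write_tables(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.patients.to_csv(out / "patients.csv", index=False)
        self.visits.to_csv(out / "visits.csv", index=False)
        self.fills.to_csv(out / "fills.csv", index=False)
        self.vocab.to_frame().to_csv(out / "vocabulary.csv", index=False)
        gt = asdict(self.ground_truth)
        gt["confounder_codes"] = self.confounder_codes
        (out / "ground_truth.json").write_text(json.dumps(gt, indent=2))


def generate_population(
    gt: GroundTruth,
    n_patients: int,
    horizon_days: int,
    seed: int,
    *,
    vocab: CodeVocabulary | None = None,
    bd_two_codes_fraction: float = 0.92,
    exclusion_fraction: float = 0.04,
    censor_condition_fraction: float = 0.02,
    antidementia_fill_fraction: float = 0.01,
    confounder_prevalence: float = 0.20,
    psychotherapy_fraction: float = 0.0,
    mean_episode_periods: int = 6,
    background_visit_rate_per_year: float = 6.0,
    hospitalization_rate_per_year: float = 0.30,
    proxy_false_rate: float = 0.01,
    proxy_bundle_range: tuple[int, int] = (3, 8),
) -> SimulatedClaims:
    """Generate a synthetic cohort; deterministic for a fixed seed.

    ``psychotherapy_fraction`` is the per-episode probability that
    psychosocial-intervention procedure codes occur during the episode (and,
    if ``gt.psychotherapy_log_hr`` is non-zero, modify the hazard).
    """
    if n_patients < 1:
        raise ConfigurationError("n_patients must be >= 1")
    if horizon_days < 800:
        raise ConfigurationError("horizon_days must be >= 800 to fit the 1-year lookback")

    if vocab is None:
        vocab = generate_vocabulary(60, 3, seed=gt.seed)
    rng = np.random.default_rng(seed)

    labels = list(gt.regimen_log_hr)
    label_agents = {lab: agents_for_label(lab, vocab) for lab in labels}
    combo = {lab: len(ag) >= 2 for lab, ag in label_agents.items()}
    # keep the drug-free state common when it is a comparator
    base_logit = {lab: (0.6 if lab == "NO_DRUG" else 0.0) for lab in labels}

    conf_names = list(gt.confounder_effects)
    bg_leaves = sorted(
        c for c in vocab.role_codes("background") if all(
            c not in vocab.parents.get(o, ()) for o in vocab.roles
        )
    )
    bg_all = sorted(vocab.role_codes("background"))
    confounder_codes = {name: bg_leaves[-(i + 1)] for i, name in enumerate(conf_names)}
    reserved = set(confounder_codes.values())
    noise_pool = [c for c in bg_all if c not in reserved]
    proxy_pool = sorted(vocab.proxy_codes)
    sh_pool = sorted(vocab.self_harm_codes)
    bd_pool = sorted(vocab.bd_codes)
    mx_pool = sorted(vocab.exclusion_codes)
    cn_pool = sorted(vocab.censoring_codes)
    pt_pool = sorted(vocab.psychotherapy_codes)
    dementia_drug = sorted(vocab.censoring_drug_ids)[0] if vocab.censoring_drug_ids else None

    patients_rows: list[tuple] = []
    visit_rows: list[tuple] = []
    fill_rows: list[tuple] = []
    event_rows: list[tuple] = []
    exposure_rows: list[tuple] = []
    conf_rows: list[list[int]] = []
    index_days: dict[int, int] = {}

    def noise_codes(k: int) -> list[str]:
        idx = rng.integers(0, len(noise_pool), size=k)
        return [noise_pool[j] for j in idx]

    for pid in range(n_patients):
        sex = "M" if rng.random() < 0.45 else "F"
        e_start = int(rng.integers(0, max(1, horizon_days // 6)))
        min_len = 800
        e_len = int(rng.integers(min_len, max(min_len + 1, horizon_days - e_start)))
        e_end = min(e_start + e_len, horizon_days)
        age_at_start = int(rng.integers(12, 71))
        birth_year = YEAR_ZERO + e_start // 365 - age_at_start
        patients_rows.append((pid, sex, birth_year, e_start, e_end))

        x = (rng.random(len(conf_names)) < confounder_prevalence).astype(int)
        conf_rows.append(list(x))
        conf_hazard = float(sum(gt.confounder_effects[n][1] * xi for n, xi in zip(conf_names, x)))
        conf_treat = float(sum(gt.confounder_effects[n][0] * xi for n, xi in zip(conf_names, x)))

        # BD diagnosis stream; the first BD visit is placed after >= 365 days
        # of enrollment so most patients can stage
        bd_first = e_start + 365 + int(rng.integers(0, 90))
        if bd_first >= e_end - 60:
            bd_first = max(e_start + 1, e_end - 60)
        index_days[pid] = bd_first
        bd_days = [bd_first]
        n_extra = (1 if rng.random() < bd_two_codes_fraction else 0) + int(rng.poisson(1.0))
        for _ in range(n_extra):
            bd_days.append(int(rng.integers(bd_first, e_end + 1)))
        for d in bd_days:
            codes = [bd_pool[int(rng.integers(0, len(bd_pool)))]] + noise_codes(int(rng.integers(1, 3)))
            visit_rows.append((pid, "outpatient", d, d, ";".join(sorted(set(codes)))))

        if rng.random() < exclusion_fraction:
            d = int(rng.integers(e_start, e_end + 1))
            visit_rows.append((pid, "outpatient", d, d,
                               ";".join(sorted({mx_pool[0]} | set(noise_codes(1))))))
        if rng.random() < censor_condition_fraction:
            d = int(rng.integers(e_start, e_end + 1))
            visit_rows.append((pid, "outpatient", d, d,
                               ";".join(sorted({cn_pool[int(rng.integers(0, len(cn_pool)))]}
                                               | set(noise_codes(1))))))
        if dementia_drug is not None and rng.random() < antidementia_fill_fraction:
            d = int(rng.integers(e_start, e_end + 1))
            fill_rows.append((pid, dementia_drug, d, 30))

        # treatment episodes tile (bd_first, e_end]; durations are multiples
        # of 30 days so 30-day fills tile episodes exactly
        logits = np.array([base_logit[lab] + (conf_treat if combo[lab] else 0.0) for lab in labels])
        probs = np.exp(logits - logits.max())
        probs /= probs.sum()
        spans: list[tuple[int, int, str, bool]] = []  # [start, end), label, psychotherapy
        if bd_first > e_start:
            spans.append((e_start, bd_first, "NO_DRUG", False))
        t = bd_first
        while t < e_end:
            lab = labels[int(rng.choice(len(labels), p=probs))]
            periods = 1 + int(rng.geometric(1.0 / mean_episode_periods))
            end = min(t + 30 * periods, e_end)
            psy = bool(rng.random() < psychotherapy_fraction)
            spans.append((t, end, lab, psy))
            for agent in label_agents[lab]:
                for fd in range(t, end, 30):
                    fill_rows.append((pid, agent, fd, 30))
            if psy:
                for d in range(t + int(rng.integers(0, 30)), end, 45):
                    visit_rows.append((pid, "outpatient", d, d,
                                       ";".join(sorted({pt_pool[int(rng.integers(0, len(pt_pool)))]}
                                                       | set(noise_codes(1))))))
            t = end

        # true self-harm events: exponential waiting times within each
        # piecewise-constant-hazard span
        for (s, e, lab, psy) in spans:
            exposure_rows.append((pid, s, e, lab, psy, s < bd_first))
            lhr = gt.regimen_log_hr.get(lab, 0.0)
            h = gt.baseline_hazard * float(np.exp(lhr + conf_hazard
                                                  + (gt.psychotherapy_log_hr if psy else 0.0)))
            if h <= 0:
                continue
            t_cur = float(s)
            while True:
                t_cur += rng.exponential(1.0 / h)
                if t_cur >= e:
                    break
                day = int(t_cur)
                was_coded = bool(rng.random() < gt.coding_fraction)
                event_rows.append((pid, day, was_coded, lab))
                setting = "ER" if rng.random() < 0.5 else "inpatient"
                vend = min(day + int(rng.integers(0, 4)), e_end)
                lo, hi = proxy_bundle_range
                k = int(rng.integers(lo, hi + 1))
                pidx = rng.choice(len(proxy_pool), size=min(k, len(proxy_pool)), replace=False)
                codes = {proxy_pool[j] for j in pidx} | set(noise_codes(int(rng.integers(1, 4))))
                if was_coded:
                    codes.add(sh_pool[int(rng.integers(0, len(sh_pool)))])
                visit_rows.append((pid, setting, day, vend, ";".join(sorted(codes))))
                t_cur = day + 1.0

        # ordinary (self-harm-unrelated) hospitalizations: the true-negative
        # class for the imputation model and the hospitalization-censoring
        # mechanism downstream
        n_hosp = int(rng.poisson(hospitalization_rate_per_year * (e_end - e_start) / 365.0))
        for _ in range(n_hosp):
            d = int(rng.integers(e_start, e_end + 1))
            vend = min(d + int(rng.integers(1, 6)), e_end)
            codes = set(noise_codes(int(rng.integers(2, 6))))
            if rng.random() < proxy_false_rate:
                codes.add(proxy_pool[int(rng.integers(0, len(proxy_pool)))])
            setting = "ER" if rng.random() < 0.4 else "inpatient"
            visit_rows.append((pid, setting, d, vend, ";".join(sorted(codes))))

        # background outpatient stream (with occasional false-positive proxy
        # codes so imputation is not trivially separable)
        n_bg = int(rng.poisson(background_visit_rate_per_year * (e_end - e_start) / 365.0))
        for _ in range(n_bg):
            d = int(rng.integers(e_start, e_end + 1))
            codes = set(noise_codes(int(rng.integers(1, 4))))
            if rng.random() < proxy_false_rate:
                codes.add(proxy_pool[int(rng.integers(0, len(proxy_pool)))])
            for name, xi in zip(conf_names, x):
                if xi and rng.random() < 0.5:
                    codes.add(confounder_codes[name])
            visit_rows.append((pid, "outpatient", d, d, ";".join(sorted(codes))))
        # guarantee lookback evidence of each positive confounder
        for name, xi in zip(conf_names, x):
            if xi:
                d = bd_first - int(rng.integers(30, 330))
                if d >= e_start:
                    visit_rows.append((pid, "outpatient", d, d, confounder_codes[name]))

    patients = pd.DataFrame(patients_rows, columns=PATIENT_COLUMNS)
    visits = pd.DataFrame(visit_rows, columns=VISIT_COLUMNS)
    visits["end_day"] = np.minimum(
        visits["end_day"].to_numpy(),
        patients.set_index("patient_id").loc[visits["patient_id"], "enroll_end_day"].to_numpy(),
    )
    visits = visits.sort_values(["patient_id", "start_day", "end_day", "setting"],
                                kind="mergesort").reset_index(drop=True)
    fills = pd.DataFrame(fill_rows, columns=FILL_COLUMNS)
    fills = fills.sort_values(["patient_id", "fill_day", "drug_id"],
                              kind="mergesort").reset_index(drop=True)
    events = pd.DataFrame(event_rows, columns=["patient_id", "true_event_day", "was_coded", "regimen"])
    exposure = pd.DataFrame(
        exposure_rows,
        columns=["patient_id", "start_day", "end_day", "regimen", "psychotherapy", "pre_index"],
    )
    conf_values = pd.DataFrame(conf_rows, columns=conf_names)
    conf_values.insert(0, "patient_id", range(n_patients))

    return SimulatedClaims(
        patients=patients,
        visits=visits,
        fills=fills,
        vocab=vocab,
        ground_truth=gt,
        confounder_codes=confounder_codes,
        confounder_values=conf_values,
        index_days=index_days,
        _events=events,
        _exposure=exposure,
    )
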