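"""End-to-end pipeline orchestration, incidence arithmetic, threshold
sensitivity sweep, and publication-shaped artifacts.

The pipeline runs: generate/load claims tables → meta-visits + coded label →
cross-fitted self-harm probabilities → threshold → staging → exposure
intervals → counting-process rows → Cox models.  Probabilities are computed
once and reused across thresholds; everything downstream of the threshold is
re-run per threshold in the sensitivity sweep.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ShadowharmError
from .metavisit import build_meta_visits, label_coded_selfharm
from .imputation import crossfit_probabilities, apply_threshold, counts_from_scores, classification_metrics
from .staging import locate_sequence, extract_baseline_covariates
from .exposure import (
    build_intervals, collapse_regimens, emit_counting_process, psychotherapy_day_table,
)
from .cox import assemble_model, CoxFit
from .simulate import SimulatedClaims

DEFAULT_THRESHOLDS = (0.20, 0.30, 0.40, 0.50, 0.60, 0.70, 0.80, 0.90, 0.95, 1.0)

DAYS_PER_YEAR = 365.25


# ---------------------------------------------------------------------------
# incidence


@dataclass(frozen=True)
class IncidenceSummary:
    """Events per 100,000 person-years at risk (PYAR)."""

    events: float
    person_years: float
    rate_per_1e5_pyar: float
    rate_rounded: int

    @property
    def annual_incidence(self) -> float:
        return self.events / self.person_years


def incidence(events: float, person_years: float) -> IncidenceSummary:
    """Exact incidence arithmetic; the numerator may be an event count or a
    summed probability over meta-visits."""
    if person_years <= 0:
        raise ConfigurationError("person_years must be positive")
    if events < 0:
        raise ConfigurationError("events must be non-negative")
    rate = events / person_years * 100_000.0
    return IncidenceSummary(
        events=events,
        person_years=person_years,
        rate_per_1e5_pyar=rate,
        rate_rounded=int(round(rate)),
    )


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    threshold: float = 0.5
    k_folds: int = 5
    seed: int = 0
    merge_gap: int = 1
    grace_days: int = 30
    min_intervals: int = 1000
    min_events: int = 5
    min_feature_support: int = 10
    fold_unit: str = "metavisit"
    spline_df: int = 4
    age_reference: float = 50.0
    covariates: tuple = ()          # baseline covariate columns for the models
    reference_regimen: str = "LITHIUM" 
    covariate_codesets: dict = field(default_factory=dict)
    fit_model2: bool = True
    spline_terms: bool = True
    penalizer: float = 0.0


@dataclass
class PipelineResult:
    metavisits: pd.DataFrame
    metrics: dict
    staged: pd.DataFrame
    staging_reasons: pd.DataFrame
    rows: pd.DataFrame
    catalog: object
    fit1: CoxFit | None
    fit2: CoxFit | None
    config: PipelineConfig

    @property
    def n_outcomes(self) -> int:
        return int(self.rows["event"].sum())

    @property
    def person_years(self) -> float:
        return float((self.rows["stop"] - self.rows["start"]).sum() / DAYS_PER_YEAR)


def run_pipeline(sim: SimulatedClaims, config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full analysis on a claims world and fit both Cox models."""
    cfg = config or PipelineConfig()
    mv = build_meta_visits(sim.visits, merge_gap=cfg.merge_gap)
    mv = label_coded_selfharm(mv, sim.vocab)
    mv = crossfit_probabilities(
        mv, sim.patients, sim.vocab,
        k=cfg.k_folds, seed=cfg.seed,
        min_support=cfg.min_feature_support, fold_unit=cfg.fold_unit,
    )
    scored = mv[mv["has_inpatient_or_er"]]
    counts = counts_from_scores(
        scored["coded_selfharm"], scored["selfharm_prob"], cfg.threshold
    )
    metrics = classification_metrics(
        counts, scored["selfharm_prob"], scored["coded_selfharm"]
    )
    return _rerun_from_threshold(sim, mv, cfg, metrics)


def _rerun_from_threshold(
    sim: SimulatedClaims,
    mv: pd.DataFrame,
    cfg: PipelineConfig,
    metrics: dict | None = None,
    strict: bool = True,
) -> PipelineResult:
    """Everything downstream of the (already computed) probabilities.

    With ``strict=False`` (the sensitivity sweep) a threshold whose model
    cannot be fitted — too few events, degenerate risk sets — yields
    ``fit1 = fit2 = None`` instead of an error.
    """
    outcome = apply_threshold(mv, cfg.threshold)
    staged, reasons = locate_sequence(
        mv, sim.patients, sim.fills, sim.vocab, outcome=outcome
    )
    covsets = {
        name: frozenset({code})
        for name, code in sim.confounder_codes.items()
    }
    covsets.update(cfg.covariate_codesets)
    baseline = extract_baseline_covariates(
        staged, mv, sim.fills, sim.patients, sim.vocab, covariate_codesets=covsets
    )
    intervals = build_intervals(staged, sim.fills, sim.vocab, grace_days=cfg.grace_days)
    intervals, catalog = collapse_regimens(
        intervals, sim.vocab,
        min_intervals=cfg.min_intervals, min_events=cfg.min_events,
        keep=frozenset({cfg.reference_regimen}),
    )
    psy = psychotherapy_day_table(sim.visits, sim.vocab)
    rows = emit_counting_process(
        staged, intervals, sim.fills, sim.vocab,
        psychotherapy_days=psy, baseline_covariates=baseline,
    )

    fit1 = fit2 = None
    if rows["event"].sum() > 0:
        model_kwargs = dict(
            covariates=list(cfg.covariates),
            reference_regimen=cfg.reference_regimen,
            spline_df=cfg.spline_df,
            age_reference=cfg.age_reference,
            spline_age=cfg.spline_terms,
            spline_prior_drugs=cfg.spline_terms,
            penalizer=cfg.penalizer,
        )
        try:
            fit1 = assemble_model(rows, "model1", **model_kwargs)
            if cfg.fit_model2:
                fit2 = assemble_model(rows, "model2", **model_kwargs)
        except (ShadowharmError, np.linalg.LinAlgError):
            if strict:
                raise
            fit1 = fit2 = None
    return PipelineResult(
        metavisits=mv, metrics=metrics or {}, staged=staged, staging_reasons=reasons,
        rows=rows, catalog=catalog, fit1=fit1, fit2=fit2, config=cfg,
    )


# ---------------------------------------------------------------------------
# threshold sweep


def threshold_sweep(
    sim: SimulatedClaims,
    config: PipelineConfig | None = None,
    thresholds=DEFAULT_THRESHOLDS,
) -> dict[float, dict]:
    """Re-run staging/exposure/fitting at each probability threshold.

    Probabilities are computed once.  Returns, per threshold: outcome count,
    staged-patient count, retained regimen list, and the hazard-ratio table
    (or ``feasible=False`` when a threshold yields no events).
    """
    cfg = config or PipelineConfig()
    base = run_pipeline(sim, cfg)
    mv = base.metavisits
    out: dict[float, dict] = {}
    for t in thresholds:
        cfg_t = PipelineConfig(**{**cfg.__dict__, "threshold": t})
        res = _rerun_from_threshold(sim, mv, cfg_t, base.metrics, strict=False)
        entry: dict = {
            "outcome_count": res.n_outcomes,
            "staged_count": len(res.staged),
            "retained_regimens": res.catalog.retained,
            "feasible": res.fit1 is not None,
        }
        if res.fit1 is not None:
            entry["hr_table"] = res.fit1.summary
        out[t] = entry
    counts = [out[t]["outcome_count"] for t in sorted(out)]
    if any(later > earlier for later, earlier in zip(counts[1:], counts[:-1])):
        raise AssertionError("outcome counts must be non-increasing in the threshold")
    return out


# ---------------------------------------------------------------------------
# artifacts


def render_report(result: PipelineResult, outdir: str | Path,
                  sweep: dict | None = None, figures: bool = False) -> dict:
    """Write publication-shaped CSV tables plus a JSON run manifest.

    Re-rendering from the same artifacts is byte-identical.  Figures
    (forest/sensitivity panels, spline curves) are written only on request.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "seed": result.config.seed}

    def write(df: pd.DataFrame, name: str) -> None:
        df.to_csv(out / name, index=False, float_format="%.10g")
        manifest["stages"][name] = {"rows": int(len(df))}

    write(result.metavisits, "metavisits.csv")
    write(result.staged, "staged.csv")
    write(result.rows, "rows.csv")
    write(result.catalog.counts, "catalog.csv")
    if result.fit1 is not None:
        write(_hr_table(result.fit1, result.rows), "model1_hr.csv")
    if result.fit2 is not None:
        write(_hr_table(result.fit2, result.rows), "model2_hr.csv")
    if result.metrics:
        (out / "metrics.json").write_text(json.dumps(
            {k: (None if isinstance(v, float) and math.isnan(v) else v)
             for k, v in result.metrics.items()}, indent=2))
    if sweep is not None:
        rows = []
        for t, entry in sorted(sweep.items()):
            rows.append({
                "threshold": t,
                "outcome_count": entry["outcome_count"],
                "staged_count": entry["staged_count"],
                "n_retained_regimens": len(entry["retained_regimens"]),
                "feasible": entry["feasible"],
            })
            if "hr_table" in entry:  # forest-plot-ready table per threshold
                tag = f"{t:.2f}".replace(".", "")
                write(entry["hr_table"], f"sweep_hr_t{tag}.csv")
        write(pd.DataFrame(rows), "sweep.csv")
    if figures and result.fit1 is not None:
        _write_figures(result, out)

    cfg_json = json.dumps(result.config.__dict__, sort_keys=True, default=str)
    manifest["config"] = json.loads(cfg_json)
    manifest["config_hash"] = hashlib.sha256(cfg_json.encode()).hexdigest()[:16]
    manifest["versions"] = _versions()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _hr_table(fit: CoxFit, rows: pd.DataFrame | None = None) -> pd.DataFrame:
    t = fit.summary.rename(columns={
        "term": "Covariate", "hr": "HR", "lower95": "Lower 95%",
        "upper95": "Upper 95%", "p": "P value",
    })
    t = t[["Covariate", "HR", "Lower 95%", "Upper 95%", "P value"]]
    if rows is not None:
        # per-regimen tallies for the treatment terms
        grp = rows.groupby("regimen")
        pa = grp["patient_id"].nunique()
        iv = grp.size()
        ev = grp["event"].sum()

        def tally(col, series):
            vals = []
            for term in t["Covariate"]:
                if term.startswith("regimen[") and term.endswith("]"):
                    vals.append(int(series.get(term[8:-1], 0)))
                else:
                    vals.append(pd.NA)
            return vals

        t = t.assign(Patients=tally("p", pa), Intervals=tally("i", iv),
                     Events=tally("e", ev))
    return t


def _versions() -> dict:
    import lifelines
    import sklearn
    import scipy

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "lifelines": lifelines.__version__,
        "sklearn": sklearn.__version__,
    }


def _write_figures(result: PipelineResult, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fit = result.fit1
    reg = fit.summary[fit.summary["term"].str.startswith("regimen[")]
    fig, ax = plt.subplots(figsize=(6, max(2, 0.3 * len(reg))))
    y = np.arange(len(reg))
    ax.errorbar(reg["hr"], y,
                xerr=[reg["hr"] - reg["lower95"], reg["upper95"] - reg["hr"]],
                fmt="o", ms=3, lw=1)
    ax.axvline(1.0, color="grey", lw=0.8)
    ax.set_yticks(y)
    ax.set_yticklabels([t[8:-1] for t in reg["term"]], fontsize=7)
    ax.set_xscale("log")
    ax.set_xlabel("hazard ratio vs lithium")
    fig.tight_layout()
    fig.savefig(out / "forest_model1.png", dpi=120)
    plt.close(fig)

    for name, term in fit.spline_reports.items():
        col = "age_at_index" if name == "age" else "prior_unique_bd_drugs"
        vals = result.rows[col]
        grid = np.linspace(vals.min(), vals.max(), 80)
        curve = term.curve(fit, grid)
        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.plot(curve["x"], curve["hr"])
        ax.fill_between(curve["x"], curve["lower95"], curve["upper95"], alpha=0.2)
        ax.axhline(1.0, color="grey", lw=0.8)
        ax.set_yscale("log")
        ax.set_xlabel(col)
        ax.set_ylabel("hazard ratio")
        fig.tight_layout()
        fig.savefig(out / f"spline_{name}.png", dpi=120)
        plt.close(fig)
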