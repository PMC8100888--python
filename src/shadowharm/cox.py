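"""Time-varying proportional-hazards models, spline terms, and the
Benjamini–Yekutieli correction.

Model 1 compares every retained regimen to lithium monotherapy (regimen
one-hot, psychotherapy as a binary time-varying covariate, natural-spline
terms for age and the number of previously tried study drugs, plus selected
baseline covariates).  Model 2 collapses treatment into four mutually
exclusive time-varying categories — pharmacotherapy alone, psychotherapy
alone, both, or neither ("no treatment", the reference).

Fitting maximizes the Efron-tie partial likelihood over counting-process
(start, stop] rows via :class:`lifelines.CoxTimeVaryingFitter`.  Confidence
intervals are Wald: exp(coefficient ± 1.96·SE).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from patsy import dmatrix, build_design_matrices
from scipy import stats
from lifelines import CoxTimeVaryingFitter
from lifelines.exceptions import ConvergenceError

from .errors import ConfigurationError, DataError
from .exposure import NO_DRUG

Z95 = 1.959963984540054


# ---------------------------------------------------------------------------
# spline terms


class NaturalSplineTerm:
    """Natural cubic spline with a separable linear component.

    The basis is a patsy ``cr()`` natural cubic spline with ``df`` degrees of
    freedom and interior knots at quantiles of the training values.  For
    reporting, the term is decomposed into a pure linear column
    (``{name}_lin`` = x − reference) plus nonlinear columns residualized
    against [1, x], so the fit exposes a linear-component hazard ratio and a
    joint Wald p-value for the nonlinear components, and the fitted curve is
    anchored at HR = 1 (CI width 0) at the reference value.
    """

    def __init__(self, values, df: int = 4, reference_value: float = 0.0, name: str = "x"):
        values = np.asarray(values, float)
        if df < 2:
            raise ConfigurationError("spline df must be >= 2")
        self.df = df
        self.reference_value = float(reference_value)
        self.name = name
        distinct = np.unique(values)
        if distinct.size < df + 2:
            warnings.warn(
                f"{name}: only {distinct.size} distinct values; degrading to a linear term",
                stacklevel=2,
            )
            self._design_info = None
            self._proj = None
            return
        try:
            dm = dmatrix("cr(x, df=df) - 1", {"x": values, "df": df})
        except Exception:  # knot placement fails on heavily discrete data
            warnings.warn(
                f"{name}: could not place {df}-df spline knots; degrading to a linear term",
                stacklevel=2,
            )
            self._design_info = None
            self._proj = None
            return
        self._design_info = dm.design_info
        B = np.asarray(dm)
        A = np.column_stack([np.ones_like(values), values])
        # fixed affine map removing the constant+linear span from the basis;
        # the residual space has rank df-2, so project onto its principal
        # directions to get well-conditioned nonlinear columns
        self._proj, *_ = np.linalg.lstsq(A, B, rcond=None)
        resid = B - A @ self._proj
        _, s, Vt = np.linalg.svd(resid, full_matrices=False)
        keep = s > s[0] * 1e-8
        self._V = Vt[keep].T
        self._scale = s[keep] / np.sqrt(len(values))

    @property
    def column_names(self) -> list[str]:
        cols = [f"{self.name}_lin"]
        if self._design_info is not None:
            cols += [f"{self.name}_nl{i}" for i in range(self._V.shape[1])]
        return cols

    @property
    def nonlinear_names(self) -> list[str]:
        return self.column_names[1:]

    def columns(self, values) -> pd.DataFrame:
        values = np.asarray(values, float)
        out = {f"{self.name}_lin": values - self.reference_value}
        if self._design_info is not None:
            (B,) = build_design_matrices([self._design_info], {"x": values, "df": self.df})
            resid = np.asarray(B) - np.column_stack(
                [np.ones_like(values), values]
            ) @ self._proj
            nl = (resid @ self._V) / self._scale
            for i in range(nl.shape[1]):
                out[f"{self.name}_nl{i}"] = nl[:, i]
        return pd.DataFrame(out)

    def curve(self, fit: "CoxFit", grid) -> pd.DataFrame:
        """HR(x) versus the reference value with pointwise Wald 95% CI."""
        grid = np.asarray(grid, float)
        cols = self.column_names
        C = self.columns(grid)[cols].to_numpy()
        Cref = self.columns([self.reference_value])[cols].to_numpy()
        D = C - Cref
        beta = fit.params.loc[cols].to_numpy()
        V = fit.covariance.loc[cols, cols].to_numpy()
        log_hr = D @ beta
        se = np.sqrt(np.einsum("ij,jk,ik->i", D, V, D))
        return pd.DataFrame({
            "x": grid,
            "hr": np.exp(log_hr),
            "lower95": np.exp(log_hr - Z95 * se),
            "upper95": np.exp(log_hr + Z95 * se),
        })


# ---------------------------------------------------------------------------
# fitting


@dataclass
class CoxFit:
    """Per-term estimates plus bookkeeping for spline reporting."""

    summary: pd.DataFrame          # term, coef, se, hr, lower95, upper95, p
    log_likelihood: float
    null_log_likelihood: float
    converged: bool
    covariance: pd.DataFrame
    n_rows: int
    n_events: int
    spline_reports: dict = field(default_factory=dict)
    dropped_regimens: list = field(default_factory=list)

    @property
    def params(self) -> pd.Series:
        return self.summary.set_index("term")["coef"]

    def wald_joint_p(self, terms: list[str]) -> float:
        """Joint Wald chi-square p-value for a set of coefficients."""
        beta = self.params.loc[terms].to_numpy()
        V = self.covariance.loc[terms, terms].to_numpy()
        stat = float(beta @ np.linalg.solve(V, beta))
        return float(stats.chi2.sf(stat, df=len(terms)))


def fit_cox(
    rows: pd.DataFrame,
    terms: list[str],
    *,
    id_col: str = "patient_id",
    start_col: str = "start",
    stop_col: str = "stop",
    event_col: str = "event",
    penalizer: float = 0.0,
    max_steps: int = 100,
    tol: float = 1e-9,
) -> CoxFit:
    """Maximize the partial likelihood over counting-process rows.

    Efron tie handling; deterministic for fixed input.  A term constant
    across all rows is reported as a non-identifiability error naming the
    term; separation surfaces as a convergence error (a small ``penalizer``
    is the documented fallback).
    """
    if rows[event_col].sum() < 1:
        raise DataError("no events in the data")
    for t in terms:
        if t not in rows.columns:
            raise ConfigurationError(f"unknown term {t!r}")
        if rows[t].nunique() <= 1:
            raise DataError(f"term {t!r} is constant across all rows (non-identifiable)")
    df = rows[[id_col, start_col, stop_col, event_col] + list(terms)].copy()
    df[event_col] = df[event_col].astype(bool)
    ctv = CoxTimeVaryingFitter(penalizer=penalizer)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ctv.fit(
                df,
                id_col=id_col,
                start_col=start_col,
                stop_col=stop_col,
                event_col=event_col,
                show_progress=False,
                fit_options={"max_steps": max_steps, "precision": tol},
            )
    except ConvergenceError as exc:
        raise DataError(
            f"partial-likelihood maximization failed (possible separation): {exc}"
        ) from exc

    coef = ctv.params_
    se = ctv.standard_errors_
    summary = pd.DataFrame({
        "term": coef.index,
        "coef": coef.to_numpy(),
        "se": se.to_numpy(),
    })
    summary["hr"] = np.exp(summary["coef"])
    summary["lower95"] = np.exp(summary["coef"] - Z95 * summary["se"])
    summary["upper95"] = np.exp(summary["coef"] + Z95 * summary["se"])
    z = summary["coef"] / summary["se"]
    summary["p"] = 2.0 * stats.norm.sf(np.abs(z))
    covariance = pd.DataFrame(
        np.asarray(ctv.variance_matrix_), index=coef.index, columns=coef.index
    )
    return CoxFit(
        summary=summary.reset_index(drop=True),
        log_likelihood=float(ctv.log_likelihood_),
        null_log_likelihood=float(getattr(ctv, "_log_likelihood_null", np.nan)),
        converged=True,
        covariance=covariance,
        n_rows=len(df),
        n_events=int(df[event_col].sum()),
    )


# ---------------------------------------------------------------------------
# multiple testing


def benjamini_yekutieli(pvalues, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Step-up FDR control under arbitrary dependence.

    Rejects the k smallest p-values where k is the largest index with
    p(k) <= k·q / (m·c(m)), c(m) = sum_{i<=m} 1/i.  Returns a boolean mask in
    the input order and the realized p-value cutoff (0.0 when nothing is
    rejected).
    """
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return np.zeros(0, bool), 0.0
    if np.any((p < 0) | (p > 1)):
        raise ConfigurationError("p-values must lie in [0, 1]")
    m = p.size
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    thresholds = np.arange(1, m + 1) * q / (m * c_m)
    passing = np.nonzero(sorted_p <= thresholds)[0]
    mask = np.zeros(m, bool)
    if passing.size == 0:
        return mask, 0.0
    k = passing.max()
    mask[order[: k + 1]] = True
    return mask, float(sorted_p[k])


# ---------------------------------------------------------------------------
# model assembly


MODEL2_CATEGORIES = ("pharm_only", "psy_only", "pharm_psy")  # reference: no treatment


def model2_category(regimen: str, psychotherapy: int) -> str:
    drug = regimen != NO_DRUG
    psy = bool(psychotherapy)
    if drug and psy:
        return "pharm_psy"
    if drug:
        return "pharm_only"
    if psy:
        return "psy_only"
    return "no_treatment"


def assemble_model(
    rows: pd.DataFrame,
    which: str,
    covariates: list[str] | None = None,
    *,
    reference_regimen: str = "LITHIUM",
    spline_age: bool = True,
    spline_prior_drugs: bool = True,
    spline_df: int = 4,
    age_reference: float = 50.0,
    prior_drugs_reference: float = 0.0,
    penalizer: float = 0.0,
) -> CoxFit:
    """Fit model 1 (regimens vs lithium + psychotherapy) or model 2
    (4-category treatment vs no treatment); identical covariate/spline sets.

    Regimens with zero events are dropped from model 1 with a log entry
    (their intervals are excluded), mirroring removal for lack of events.
    Output is sorted by hazard ratio, descending.
    """
    covariates = list(covariates or [])
    rows = rows.reset_index(drop=True).copy()
    dropped: list[str] = []

    if which == "model1":
        if reference_regimen not in set(rows["regimen"]):
            raise ConfigurationError(
                f"reference regimen {reference_regimen!r} has no intervals; "
                "retain it during collapsing or choose another reference"
            )
        ev = rows.groupby("regimen")["event"].sum()
        dead = sorted(set(ev.index[ev == 0]) - {reference_regimen})
        if dead:
            dropped = dead
            rows = rows[~rows["regimen"].isin(dead)].reset_index(drop=True)
        regimens = sorted(set(rows["regimen"]) - {reference_regimen})
        terms = []
        for r in regimens:
            col = f"regimen[{r}]"
            rows[col] = (rows["regimen"] == r).astype(float)
            terms.append(col)
        if rows["psychotherapy"].nunique() > 1:  # worlds without psychotherapy
            terms.append("psychotherapy")
    elif which == "model2":
        cat = [model2_category(r, p) for r, p in zip(rows["regimen"], rows["psychotherapy"])]
        rows["treatment_category"] = cat
        if "no_treatment" not in set(cat):
            raise ConfigurationError("model 2 reference category 'no treatment' is empty")
        terms = []
        for c in MODEL2_CATEGORIES:
            if c not in set(cat):  # category absent from this world
                continue
            col = f"treatment[{c}]"
            rows[col] = (rows["treatment_category"] == c).astype(float)
            terms.append(col)
    else:
        raise ConfigurationError(f"unknown model {which!r}")

    spline_reports: dict = {}
    if spline_age and "age_at_index" in rows.columns:
        term = NaturalSplineTerm(rows["age_at_index"], df=spline_df,
                                 reference_value=age_reference, name="age")
        rows = pd.concat([rows, term.columns(rows["age_at_index"])], axis=1)
        terms += term.column_names
        spline_reports["age"] = term
    if spline_prior_drugs and "prior_unique_bd_drugs" in rows.columns:
        term = NaturalSplineTerm(rows["prior_unique_bd_drugs"], df=spline_df,
                                 reference_value=prior_drugs_reference, name="prior_drugs")
        rows = pd.concat([rows, term.columns(rows["prior_unique_bd_drugs"])], axis=1)
        terms += term.column_names
        spline_reports["prior_drugs"] = term
    terms += covariates

    fit = fit_cox(rows, terms, penalizer=penalizer)
    fit.spline_reports = spline_reports
    fit.dropped_regimens = dropped
    fit.summary = fit.summary.sort_values("hr", ascending=False).reset_index(drop=True)
    return fit
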