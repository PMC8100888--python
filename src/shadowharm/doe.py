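"""Fractional-factorial screening of pretreatment covariates.

With dozens of treatment comparators and time-varying exposure, propensity
matching is impractical; instead, the impact of each candidate pretreatment
covariate on the *treatment* coefficient estimates is screened directly.
Covariate inclusion/exclusion patterns follow a two-level resolution IV
fractional factorial design (main effects unconfounded with two-factor
interactions), built by folding over a saturated resolution III design and
appending an all-exclude reference run.  One Cox model is fitted per run
(treatment terms always included); the treatment-coefficient matrix Y
(runs × treatments) is then regressed column-by-column on the ±1 design
matrix X, and a covariate's importance is the number of treatment
coefficients it shifts significantly.  A per-run L2 distance of the
coefficient vector from the reference run's vector (Y′) regressed on X ranks
the largest overall bias sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConfigurationError, DataError
from .cox import fit_cox


# ---------------------------------------------------------------------------
# design construction


@dataclass
class FactorialDesign:
    """±1 run matrix (+1 include, −1 exclude) with an appended reference run."""

    X: np.ndarray                 # (n_runs, n_covariates), includes reference run
    resolution: int
    reference_run_index: int

    @property
    def n_runs(self) -> int:
        return self.X.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.X.shape[1]

    @property
    def factorial_rows(self) -> np.ndarray:
        return np.delete(self.X, self.reference_run_index, axis=0)


def _saturated_res3(m: int) -> np.ndarray:
    """Saturated two-level resolution III design: m runs × (m−1) columns.

    Full factorial on k = log2(m) base factors; the remaining columns are the
    elementwise products of every non-empty factor subset (binary counting
    order), i.e. the nonconstant rows of the order-m Hadamard matrix.
    """
    k = int(np.log2(m))
    base = np.ones((m, k), dtype=int)
    for j in range(k):
        base[:, j] = np.where((np.arange(m) >> j) & 1, 1, -1)
    cols = []
    for word in range(1, m):
        col = np.ones(m, dtype=int)
        for j in range(k):
            if (word >> j) & 1:
                col = col * base[:, j]
        cols.append(col)
    return np.column_stack(cols)


def build_design(n_covariates: int, n_base_runs: int) -> FactorialDesign:
    """Resolution IV design by fold-over, plus the all-exclude reference run.

    ``n_base_runs`` must be a power of two; capacity is
    ``n_covariates <= n_base_runs/2 − 1`` (a saturated resolution III design
    on ``n_base_runs/2`` runs is folded over, doubling the runs and raising
    the resolution to IV).  The aliasing property — main-effect columns
    orthogonal to all two-column elementwise products — is verified
    programmatically on the factorial rows.
    """
    if n_base_runs < 4 or (n_base_runs & (n_base_runs - 1)) != 0:
        raise ConfigurationError("n_base_runs must be a power of two >= 4")
    m = n_base_runs // 2
    if n_covariates > m - 1:
        need = 2
        while need // 2 - 1 < n_covariates:
            need *= 2
        raise ConfigurationError(
            f"{n_covariates} covariates exceed the fold-over capacity of "
            f"{n_base_runs} runs; need n_base_runs >= {need}"
        )
    H = _saturated_res3(m)[:, :n_covariates]
    X = np.vstack([H, -H])
    reference = -np.ones((1, n_covariates), dtype=int)
    X = np.vstack([X, reference])
    design = FactorialDesign(X=X, resolution=4, reference_run_index=X.shape[0] - 1)

    F = design.factorial_rows
    rng = np.random.default_rng(0)
    n = F.shape[1]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    if len(pairs) > 2000:
        idx = rng.choice(len(pairs), size=2000, replace=False)
        pairs = [pairs[i] for i in idx]
    # orthogonality check: every main-effect column ⊥ every (sampled)
    # two-column elementwise product
    for i, j in pairs:
        prod = F[:, i] * F[:, j]
        if np.any(F.T @ prod != 0):
            raise ConfigurationError("fold-over construction failed the resolution IV check")
    return design


# ---------------------------------------------------------------------------
# factorial runs


@dataclass
class DOEResult:
    Y: np.ndarray                              # (n_runs, n_treatments)
    treatment_terms: list
    failed_runs: list = field(default_factory=list)
    significance_counts: np.ndarray | None = None
    min_p: np.ndarray | None = None
    pvalues: np.ndarray | None = None          # (n_covariates, n_treatments)
    discarded: list = field(default_factory=list)
    elimination_trace: list = field(default_factory=list)
    final_covariates: list = field(default_factory=list)
    yprime: np.ndarray | None = None
    bias_regression: pd.DataFrame | None = None


def run_factorial(
    rows: pd.DataFrame,
    design: FactorialDesign,
    treatment_terms: list[str],
    covariate_names: list[str],
    *,
    max_failed_fraction: float = 0.05,
    penalizer: float = 0.0,
) -> DOEResult:
    """One Cox fit per design run; Y[run, i] = coefficient of treatment i.

    Treatment terms are always included; covariate j enters iff
    X[run, j] = +1.  Failed fits are recorded and their rows masked (NaN);
    more than ``max_failed_fraction`` failures is a hard error.
    """
    if len(covariate_names) != design.n_covariates:
        raise ConfigurationError("covariate list does not match design width")
    Y = np.full((design.n_runs, len(treatment_terms)), np.nan)
    failed: list[int] = []
    for r in range(design.n_runs):
        included = [c for c, x in zip(covariate_names, design.X[r]) if x == 1]
        try:
            fit = fit_cox(rows, treatment_terms + included, penalizer=penalizer)
            Y[r] = fit.params.loc[treatment_terms].to_numpy()
        except Exception:
            failed.append(r)
    if len(failed) > max_failed_fraction * design.n_runs:
        raise DataError(
            f"{len(failed)}/{design.n_runs} factorial runs failed; design inadequate at this scale"
        )
    return DOEResult(Y=Y, treatment_terms=list(treatment_terms), failed_runs=failed)


def score_covariates(
    result: DOEResult,
    design: FactorialDesign,
    alpha: float | None = None,
) -> DOEResult:
    """OLS of every treatment-coefficient column on the ±1 design matrix.

    The significance count of covariate j is the number of treatment columns
    where its OLS coefficient has p < alpha (default 0.05 / n_treatments);
    covariates never significant are discarded.
    """
    Y, X = result.Y, design.X.astype(float)
    ok = ~np.isnan(Y).any(axis=1)
    Y, X = Y[ok], X[ok]
    n_treat = Y.shape[1]
    if alpha is None:
        alpha = 0.05 / n_treat
    Xc = sm.add_constant(X)
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise DataError("rank-deficient design matrix (design violated)")
    pmat = np.empty((design.n_covariates, n_treat))
    for i in range(n_treat):
        ols = sm.OLS(Y[:, i], Xc).fit()
        pmat[:, i] = ols.pvalues[1:]
    counts = (pmat < alpha).sum(axis=1)
    result.pvalues = pmat
    result.significance_counts = counts
    result.min_p = pmat.min(axis=1)
    result.discarded = [j for j in range(design.n_covariates) if counts[j] == 0]
    return result


def backward_eliminate(
    rows: pd.DataFrame,
    result: DOEResult,
    covariate_names: list[str],
    *,
    stop_p: float = 1e-3,
    floor: int = 0,
    penalizer: float = 0.0,
) -> DOEResult:
    """Backward elimination over the covariates that survived scoring.

    Candidates are ordered by (significance count ascending, minimum
    impact-regression p descending); the full Cox model is refitted after
    each drop.  Elimination stops when the next candidate's minimum p across
    the treatment-impact regressions is below ``stop_p`` ("highly
    significant"), or when only ``floor`` candidates remain.
    """
    if result.significance_counts is None:
        raise DataError("score_covariates must run before backward elimination")
    counts, min_p = result.significance_counts, result.min_p
    current = [j for j in range(len(covariate_names)) if j not in result.discarded]
    order = sorted(current, key=lambda j: (counts[j], -min_p[j]))
    trace: list[dict] = []
    for j in order:
        if len(current) <= floor:
            break
        if min_p[j] < stop_p:
            trace.append({
                "covariate": covariate_names[j], "action": "stop",
                "count": int(counts[j]), "min_p": float(min_p[j]),
            })
            break
        current = [c for c in current if c != j]
        entry = {
            "covariate": covariate_names[j], "action": "drop",
            "count": int(counts[j]), "min_p": float(min_p[j]),
        }
        if current:
            fit = fit_cox(
                rows,
                result.treatment_terms + [covariate_names[c] for c in current],
                penalizer=penalizer,
            )
            entry["log_likelihood"] = fit.log_likelihood
        trace.append(entry)
    result.elimination_trace = trace
    result.final_covariates = [covariate_names[j] for j in current]
    return result


def bias_norm(result: DOEResult, design: FactorialDesign) -> DOEResult:
    """Per-run Euclidean distance of the coefficient vector from the
    reference run's vector (Y′), regressed on the design matrix to rank the
    covariates whose inclusion most shifts the treatment estimates."""
    Y = result.Y
    ref = Y[design.reference_run_index]
    yprime = np.linalg.norm(Y - ref, axis=1)
    result.yprime = yprime
    ok = ~np.isnan(yprime)
    Xc = sm.add_constant(design.X.astype(float)[ok])
    ols = sm.OLS(yprime[ok], Xc).fit()
    result.bias_regression = pd.DataFrame({
        "covariate_index": np.arange(design.n_covariates),
        "coef": ols.params[1:],
        "p": ols.pvalues[1:],
    }).sort_values("p", kind="mergesort").reset_index(drop=True)
    return result
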