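"""Weekly linear models of log CDR on dominant-coded genotype indicators.

The base model regresses each week's per-patient median log CDR on the two
major-effect indicators (donor and recipient CYP3A5 rs776746 expresser
status).  Minor-effect loci enter by forward selection on top of the
always-included base, with an alpha-to-enter of 0.05; within the paired-EM
and paired-PM strata single minor loci are fitted on their own.  Fits are
ordinary least squares (statsmodels) on complete cases; the headline
summary is the adjusted R², 1 - (1 - R²)(n - 1)/(n - p - 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .types import ValidationError


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Adjusted R² for n observations and p predictors (no intercept counted)."""
    if n <= p + 1:
        raise ValidationError(f"n={n} too small for {p} predictors")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


@dataclass
class RegressionFit:
    """One weekly OLS fit."""

    week: int
    predictors: tuple[str, ...]
    coef: dict[str, float]
    stderr: dict[str, float]
    pvalues: dict[str, float]
    r2: float
    adj_r2: float
    n: int
    n_dropped: int = 0
    added: tuple[str, ...] = field(default_factory=tuple)  # forward-selected on top of base

    def __post_init__(self) -> None:
        if self.adj_r2 > self.r2 + 1e-12:
            raise ValidationError("adjusted R² exceeds R²")


def fit_week_model(y: pd.Series, X: pd.DataFrame, week: int = 0) -> RegressionFit:
    """OLS of one week's log CDR on a design of genotype indicators.

    Patients missing the response or any predictor are dropped (complete
    cases; the dropped count is reported).  A rank-deficient design is
    fatal, naming the collinear columns.
    """
    data = pd.concat([y.rename("__y"), X], axis=1, join="inner")
    n_total = len(data)
    data = data.dropna()
    n = len(data)
    p = X.shape[1]
    if n <= p + 1:
        raise ValidationError(f"n={n} complete cases too few for {p} predictors")
    design = sm.add_constant(data[list(X.columns)], has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        bad = _collinear_columns(design)
        raise ValidationError(f"design is rank-deficient; collinear columns: {bad}")
    fit = sm.OLS(data["__y"], design).fit()
    names = tuple(X.columns)
    return RegressionFit(
        week=week,
        predictors=names,
        coef={k: float(fit.params[k]) for k in names},
        stderr={k: float(fit.bse[k]) for k in names},
        pvalues={k: float(fit.pvalues[k]) for k in names},
        r2=float(fit.rsquared),
        adj_r2=float(fit.rsquared_adj),
        n=n,
        n_dropped=n_total - n,
    )


def _collinear_columns(design: pd.DataFrame) -> list[str]:
    cols = list(design.columns)
    kept: list[str] = []
    bad: list[str] = []
    for c in cols:
        trial = design[kept + [c]].to_numpy()
        if np.linalg.matrix_rank(trial) == len(kept) + 1:
            kept.append(c)
        else:
            bad.append(c)
    return bad


def select_optimal_model(
    y: pd.Series,
    base: pd.DataFrame,
    candidates: pd.DataFrame,
    week: int = 0,
    alpha_to_enter: float = 0.05,
) -> RegressionFit:
    """Forward selection of minor loci on top of an always-included base.

    At each step the candidate with the smallest coefficient p in the
    current model is added if that p is below ``alpha_to_enter``; selection
    stops when no candidate qualifies.  Base predictors are never dropped.
    Candidates collinear with the current design are skipped, so of two
    near-duplicate loci at most one can enter.
    """
    selected: list[str] = []
    remaining = list(candidates.columns)
    current = fit_week_model(y, base, week=week)
    while remaining:
        best_name, best_p, best_fit = None, np.inf, None
        for name in remaining:
            X = pd.concat([base, candidates[selected + [name]]], axis=1)
            try:
                trial = fit_week_model(y, X, week=week)
            except ValidationError:
                continue
            p = trial.pvalues[name]
            if p < best_p:
                best_name, best_p, best_fit = name, p, trial
        if best_name is None or best_p >= alpha_to_enter:
            break
        selected.append(best_name)
        remaining.remove(best_name)
        current = best_fit
    current.added = tuple(selected)
    return current


def stratified_model(
    y: pd.Series, predictor: pd.Series, week: int = 0, min_n: int = 10
) -> RegressionFit:
    """Single-predictor OLS within a paired-EIP stratum.

    Strata below ``min_n`` complete cases cannot support even a one-
    predictor fit and are refused rather than reported with a meaningless
    R².
    """
    data = pd.concat([y.rename("__y"), predictor], axis=1, join="inner").dropna()
    if len(data) < min_n:
        raise ValidationError(
            f"stratum has {len(data)} complete cases; fewer than {min_n}, fit refused"
        )
    return fit_week_model(y, predictor.to_frame(), week=week)


def fits_frame(fits: list[RegressionFit], stratum: str = "all") -> pd.DataFrame:
    """Flat summary table of weekly fits (one row per fit)."""
    rows = []
    for f in fits:
        terms = " + ".join(f"{k} ({f.pvalues[k]:.3g})" for k in f.predictors)
        rows.append(
            {
                "stratum": stratum,
                "week": f.week,
                "model": terms if terms else "NONE",
                "added": " + ".join(f.added) if f.added else "NONE",
                "adj_r2_pct": round(100 * f.adj_r2, 2),
                "n": f.n,
            }
        )
    return pd.DataFrame(rows)
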