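"""Cognitive composites, group contrasts, and VOI regression modelling.

Implements the cohort-level statistical stage: neuropsychological composite
z-scores against a normal-control reference, ANCOVA group contrasts with
demographic covariates, Cohen's d with the pooled-SD convention, ordinary
least squares with backwards elimination of non-significant predictors, and
the two-stage lobar-then-subregion VOI screening strategy.  Standardized
coefficients are obtained by z-scoring outcome and predictors before the
fit; per-predictor R-squared is the squared partial correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import CollinearityError, InputError, UndefinedEffectError

__all__ = [
    "EffectSize", "RegressionResult", "StepwiseResult",
    "composite_score", "cohens_d_pooled", "ancova_group_difference",
    "backwards_elimination", "stepwise_voi_analysis", "partial_regression_data",
    "DEFAULT_DOMAIN_MAP", "DEFAULT_ORIENTATION",
]

# Cognitive battery: domain -> tests; orientation -1 where a higher raw
# score means worse performance (times, error counts), so that every
# composite is oriented higher = better.
DEFAULT_DOMAIN_MAP: dict[str, tuple[str, ...]] = {
    "executive": ("fas_fluency", "wcst_categories", "wcst_perseverative_errors"),
    "speed": ("trails_a_time",),
    "memory": ("cvlt_total", "wms_visual_reproduction", "drs_memory"),
}
DEFAULT_ORIENTATION: dict[str, int] = {
    "fas_fluency": +1, "wcst_categories": +1, "wcst_perseverative_errors": -1,
    "trails_a_time": -1,
    "cvlt_total": +1, "wms_visual_reproduction": +1, "drs_memory": +1,
}


@dataclass
class EffectSize:
    d: float
    pooled_sd: float
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int

    @property
    def magnitude(self) -> float:
        return abs(self.d)


@dataclass
class RegressionResult:
    outcome: str
    retained: pd.DataFrame          # predictor, beta, partial_r2, p, forced
    eliminated: list[tuple[str, float]]   # (predictor, p at removal), in order
    n: int
    r_squared: float

    def retained_names(self) -> list[str]:
        return self.retained["predictor"].tolist()


@dataclass
class StepwiseResult:
    stage1: RegressionResult
    localized_lobes: list[str]
    stage2: dict[str, RegressionResult] = field(default_factory=dict)

    def final(self) -> RegressionResult | dict[str, RegressionResult]:
        return self.stage2 if self.stage2 else self.stage1


def composite_score(raw_scores: pd.DataFrame, reference_index,
                    domain_map: Mapping[str, Sequence[str]] | None = None,
                    orientation: Mapping[str, int] | None = None) -> pd.DataFrame:
    """Domain composites as oriented mean z-scores against the reference.

    Each test is z-scored with the reference (control) mean/SD, multiplied
    by its orientation so higher always means better, and averaged within
    each domain over the tests the subject completed.  A subject missing
    every test of a domain gets a missing composite.
    """
    domain_map = dict(domain_map or DEFAULT_DOMAIN_MAP)
    orientation = dict(orientation or DEFAULT_ORIENTATION)
    out = {}
    for domain, tests in domain_map.items():
        zcols = []
        for t in tests:
            if t not in raw_scores.columns:
                continue
            ref = raw_scores.loc[reference_index, t].dropna()
            sd = float(ref.std(ddof=1))
            if len(ref) < 2 or sd == 0:
                raise InputError(f"test '{t}' has no reference variance")
            z = (raw_scores[t] - float(ref.mean())) / sd
            zcols.append(z * orientation.get(t, +1))
        if not zcols:
            raise InputError(f"domain '{domain}' has no available tests")
        out[domain] = pd.concat(zcols, axis=1).mean(axis=1, skipna=True)
    return pd.DataFrame(out, index=raw_scores.index)


def cohens_d_pooled(mean1: float, sd1: float, n1: int,
                    mean2: float, sd2: float, n2: int) -> EffectSize:
    """Standardized mean difference with the pooled-SD convention:
    sp = sqrt(((n1-1) sd1^2 + (n2-1) sd2^2) / (n1+n2-2)), d = (m1-m2)/sp."""
    if n1 < 2 or n2 < 2:
        raise InputError("each group needs at least two observations")
    if sd1 < 0 or sd2 < 0:
        raise InputError("standard deviations must be nonnegative")
    pooled = np.sqrt(((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / (n1 + n2 - 2))
    if pooled == 0:
        raise UndefinedEffectError("pooled standard deviation is zero")
    return EffectSize(float((mean1 - mean2) / pooled), float(pooled),
                      mean1, sd1, n1, mean2, sd2, n2)


def _design(table: pd.DataFrame, cols: Sequence[str]) -> np.ndarray:
    X = table[list(cols)].to_numpy(dtype=float)
    return sm.add_constant(X, has_constant="add")


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = []
        for j in range(1, X.shape[1]):
            keep = [c for c in range(X.shape[1]) if c != j]
            if np.linalg.matrix_rank(X[:, keep]) == rank:
                bad.append(names[j - 1])
        raise CollinearityError(f"design matrix is rank deficient: {bad}", bad)


def ancova_group_difference(table: pd.DataFrame, outcome: str,
                            group_col: str = "group",
                            covariates: Sequence[str] = ("age", "sex", "education")):
    """OLS of outcome on a group indicator plus covariates.

    Returns (adjusted group difference, t statistic, p value, fitted model).
    The group indicator is 1 for the lexicographically later level (AD vs NC
    gives AD = 1... NC = 0 under 'AD' < 'NC'; the first level is the
    reference), so the estimate is the covariate-adjusted group offset.
    """
    data = table.dropna(subset=[outcome, *covariates])
    levels = sorted(data[group_col].unique())
    if len(levels) != 2:
        raise InputError("ANCOVA requires exactly two group levels")
    y = data[outcome].to_numpy(dtype=float)
    g = (data[group_col] == levels[1]).astype(float)
    work = data[list(covariates)].astype(float).copy()
    work.insert(0, "_group", g)
    X = _design(work, ["_group", *covariates])
    _check_rank(X, ["_group", *covariates])
    fit = sm.OLS(y, X).fit()
    return float(fit.params[1]), float(fit.tvalues[1]), float(fit.pvalues[1]), fit


def _zscore_frame(df: pd.DataFrame) -> pd.DataFrame:
    return (df - df.mean()) / df.std(ddof=1)


def backwards_elimination(table: pd.DataFrame, outcome: str,
                          candidates: Sequence[str],
                          forced: Sequence[str] = (),
                          alpha: float = 0.05,
                          max_candidates: int = 6,
                          standardize: bool = True) -> RegressionResult:
    """Iterative OLS dropping the worst non-significant candidate.

    At each step the candidate with the highest p value above ``alpha`` is
    removed (ties broken toward the smaller absolute coefficient) and the
    model refitted, until every remaining candidate satisfies p <= alpha.
    ``forced`` covariates are always kept in the model and never eligible
    for removal.  Betas are standardized by z-scoring outcome and
    predictors; per-predictor R-squared is the squared partial correlation
    t^2 / (t^2 + df_resid).
    """
    candidates = list(candidates)
    forced = list(forced)
    if len(candidates) > max_candidates:
        raise InputError(
            f"{len(candidates)} candidate terms exceed the limit of {max_candidates}")
    cols = [outcome, *candidates, *forced]
    data = table[cols].dropna().astype(float)
    if standardize:
        data = _zscore_frame(data)
    n = len(data)
    if n <= len(cols) + 1:
        raise InputError("too few observations for the full model")

    current = list(candidates)
    eliminated: list[tuple[str, float]] = []
    while True:
        names = current + forced
        X = _design(data, names) if names else sm.add_constant(
            np.empty((n, 0)), has_constant="add")
        _check_rank(X, names)
        fit = sm.OLS(data[outcome].to_numpy(), X).fit()
        pvals = {nm: float(fit.pvalues[i + 1]) for i, nm in enumerate(names)}
        betas = {nm: float(fit.params[i + 1]) for i, nm in enumerate(names)}
        over = [c for c in current if pvals[c] > alpha]
        if not over:
            break
        worst_p = max(pvals[c] for c in over)
        ties = [c for c in over if pvals[c] == worst_p]
        drop = min(ties, key=lambda c: abs(betas[c]))
        eliminated.append((drop, pvals[drop]))
        current.remove(drop)

    names = current + forced
    rows = []
    df_resid = float(fit.df_resid)
    for i, nm in enumerate(names):
        t = float(fit.tvalues[i + 1])
        rows.append({"predictor": nm, "beta": float(fit.params[i + 1]),
                     "partial_r2": t * t / (t * t + df_resid),
                     "p": float(fit.pvalues[i + 1]), "forced": nm in forced})
    retained = pd.DataFrame(rows, columns=["predictor", "beta", "partial_r2",
                                           "p", "forced"])
    return RegressionResult(outcome, retained, eliminated, n, float(fit.rsquared))


def stepwise_voi_analysis(table: pd.DataFrame, outcome: str,
                          lobar_map: Mapping[str, Sequence[str]],
                          covariates: Sequence[str] = (),
                          alpha: float = 0.05) -> StepwiseResult:
    """Two-stage lobar screening then subregional localization.

    Stage 1 regresses the outcome on the four lobar aggregates (standardized
    sums of each lobe's subregion scores) plus covariates with backwards
    elimination.  For every lobe retained at p <= alpha, stage 2 refits on
    that lobe's subregions (at most six per model) plus covariates.  If no
    lobe survives, the stage-1 result stands.
    """
    work = table.copy()
    lobe_cols = []
    for lobe, regions in lobar_map.items():
        col = f"lobe_{lobe}"
        agg = work[list(regions)].sum(axis=1)
        work[col] = (agg - agg.mean()) / agg.std(ddof=1)
        lobe_cols.append(col)
    stage1 = backwards_elimination(work, outcome, lobe_cols, forced=covariates,
                                   alpha=alpha)
    localized = [c.removeprefix("lobe_") for c in stage1.retained_names()
                 if c in lobe_cols]
    stage2 = {}
    for lobe in localized:
        stage2[lobe] = backwards_elimination(work, outcome,
                                             list(lobar_map[lobe])[:6],
                                             forced=covariates, alpha=alpha)
    return StepwiseResult(stage1, localized, stage2)


def partial_regression_data(table: pd.DataFrame, outcome: str,
                            focal: str, covariates: Sequence[str] = ()):
    """Residualized series for a partial regression plot.

    Returns (x residuals, y residuals, slope).  By the Frisch-Waugh theorem
    the slope of y-residuals on x-residuals equals the focal coefficient in
    the joint model of outcome on focal + covariates.
    """
    data = table[[outcome, focal, *covariates]].dropna().astype(float)
    y = data[outcome].to_numpy()
    x = data[focal].to_numpy()
    if covariates:
        Z = _design(data, covariates)
        y_res = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
        x_res = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    else:
        y_res = y - y.mean()
        x_res = x - x.mean()
    denom = float(x_res @ x_res)
    if denom == 0:
        raise InputError("focal predictor has no residual variance")
    slope = float(x_res @ y_res) / denom
    return x_res, y_res, slope
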