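"""Blood-marker normalization, longitudinal mixed models, and Cox survival.

Markers are harmonized per cohort: outliers beyond 3 IQR from the
quartiles are removed, the transformation (log, square root, Box-Cox or
Yeo-Johnson) whose output is closest to normal is applied, and the
result is z-scored within the cohort.  Binary markers bypass
transformation.  Each marker is then regressed on the CH metrics with

    marker ~ age * maxVAF + maxFitness + MACS120

as a linear mixed model with a participant random intercept; the
age x maxVAF interaction carries the rate-of-change interpretation.
P-values are corrected across the marker panel per predictor with the
two-stage (adaptive) Benjamini-Hochberg procedure.  Survival runs
through a Cox proportional-hazards model on z-scored metrics plus age
and sex, optionally stratified into age bins 50-59 / 60-69 / 70-79 /
80+ or refit per cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AssociationResult",
    "NormalizedMarker",
    "normalize_marker",
    "normalize_marker_table",
    "fit_marker_lmm",
    "fit_cox",
    "assign_age_bin",
]

LMM_PREDICTORS = ("max_vaf_z", "age:max_vaf_z", "max_fitness_z", "macs120_z")
AGE_BINS = ((50.0, 60.0), (60.0, 70.0), (70.0, 80.0), (80.0, float("inf")))


@dataclass
class AssociationResult:
    outcome: str
    predictor: str
    beta: float | None
    ci_low: float | None
    ci_high: float | None
    p_raw: float | None
    p_adjusted: float | None = None
    n: int = 0
    scope: str = "pooled"
    flag: str | None = None


@dataclass
class NormalizedMarker:
    values: np.ndarray  # z-scored retained values
    kept: np.ndarray  # boolean mask into the input
    transform: str  # identity-binary / log / sqrt / box-cox / yeo-johnson
    shapiro_w: float | None
    n_outliers: int
    flag: str | None = None


def _shapiro_w(x, rng=np.random.default_rng(0)):
    if len(x) > 5000:
        x = rng.choice(x, 5000, replace=False)
    if np.ptp(x) == 0:
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.shapiro(x).statistic)


def normalize_marker(values, min_n: int = 8) -> NormalizedMarker:
    """Standardize one marker within one cohort.

    Removes values outside [Q1 - 3 IQR, Q3 + 3 IQR], applies the
    domain-valid transform with the largest Shapiro-Wilk W, and z-scores
    the result.  Binary markers (exactly two distinct values) are
    returned untransformed and un-z-scored; short or degenerate series
    are flagged and skipped.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < min_n:
        return NormalizedMarker(np.array([]), np.zeros_like(finite), "none", None, 0, "too-few-values")
    if len(np.unique(x[finite])) == 2:
        return NormalizedMarker(x[finite], finite, "identity-binary", None, 0, "binary")

    q1, q3 = np.percentile(x[finite], [25, 75])
    iqr = q3 - q1
    kept = finite & (x >= q1 - 3 * iqr) & (x <= q3 + 3 * iqr)
    v = x[kept]
    if np.ptp(v) == 0:
        return NormalizedMarker(np.array([]), kept, "none", None, int(finite.sum() - kept.sum()), "zero-variance")

    candidates: dict[str, np.ndarray] = {}
    if np.all(v > 0):
        candidates["log"] = np.log(v)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bc, _ = stats.boxcox(v)
        candidates["box-cox"] = bc
    if np.all(v >= 0):
        candidates["sqrt"] = np.sqrt(v)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yj, _ = stats.yeojohnson(v)
    candidates["yeo-johnson"] = yj

    scores = {name: _shapiro_w(t) for name, t in candidates.items()}
    best = max(sorted(scores), key=lambda k: scores[k])
    t = candidates[best]
    z = (t - t.mean()) / t.std(ddof=0)
    return NormalizedMarker(z, kept, best, scores[best], int(finite.sum() - kept.sum()))


def normalize_marker_table(markers: pd.DataFrame, min_n: int = 8):
    """Apply :func:`normalize_marker` per (cohort, marker).

    Returns ``(standardized long table, report table)``; skipped markers
    appear only in the report.
    """
    out, report = [], []
    for (cohort, marker), sub in markers.groupby(["cohort", "marker_name"]):
        norm = normalize_marker(sub["value"].to_numpy(), min_n=min_n)
        report.append(
            {
                "cohort": cohort,
                "marker_name": marker,
                "transform": norm.transform,
                "shapiro_w": norm.shapiro_w,
                "n_outliers": norm.n_outliers,
                "flag": norm.flag,
            }
        )
        if norm.flag not in (None, "binary"):
            continue
        keep = sub.iloc[np.flatnonzero(norm.kept)].copy()
        keep["value"] = norm.values
        out.append(keep)
    std = pd.concat(out, ignore_index=True) if out else markers.iloc[0:0].copy()
    return std, pd.DataFrame(report)


def fit_marker_lmm(
    markers: pd.DataFrame,
    metrics: pd.DataFrame,
    scope: str = "pooled",
    fdr: float = 0.05,
    extra_rate_terms: bool = False,
):
    """Per-marker linear mixed models with participant random intercepts.

    ``markers`` is the standardized long table, ``metrics`` the z-scored
    participant metrics.  Participants contribute only markers with at
    least two visits.  Returns one :class:`AssociationResult` per
    (marker, predictor); adjusted p-values are two-stage BH across the
    marker panel, per predictor.  ``extra_rate_terms`` adds
    age x maxFitness and age x MACS120 interactions to the formula.
    """
    formula = "value ~ age * max_vaf_z + max_fitness_z + macs120_z"
    predictors = list(LMM_PREDICTORS)
    if extra_rate_terms:
        formula += " + age:max_fitness_z + age:macs120_z"
        predictors += ["age:max_fitness_z", "age:macs120_z"]

    merged = markers.merge(
        metrics[["participant_id", "max_vaf_z", "max_fitness_z", "macs120_z"]],
        on="participant_id",
        how="inner",
    )
    results: list[AssociationResult] = []
    for marker, sub in merged.groupby("marker_name"):
        counts = sub.groupby("participant_id")["age"].transform("size")
        sub = sub[counts >= 2]
        if sub.empty or sub["participant_id"].nunique() < 3:
            results.append(
                AssociationResult(marker, "all", None, None, None, None, flag="skipped: <2 visits")
            )
            continue
        flag = None
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = smf.mixedlm(formula, sub, groups=sub["participant_id"]).fit(reml=True)
            if not fit.converged:
                raise RuntimeError("not converged")
            if not np.all(np.isfinite(fit.bse_fe)):
                raise RuntimeError("singular random-effect fit")
        except Exception:
            # singular or non-convergent mixed fit: fall back to OLS, flagged
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = smf.ols(formula, sub).fit()
            flag = "refit-ols"
        params, bse, pvals = fit.params, fit.bse, fit.pvalues
        n = int(sub["participant_id"].nunique())
        for pred in predictors:
            if pred not in params.index:
                continue
            beta, se = float(params[pred]), float(bse[pred])
            results.append(
                AssociationResult(
                    outcome=marker,
                    predictor=pred,
                    beta=beta,
                    ci_low=beta - 1.959963984540054 * se,
                    ci_high=beta + 1.959963984540054 * se,
                    p_raw=float(pvals[pred]),
                    n=n,
                    scope=scope,
                    flag=flag,
                )
            )

    for pred in predictors:
        batch = [r for r in results if r.predictor == pred and r.p_raw is not None and r.flag is None]
        if batch:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                adj = multipletests([r.p_raw for r in batch], alpha=fdr, method="fdr_tsbh")[1]
            for r, p in zip(batch, adj):
                r.p_adjusted = float(min(p, 1.0))
    return results


def assign_age_bin(age: float) -> str | None:
    for lo, hi in AGE_BINS:
        if lo <= age < hi:
            return f"{int(lo)}-{int(hi) - 1 if np.isfinite(hi) else '+'}" if np.isfinite(hi) else f"{int(lo)}+"
    return None


def fit_cox(
    survival: pd.DataFrame,
    metrics: pd.DataFrame,
    scope: str = "pooled",
):
    """Cox proportional-hazards fit on z-scored CH metrics, age and sex.

    ``survival`` needs participant_id / time / event plus age_first_obs
    and sex; ``metrics`` the z-scored participant metrics.  Constant
    covariates are dropped with a warning flag; separation or
    non-convergence triggers a penalized refit.  Returns
    ``(results, concordance)`` with one result per covariate (beta is
    the log proportional hazard).
    """
    df = survival.merge(
        metrics[["participant_id", "max_vaf_z", "max_fitness_z", "macs120_z"]],
        on="participant_id",
        how="inner",
    ).copy()
    if df["event"].sum() == 0:
        raise ValueError("no events")
    age = df["age_first_obs"].to_numpy(dtype=float)
    df["age_z"] = (age - age.mean()) / age.std(ddof=0) if age.std(ddof=0) > 0 else 0.0
    df["sex_male"] = (df["sex"] == "M").astype(float)

    covs = ["max_vaf_z", "max_fitness_z", "macs120_z", "age_z", "sex_male"]
    dropped = [c for c in covs if df[c].nunique() <= 1]
    covs = [c for c in covs if c not in dropped]
    flag = f"dropped constant covariates: {dropped}" if dropped else None

    cph = CoxPHFitter()
    fit_df = df[["time", "event"] + covs]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(fit_df, duration_col="time", event_col="event")
    except ConvergenceError:
        cph = CoxPHFitter(penalizer=0.1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(fit_df, duration_col="time", event_col="event")
        flag = (flag + "; " if flag else "") + "penalized-refit"

    results = []
    summ = cph.summary
    for cov in covs:
        row = summ.loc[cov]
        results.append(
            AssociationResult(
                outcome="survival",
                predictor=cov,
                beta=float(row["coef"]),
                ci_low=float(row["coef lower 95%"]),
                ci_high=float(row["coef upper 95%"]),
                p_raw=float(row["p"]),
                n=len(df),
                scope=scope,
                flag=flag,
            )
        )
    return results, float(cph.concordance_index_)


def fit_cox_stratified(survival: pd.DataFrame, metrics: pd.DataFrame, by: str = "age_bin"):
    """Per-age-bin (or per-cohort) Cox refits; bins without events are skipped."""
    df = survival.copy()
    if by == "age_bin":
        df["stratum"] = [assign_age_bin(a) for a in df["age_first_obs"]]
    elif by == "cohort":
        df["stratum"] = df["cohort"]
    else:
        raise ValueError(f"unknown stratification {by!r}")
    out = {}
    for stratum, sub in df.groupby("stratum"):
        if sub["event"].sum() == 0 or len(sub) < 10:
            continue
        try:
            out[stratum] = fit_cox(sub, metrics, scope=str(stratum))
        except Exception:
            continue
    return out
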