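"""Association analyses: composites, mixed models, LRTs, R², stepwise.

The modelling follows the repeated-measures design of the speech-timing
study: each timing feature (log-transformed when skewed) is the dependent
variable of a random-intercept linear mixed model with speaker intercepts;
fixed effects are the group, a composite cognitive score or a z-scored ROI
volume, crossed with trial, always adjusted for age, sex and education
(plus estimated total intracranial volume for ROI models).  Interaction
significance comes from likelihood-ratio tests of ML fits; effect sizes
are Nakagawa–Schielzeth marginal and conditional R²; multiple testing is
handled by Bonferroni-divided alpha levels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
import statsmodels.api as sm
import statsmodels.formula.api as smf

#: composite -> constituent corrected subscore columns; each composite is
#: the arithmetic mean of the constituents that are present
COMPOSITE_CONSTITUENTS: dict[str, tuple[str, ...]] = {
    "memory": ("rbans_immediate_recall", "rbans_delayed_recall",
               "moca_immediate_recall", "moca_delayed_recall"),
    "language": ("rbans_language", "moca_language", "moca_naming"),
    "wm_attention": ("rbans_working_memory", "rbans_attention", "moca_wm_attention"),
    "visuo_ef": ("rbans_visuospatial", "moca_visuo_ef"),
    "orientation": ("moca_orientation",),
}


def compute_composites(scores: pd.DataFrame) -> pd.DataFrame:
    """Domain composite scores from corrected RBANS/MoCA subscores.

    Each composite is the arithmetic mean of its constituent columns; a
    missing constituent is skipped (flagged in ``<name>_partial``), and a
    composite with no constituent present is missing.
    """
    out = pd.DataFrame(index=scores.index)
    for name, cols in COMPOSITE_CONSTITUENTS.items():
        present = [c for c in cols if c in scores.columns]
        if not present:
            out[name] = np.nan
            out[name + "_partial"] = True
            continue
        block = scores[present]
        out[name] = block.mean(axis=1, skipna=True)
        out[name + "_partial"] = block.isna().any(axis=1) | (len(present) < len(cols))
    return out


def bonferroni_alpha(family_alpha: float = 0.05, n_models: int = 1) -> float:
    """Per-model significance threshold family_alpha / n_models."""
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    if not 0 < family_alpha <= 1:
        raise ValueError("family_alpha must be in (0, 1]")
    return family_alpha / n_models


def report_alpha(threshold: float, decimals: int = 3) -> float:
    """Reporting convention: thresholds rounded to three decimals."""
    return round(threshold, decimals)


@dataclass
class ModelSpec:
    """Specification of one random-intercept mixed model.

    ``predictors`` are the focal fixed effects ("group" or continuous
    score/ROI columns); each is crossed with trial when
    ``trial_interaction`` is set.  ``scale`` applies per-predictor
    preprocessing: "center" (composite scores) or "zscore" (ROI volumes).
    """

    dv: str
    predictors: tuple[str, ...] = ("group",)
    trial_interaction: bool = True
    covariates: tuple[str, ...] = ("age", "sex", "education")
    scale: dict[str, str] = field(default_factory=dict)
    log_dv: bool | str = "auto"   # "auto": log-transform when raw skewness > 1
    ref_group: str = "HC"
    ref_trial: str = "describe_and_match"
    group_col: str = "speaker"
    trial_col: str = "trial"
    method: str = "reml"          # "reml" or "ml" (use "ml" for LRTs)


@dataclass
class LmmFit:
    """A fitted random-intercept linear mixed model."""

    spec: ModelSpec
    params: pd.Series
    conf_int: pd.DataFrame        # columns [lower, upper], Wald 95%
    pvalues: pd.Series
    var_fixed: float
    var_random: float
    var_residual: float
    llf: float
    n_obs: int
    n_groups: int
    method: str
    log_transformed: bool
    converged: bool
    boundary: bool                # random-intercept variance at zero
    formula: str

    @property
    def coefficients(self) -> pd.DataFrame:
        return pd.DataFrame({
            "estimate": self.params,
            "ci_low": self.conf_int.iloc[:, 0],
            "ci_high": self.conf_int.iloc[:, 1],
            "p": self.pvalues,
        })


def _prepare(table: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, list[str], bool]:
    df = table.copy()
    needed = [spec.dv, spec.group_col, spec.trial_col, *spec.covariates]
    needed += [p for p in spec.predictors if p != "group"]
    if "group" in spec.predictors:
        needed.append("group")
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"table is missing columns {missing}")
    df = df.dropna(subset=[c for c in needed if c in df.columns])

    y = df[spec.dv].to_numpy(float)
    if spec.log_dv == "auto":
        log_dv = bool(np.all(y > 0)) and abs(sstats.skew(y)) > 1.0
    else:
        log_dv = bool(spec.log_dv)
    if log_dv:
        if np.any(y <= 0):
            raise ValueError(f"cannot log-transform {spec.dv}: non-positive values present")
        df["_dv"] = np.log(y)
    else:
        df["_dv"] = y

    terms: list[str] = []
    for pred in spec.predictors:
        if pred == "group":
            term = f"C(group, Treatment({spec.ref_group!r}))"
        else:
            how = spec.scale.get(pred)
            col = pred
            if how == "center":
                col = f"{pred}_c"
                df[col] = df[pred] - df[pred].mean()
            elif how == "zscore":
                col = f"{pred}_z"
                df[col] = (df[pred] - df[pred].mean()) / df[pred].std(ddof=0)
            term = col
        terms.append(term)
    return df, terms, log_dv


def _formula(spec: ModelSpec, terms: list[str], interaction: bool) -> str:
    trial = f"C({spec.trial_col}, Treatment({spec.ref_trial!r}))"
    parts = []
    for t in terms:
        parts.append(f"{t} * {trial}" if interaction else f"{t} + {trial}")
    if not terms:
        parts.append(trial)
    rhs = " + ".join(dict.fromkeys(parts + list(spec.covariates)))
    return f"_dv ~ {rhs}"


def fit_lmm(table: pd.DataFrame, spec: ModelSpec) -> LmmFit:
    """Fit the random-intercept mixed model described by ``spec``.

    REML by default; pass method="ml" for fits feeding likelihood-ratio
    tests.  Composite-score predictors should be centered and ROI
    predictors z-scored via ``spec.scale``.  A variance estimate at the
    boundary (no speaker variance) is returned with a flag rather than an
    error.
    """
    df, terms, log_dv = _prepare(table, spec)
    if df[spec.group_col].nunique() < 2 or len(df) < 4:
        raise ValueError("need at least 2 speakers and 4 observations")
    formula = _formula(spec, terms, spec.trial_interaction)
    reml = spec.method.lower() == "reml"
    model = smf.mixedlm(formula, df, groups=df[spec.group_col])
    res = None
    last_exc: Exception | None = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in (None, "lbfgs", "powell", "cg"):
            try:
                cand = model.fit(reml=reml) if method is None else model.fit(reml=reml, method=method)
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_exc = exc
                continue
            if cand.converged:
                res = cand
                break
            if res is None:
                res = cand  # keep the first usable fit as fallback
    if res is None:
        raise RuntimeError(f"mixed-model fit failed for {spec.dv}: {last_exc}")
    if not res.converged:
        raise RuntimeError(f"mixed-model fit did not converge for {spec.dv}")

    fe = res.fe_params
    X = model.exog
    var_fixed = float(np.var(X @ fe.to_numpy(), ddof=0))
    var_random = float(np.asarray(res.cov_re).ravel()[0])
    var_resid = float(res.scale)
    ci = res.conf_int().loc[fe.index]
    return LmmFit(
        spec=spec,
        params=fe,
        conf_int=ci,
        pvalues=res.pvalues.loc[fe.index],
        var_fixed=var_fixed,
        var_random=var_random,
        var_residual=var_resid,
        llf=float(res.llf),
        n_obs=int(res.nobs),
        n_groups=df[spec.group_col].nunique(),
        method="reml" if reml else "ml",
        log_transformed=log_dv,
        converged=bool(res.converged),
        boundary=var_random <= 1e-8,
        formula=formula,
    )


def lrt_interaction(additive_fit: LmmFit, interaction_fit: LmmFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of the interaction model against the additive one.

    Both fits must be ML on the same data, with the additive model nested
    in the interaction model.  Returns (chi2, df, p).
    """
    for f in (additive_fit, interaction_fit):
        if f.method != "ml":
            raise ValueError("likelihood-ratio tests require ML fits, not REML")
    if additive_fit.n_obs != interaction_fit.n_obs:
        raise ValueError("fits are not on the same data (n_obs differ)")
    df = len(interaction_fit.params) - len(additive_fit.params)
    if df < 0:
        raise ValueError("additive model has more parameters than the interaction model")
    chi2 = max(2.0 * (interaction_fit.llf - additive_fit.llf), 0.0)
    p = 1.0 if df == 0 else float(sstats.chi2.sf(chi2, df))
    return chi2, df, p


def r2_nakagawa(fit: LmmFit) -> tuple[float, float]:
    """Marginal and conditional R² from the fit's variance components.

    R²m = s2_f / (s2_f + s2_r + s2_e); R²c adds the random-intercept
    variance to the numerator.  Always 0 <= R²m <= R²c <= 1.
    """
    total = fit.var_fixed + fit.var_random + fit.var_residual
    if total <= 0:
        raise ValueError("all variance components are zero")
    return fit.var_fixed / total, (fit.var_fixed + fit.var_random) / total


@dataclass
class StepwiseResult:
    spec: ModelSpec
    fit: LmmFit
    kept: tuple[str, ...]
    trace: list[str]


def _aic(fit: LmmFit) -> float:
    # fixed effects + random-intercept variance + residual variance
    k = len(fit.params) + 2
    return 2 * k - 2 * fit.llf


def stepwise_select(table: pd.DataFrame, spec: ModelSpec) -> StepwiseResult:
    """Backward/forward stepwise selection over the focal predictors.

    Alternates backward elimination and forward re-inclusion on ML fits,
    comparing AIC, until no single move improves it.  The random
    intercept, trial term and covariates are never dropped.  Deterministic
    given the data.
    """
    ml_spec = lambda preds: ModelSpec(**{**spec.__dict__, "predictors": tuple(preds),
                                         "scale": dict(spec.scale), "method": "ml"})
    current = list(spec.predictors)
    removed: list[str] = []
    trace: list[str] = []
    best_fit = fit_lmm(table, ml_spec(current))
    best_aic = _aic(best_fit)
    trace.append(f"start: {current} AIC={best_aic:.2f}")
    improved = True
    while improved:
        improved = False
        for pred in list(current):          # backward
            trial_preds = [p for p in current if p != pred]
            try:
                cand = fit_lmm(table, ml_spec(trial_preds))
            except (RuntimeError, ValueError):
                continue
            if _aic(cand) < best_aic - 1e-9:
                best_aic, best_fit = _aic(cand), cand
                current, removed = trial_preds, removed + [pred]
                trace.append(f"drop {pred}: AIC={best_aic:.2f}")
                improved = True
                break
        if improved:
            continue
        for pred in list(removed):          # forward
            trial_preds = current + [pred]
            try:
                cand = fit_lmm(table, ml_spec(trial_preds))
            except (RuntimeError, ValueError):
                continue
            if _aic(cand) < best_aic - 1e-9:
                best_aic, best_fit = _aic(cand), cand
                current = trial_preds
                removed.remove(pred)
                trace.append(f"add {pred}: AIC={best_aic:.2f}")
                improved = True
                break
    trace.append(f"final: {current} AIC={best_aic:.2f}")
    return StepwiseResult(spec=best_fit.spec, fit=best_fit, kept=tuple(current), trace=trace)


def describe_cohort(
    table: pd.DataFrame,
    continuous: tuple[str, ...],
    binary: tuple[str, ...] = (),
    group_col: str = "group",
    ref: str = "HC",
) -> pd.DataFrame:
    """Group descriptives with regression comparisons against the reference.

    Continuous variables: mean (SD) per group and OLS group contrasts vs
    the reference level; binary variables: percentage per group and
    logistic contrasts.  Returns one row per variable per non-reference
    group with the contrast p-value.
    """
    groups = [g for g in table[group_col].dropna().unique()]
    if any((table[group_col] == g).sum() == 0 for g in groups) or not groups:
        raise ValueError("every group must be non-empty")
    if ref not in groups:
        raise ValueError(f"reference group {ref!r} absent")
    rows = []
    gdummies = pd.get_dummies(table[group_col], dtype=float).drop(columns=[ref])
    X = sm.add_constant(gdummies)
    for var in continuous:
        y = table[var].to_numpy(float)
        res = sm.OLS(y, X, missing="drop").fit()
        for g in groups:
            sub = table.loc[table[group_col] == g, var]
            rows.append({
                "variable": var, "group": g, "mean": sub.mean(), "sd": sub.std(ddof=1),
                "pct": np.nan,
                "p_vs_ref": np.nan if g == ref else float(res.pvalues[g]),
            })
    for var in binary:
        y = table[var].to_numpy(float)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, X, missing="drop").fit(disp=0)
            pvals = {g: float(res.pvalues[g]) for g in gdummies.columns}
        except Exception:
            pvals = {g: np.nan for g in gdummies.columns}
        for g in groups:
            sub = table.loc[table[group_col] == g, var]
            rows.append({
                "variable": var, "group": g, "mean": np.nan, "sd": np.nan,
                "pct": 100.0 * sub.mean(),
                "p_vs_ref": np.nan if g == ref else pvals.get(g, np.nan),
            })
    return pd.DataFrame(rows)
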