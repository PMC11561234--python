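"""Cross-sectional and longitudinal validation of the CR score.

Implements the quadratic pathology -> cognition model, the
proxy-moderation model

    Performance = b0 + b1*BAE + b2*PL^2 + b3*CR_score*PL^2 + c*COV + eps

(the CR score enters only through the interaction, with the additive
brain-activity effect BAE as a main-effect control), its hippocampal-
atrophy variant, the CR-education correlation, and the longitudinal
linear mixed model with the three-way CR x atrophy^2 x time interaction
and subject random intercepts and slopes.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .qc import iqr_bounds

__all__ = [
    "ModerationFitReport",
    "LongitudinalFitReport",
    "fit_pl_outcome",
    "fit_proxy_moderation",
    "atrophy_variant",
    "correlate_cr_education",
    "fit_longitudinal",
    "cluster_moderation_curves",
    "cr_outlier_keep",
]


@dataclass
class ModerationFitReport:
    """Tidy OLS report: one row per term plus model-level statistics."""

    terms: pd.DataFrame  # index term; coef, ci_low, ci_high, t, p, beta_std
    r_squared: float
    df_resid: float
    n_obs: int
    model_tag: str

    def coef(self, term: str) -> float:
        return float(self.terms.loc[term, "coef"])


@dataclass
class LongitudinalFitReport:
    """Mixed-model report: fixed effects, random-effect (co)variances and
    the random-slope likelihood-ratio comparison."""

    fixed_effects: pd.DataFrame  # coef, ci_low, ci_high, z, p, beta_std
    random_variances: dict  # intercept, slope, covariance, residual
    lrt_statistic: float | None
    lrt_pvalue: float | None
    converged: bool
    n_obs: int
    n_subjects: int
    fitted: pd.DataFrame | None = None  # subject, time, predicted
    model_tag: str = "longitudinal"

    def coef(self, term: str) -> float:
        return float(self.fixed_effects.loc[term, "coef"])


def _ols_report(y: np.ndarray, x: pd.DataFrame, tag: str) -> ModerationFitReport:
    model = sm.OLS(np.asarray(y, dtype=float), x)
    res = model.fit()
    ci = res.conf_int(alpha=0.05)
    sd_y = np.std(y, ddof=1)
    sd_x = x.std(ddof=1)
    beta_std = res.params * sd_x / sd_y
    beta_std[sd_x == 0] = np.nan
    terms = pd.DataFrame(
        {
            "coef": res.params,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "t": res.tvalues,
            "p": res.pvalues,
            "beta_std": beta_std,
        }
    )
    return ModerationFitReport(
        terms=terms,
        r_squared=float(res.rsquared),
        df_resid=float(res.df_resid),
        n_obs=int(res.nobs),
        model_tag=tag,
    )


def _design_frame(index, columns: dict) -> pd.DataFrame:
    x = pd.DataFrame({"intercept": np.ones(len(index))}, index=index)
    for name, vals in columns.items():
        x[name] = np.asarray(vals, dtype=float)
    if np.linalg.matrix_rank(x.to_numpy()) < x.shape[1]:
        offenders = []
        arr = x.to_numpy()
        for j in range(1, arr.shape[1]):
            if np.linalg.matrix_rank(arr[:, : j + 1]) == np.linalg.matrix_rank(arr[:, :j]):
                offenders.append(x.columns[j])
        raise np.linalg.LinAlgError(f"singular design; dependent column(s): {offenders}")
    return x


def fit_pl_outcome(
    pl: pd.Series, y: pd.Series, covariates: pd.DataFrame, form: str = "quadratic"
) -> ModerationFitReport:
    """Cognition on pathological load, linear or quadratic-only form."""
    if form not in ("linear", "quadratic"):
        raise ValueError(f"form must be 'linear' or 'quadratic', got {form!r}")
    term = pl if form == "linear" else pl**2
    name = "pl" if form == "linear" else "pl2"
    cols = {name: term}
    cols.update({c: covariates[c] for c in covariates.columns})
    x = _design_frame(pl.index, cols)
    return _ols_report(y.loc[pl.index].to_numpy(), x, tag=f"pl_{form}")


def fit_proxy_moderation(
    y: pd.Series,
    pathology_sq: pd.Series,
    moderator: pd.Series,
    extra_main_terms: pd.DataFrame | None,
    covariates: pd.DataFrame | None,
    moderator_name: str = "moderator",
    include_moderator_main: bool = False,
    tag: str = "proxy_moderation",
) -> ModerationFitReport:
    """Moderation model: [1 | main terms | pathology^2 | M * pathology^2 | COV].

    ``pathology_sq`` is the already-squared pathology variable.  By default
    the moderator enters only through the interaction (as in the CR-score
    validation model); set ``include_moderator_main`` for the sensitivity
    variant with a moderator main effect (always used for education, via
    ``extra_main_terms``).
    """
    cols: dict = {}
    if extra_main_terms is not None:
        for c in extra_main_terms.columns:
            cols[c] = extra_main_terms[c]
    if include_moderator_main:
        cols[moderator_name] = moderator
    cols["pathology2"] = pathology_sq
    cols[f"{moderator_name}:pathology2"] = moderator * pathology_sq
    if covariates is not None:
        for c in covariates.columns:
            cols[c] = covariates[c]
    x = _design_frame(y.index, cols)
    return _ols_report(y.to_numpy(), x, tag=tag)


def atrophy_variant(
    y: pd.Series,
    atrophy_sq: pd.Series,
    cr: pd.Series,
    bae: pd.Series,
    covariates: pd.DataFrame | None,
) -> ModerationFitReport:
    """CR-score moderation with hippocampal atrophy^2 as the pathology term
    (for subjects without CSF measures)."""
    return fit_proxy_moderation(
        y,
        atrophy_sq,
        cr,
        extra_main_terms=bae.to_frame("bae"),
        covariates=covariates,
        moderator_name="cr",
        tag="atrophy_moderation",
    )


def correlate_cr_education(cr: np.ndarray, education: np.ndarray) -> dict:
    """Pearson correlation with Fisher-z 95% CI."""
    cr = np.asarray(cr, dtype=float)
    education = np.asarray(education, dtype=float)
    n = cr.size
    if n < 4:
        raise ValueError("need at least 4 complete pairs")
    if cr.std() == 0 or education.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(cr, education)
    z = np.arctanh(r)
    half = stats.norm.ppf(0.975) / np.sqrt(n - 3)
    return {
        "r": float(r),
        "ci_low": float(np.tanh(z - half)),
        "ci_high": float(np.tanh(z + half)),
        "p": float(p),
        "df": n - 2,
    }


def cr_outlier_keep(cr: pd.Series, k: float = 3.0) -> pd.Series:
    """Keep-mask for the CR-score extreme-outlier rule (> Q3 + k*IQR)."""
    _, upper = iqr_bounds(cr.to_numpy(), k)
    return cr <= upper


_LME_FIXED = [
    "atrophy2", "time", "cr", "atrophy2:time", "cr:time", "cr:atrophy2",
    "cr:atrophy2:time", "bae", "bae:time",
]


def fit_longitudinal(
    visits: pd.DataFrame,
    cr: pd.Series,
    bae: pd.Series,
    atrophy: pd.Series,
    covariates: pd.DataFrame | None = None,
    reml: bool = True,
    compare_random_slope: bool = True,
) -> LongitudinalFitReport:
    """Linear mixed model of longitudinal cognition.

    Fixed effects: atrophy^2, time, CR, all their two-way interactions, the
    three-way CR x atrophy^2 x time term, BAE and BAE x time, plus any
    covariates.  Random effects: subject intercept and slope with
    unstructured 2x2 covariance (REML).  The random-slope term is assessed
    by an ML likelihood-ratio comparison against a random-intercept-only
    model with a boundary-corrected 0.5*(chi2_1 + chi2_2) reference.

    With an exactly deterministic outcome (zero residual after OLS) the
    mixed model is degenerate; the report then carries the OLS fixed
    effects and zero variances.
    """
    needed = {"subject", "time_years", "pacc5"}
    if not needed.issubset(visits.columns):
        raise ValueError(f"visits table must have columns {sorted(needed)}")
    per_subject = pd.DataFrame({"cr": cr, "bae": bae, "atrophy": atrophy})
    if covariates is not None:
        per_subject = per_subject.join(covariates)
    df = visits.merge(per_subject, left_on="subject", right_index=True, how="inner").dropna()
    n_subjects = df["subject"].nunique()
    if (df.groupby("subject").size() >= 2).mean() < 0.5:
        raise ValueError("fewer than half the subjects have >= 2 visits; slopes unidentifiable")

    t = df["time_years"].to_numpy()
    atr2 = df["atrophy"].to_numpy() ** 2
    cr_v = df["cr"].to_numpy()
    bae_v = df["bae"].to_numpy()
    x = pd.DataFrame(
        {
            "intercept": 1.0,
            "atrophy2": atr2,
            "time": t,
            "cr": cr_v,
            "atrophy2:time": atr2 * t,
            "cr:time": cr_v * t,
            "cr:atrophy2": cr_v * atr2,
            "cr:atrophy2:time": cr_v * atr2 * t,
            "bae": bae_v,
            "bae:time": bae_v * t,
        },
        index=df.index,
    )
    if covariates is not None:
        for c in covariates.columns:
            x[c] = df[c].to_numpy()
    y = df["pacc5"].to_numpy(dtype=float)
    groups = df["subject"].to_numpy()
    exog_re = np.column_stack([np.ones(len(df)), t])

    # Degenerate (noise-free) outcome: OLS already fits exactly.
    ols = sm.OLS(y, x).fit()
    if ols.ssr <= 1e-12 * max(1.0, float(y @ y)):
        ci = ols.conf_int(alpha=0.05)
        fixed = pd.DataFrame(
            {"coef": ols.params, "ci_low": ci[0], "ci_high": ci[1],
             "z": ols.tvalues, "p": ols.pvalues,
             "beta_std": ols.params * x.std(ddof=1) / max(np.std(y, ddof=1), 1e-300)}
        )
        return LongitudinalFitReport(
            fixed_effects=fixed,
            random_variances={"intercept": 0.0, "slope": 0.0, "covariance": 0.0, "residual": 0.0},
            lrt_statistic=None,
            lrt_pvalue=None,
            converged=True,
            n_obs=len(df),
            n_subjects=n_subjects,
            fitted=pd.DataFrame({"subject": groups, "time_years": t, "predicted": ols.fittedvalues}),
        )

    import warnings as _warnings
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    def _fit(re_cols, use_reml):
        model = sm.MixedLM(y, x, groups=groups, exog_re=exog_re[:, :re_cols])
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", ConvergenceWarning)
            _warnings.simplefilter("ignore", RuntimeWarning)
            _warnings.simplefilter("ignore", UserWarning)
            return model.fit(reml=use_reml, maxiter=200)

    converged = True
    try:
        res = _fit(2, reml)
        if not res.converged:
            converged = False
    except Exception:
        converged = False
        res = _fit(1, reml)  # documented fallback: intercept-only random effects

    k_fe = x.shape[1]
    params = res.params[:k_fe]
    bse = res.bse[:k_fe]
    zcrit = stats.norm.ppf(0.975)
    fixed = pd.DataFrame(
        {
            "coef": params,
            "ci_low": params - zcrit * bse,
            "ci_high": params + zcrit * bse,
            "z": params / bse,
            "p": 2 * stats.norm.sf(np.abs(params / bse)),
            "beta_std": params * x.std(ddof=1).to_numpy() / np.std(y, ddof=1),
        },
        index=x.columns,
    )
    cov_re = np.atleast_2d(np.asarray(res.cov_re))
    random_variances = {
        "intercept": float(cov_re[0, 0]),
        "slope": float(cov_re[1, 1]) if cov_re.shape[0] > 1 else 0.0,
        "covariance": float(cov_re[0, 1]) if cov_re.shape[0] > 1 else 0.0,
        "residual": float(res.scale),
    }

    lrt_stat = lrt_p = None
    if compare_random_slope and converged:
        try:
            full_ml = _fit(2, False)
            null_ml = _fit(1, False)
            lrt_stat = float(2.0 * (full_ml.llf - null_ml.llf))
            lrt_stat = max(lrt_stat, 0.0)
            # Boundary-corrected reference: 0.5 chi2(1) + 0.5 chi2(2).
            lrt_p = float(
                0.5 * stats.chi2.sf(lrt_stat, 1) + 0.5 * stats.chi2.sf(lrt_stat, 2)
            )
        except Exception:
            pass

    fitted = pd.DataFrame(
        {"subject": groups, "time_years": t, "predicted": res.fittedvalues}
    )
    return LongitudinalFitReport(
        fixed_effects=fixed,
        random_variances=random_variances,
        lrt_statistic=lrt_stat,
        lrt_pvalue=lrt_p,
        converged=converged,
        n_obs=len(df),
        n_subjects=n_subjects,
        fitted=fitted,
    )


def cluster_moderation_curves(
    cluster_mean_activity: pd.Series,
    pl: pd.Series,
    y: pd.Series,
    covariates: pd.DataFrame | None,
    pl_grid: np.ndarray | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Predicted cognition curves at high/low cluster activity.

    The outcome is residualized for the covariates, then modelled as
    intercept + activity + PL^2 + activity * PL^2 with the cluster's mean
    contrast as the (centered) activity moderator.  Predictions are made
    over a PL grid at activity one SD above and below the mean, with
    pointwise CIs from the coefficient covariance.
    """
    if cluster_mean_activity.empty:
        raise ValueError("empty cluster activity series")
    act = cluster_mean_activity.astype(float)
    act_c = act - act.mean()
    y_vec = y.loc[act.index].to_numpy(dtype=float)
    if covariates is not None:
        xc = sm.add_constant(covariates.loc[act.index].to_numpy(dtype=float))
        y_vec = y_vec - xc @ np.linalg.lstsq(xc, y_vec, rcond=None)[0]
    pl2 = (pl.loc[act.index] ** 2).to_numpy()
    x = np.column_stack([np.ones(len(act)), act_c, pl2, act_c * pl2])
    res = sm.OLS(y_vec, x).fit()
    if pl_grid is None:
        pl_grid = np.linspace(float(pl.min()), float(pl.max()), 50)
    sd = float(act_c.std(ddof=1))
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    rows = []
    for label, a in (("high", sd), ("low", -sd)):
        g2 = np.asarray(pl_grid) ** 2
        xg = np.column_stack([np.ones(g2.size), np.full(g2.size, a), g2, a * g2])
        pred = xg @ res.params
        se = np.sqrt(np.einsum("ij,jk,ik->i", xg, res.cov_params(), xg))
        rows.append(
            pd.DataFrame(
                {
                    "pl": pl_grid,
                    "activity": label,
                    "predicted": pred,
                    "ci_low": pred - zcrit * se,
                    "ci_high": pred + zcrit * se,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
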