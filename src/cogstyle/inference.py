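"""Mixed-effects group comparisons for game metrics and motor summaries.

All trial-level game analyses share one model specification: fixed effects
for limb-difference group (LD vs NLD), age group (child vs adult) and their
interaction; age in years and the median motor reaction time as covariates
with separate slopes per age group (each centered within its age group, so
the group main effects are evaluated at group-typical covariate values);
and crossed random intercepts for participants and levels.  Links follow
the response: identity for times, log for attempt counts (a Gaussian model
of log counts by default; Poisson by flag), logit for solving.

Tests are likelihood-ratio chi-squares from nested maximum-likelihood
refits: the interaction is tested against the main-effects model, and each
main effect by dropping it from the main-effects model.  Reported effect
estimates come from the main-effects model, matching the convention of
quoting a single additive (or multiplicative, after exponentiation) group
offset.  Timing and attempt analyses condition on solved levels by default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from cogstyle._glmm import MixedGLM, lr_test
from cogstyle.logdata import Dataset
from cogstyle.metrics import level_metrics_frame, motor_summary_frame

TIMING_RESPONSES = ("time_to_first", "mean_gap", "time_to_solution")


@dataclass
class FitResult:
    """Coefficients, intervals and term tests of one fitted model."""

    response: str
    method: str
    params: pd.Series
    conf_int: pd.DataFrame            # lower/upper, 95%
    lrt: pd.DataFrame                 # term, chi2, df, p
    n_obs: int
    converged: bool
    extra: dict = field(default_factory=dict)

    @property
    def limb_effect(self) -> float:
        """The LD-vs-NLD coefficient from the main-effects model."""
        return float(self.params["limb_LD"])

    def limb_effect_ci(self) -> tuple[float, float]:
        return (float(self.conf_int.loc["limb_LD", "lower"]),
                float(self.conf_int.loc["limb_LD", "upper"]))

    def summary(self) -> str:
        lines = [f"{self.method} model of {self.response} (n = {self.n_obs})"]
        for name in self.params.index:
            lines.append(
                f"  {name}: {self.params[name]: .4f} "
                f"[{self.conf_int.loc[name, 'lower']: .4f}, "
                f"{self.conf_int.loc[name, 'upper']: .4f}]")
        for r in self.lrt.itertuples():
            stat_name = "F" if self.method == "OLS" else "chi2"
            lines.append(f"  {r.term}: {stat_name}({r.df:g}) = {r.stat:.2f}, "
                         f"p = {r.p:.4g}")
        if not self.converged:
            lines.append("  warning: a fit did not converge")
        return "\n".join(lines)


# ---- design matrices -----------------------------------------------------


def _analysis_frame(dataset: Dataset, solved_only: bool) -> pd.DataFrame:
    """One row per participant x level with metrics, covariates and labels."""
    lm = level_metrics_frame(dataset)
    ms = motor_summary_frame(dataset)[["participant_id", "median_rt"]]
    df = lm.merge(ms, on="participant_id", how="left")
    if solved_only:
        df = df[df["solved"]]
    return df.reset_index(drop=True)


def _center_within(df: pd.DataFrame, col: str) -> pd.Series:
    return df[col] - df.groupby("age_group")[col].transform("mean")


def _design(df: pd.DataFrame, interaction: bool, covariates: bool = True,
            drop: str | None = None) -> pd.DataFrame:
    """Fixed-effects design matrix for the shared model specification.

    ``drop`` removes a main effect ("limb" or "age") for nested LRT fits.
    """
    ld = (df["limb_group"] == "LD").astype(float)
    child = (df["age_group"] == "child").astype(float)
    X = pd.DataFrame({"Intercept": np.ones(len(df))}, index=df.index)
    if drop != "limb":
        X["limb_LD"] = ld
    if drop != "age":
        X["age_child"] = child
    if interaction:
        X["limb_LD:age_child"] = ld * child
    if covariates:
        age_c = _center_within(df, "age_years")
        X["age_c:child"] = age_c * child
        X["age_c:adult"] = age_c * (1.0 - child)
        if "median_rt" in df.columns and df["median_rt"].notna().all():
            rt_c = _center_within(df, "median_rt")
            X["rt_c:child"] = rt_c * child
            X["rt_c:adult"] = rt_c * (1.0 - child)
    # single-age-group data: drop empty/constant columns
    keep = [c for c in X.columns
            if c == "Intercept" or X[c].nunique() > 1]
    return X[keep]


# ---- Gaussian mixed models (statsmodels MixedLM, crossed intercepts) ----


def _fit_lmm(y: np.ndarray, X: pd.DataFrame, df: pd.DataFrame):
    """ML fit of a Gaussian mixed model with crossed participant/level
    intercepts, via variance components on a single spanning group."""
    safe = {c: c.replace(":", "_x_").replace("Intercept", "const")
            for c in X.columns}
    data = X.rename(columns=safe).copy()
    data["_y"] = y
    data["participant_id"] = df["participant_id"].to_numpy()
    data["level_id"] = df["level_id"].to_numpy()
    formula = "_y ~ 0 + " + " + ".join(safe[c] for c in X.columns)
    vc = {"participant": "0 + C(participant_id)", "level": "0 + C(level_id)"}
    model = sm.MixedLM.from_formula(formula, data, groups=np.ones(len(data)),
                                    vc_formula=vc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=False, method="bfgs", maxiter=2000)
        except Exception:
            res = None
        if res is None or not res.converged:
            # variance components near zero can stall gradient methods
            alt = model.fit(reml=False, method="powell", maxiter=2000)
            if res is None or alt.llf >= res.llf:
                res = alt
    res._name_map = {v: k for k, v in safe.items()}
    return res


def _lmm_lrts(df: pd.DataFrame, y: np.ndarray,
              covariates: bool = True) -> tuple[object, pd.DataFrame, bool]:
    """Main-effects fit plus LRTs for limb, age and their interaction."""
    def fit(interaction, drop=None):
        X = _design(df, interaction=interaction, covariates=covariates,
                    drop=drop)
        return _fit_lmm(y, X, df)

    mains = fit(False)
    full = fit(True)
    rows = []
    converged = bool(getattr(mains, "converged", True))
    two_groups = {"limb": df["limb_group"].nunique() == 2,
                  "age": df["age_group"].nunique() == 2}
    if two_groups["limb"]:
        red = fit(False, drop="limb")
        chi2 = max(0.0, 2.0 * (mains.llf - red.llf))
        rows.append(("limb", chi2, 1, float(stats.chi2.sf(chi2, 1))))
    if two_groups["age"]:
        red = fit(False, drop="age")
        chi2 = max(0.0, 2.0 * (mains.llf - red.llf))
        rows.append(("age", chi2, 1, float(stats.chi2.sf(chi2, 1))))
    if two_groups["limb"] and two_groups["age"]:
        chi2 = max(0.0, 2.0 * (full.llf - mains.llf))
        rows.append(("limb:age", chi2, 1, float(stats.chi2.sf(chi2, 1))))
    lrt = pd.DataFrame(rows, columns=["term", "stat", "df", "p"])
    return mains, lrt, converged


def _lmm_result(response: str, df: pd.DataFrame, y: np.ndarray,
                covariates: bool = True) -> FitResult:
    mains, lrt, converged = _lmm_lrts(df, y, covariates=covariates)
    k = len(mains.fe_params)
    name_map = getattr(mains, "_name_map", {})
    params = pd.Series(np.asarray(mains.fe_params),
                       index=[name_map.get(n, n)
                              for n in mains.fe_params.index])
    bse = np.asarray(mains.bse_fe)
    z = stats.norm.ppf(0.975)
    ci = pd.DataFrame({"lower": params - z * bse, "upper": params + z * bse})
    return FitResult(response=response, method="Gaussian mixed (ML)",
                     params=params, conf_int=ci, lrt=lrt, n_obs=len(df),
                     converged=converged,
                     extra={"re_var": dict(zip(
                         ["participant", "level"],
                         np.asarray(mains.vcomp, dtype=float))),
                         "resid_var": float(mains.scale),
                         "wald_bse": pd.Series(bse, index=params.index),
                         "llf": float(mains.llf), "n_params": k})


# ---- public model fits ---------------------------------------------------


def fit_timing_model(dataset: Dataset, response: str = "time_to_first",
                     solved_only: bool = True,
                     covariates: bool = True) -> FitResult:
    """Gaussian mixed model of a timing metric (seconds).

    The LD coefficient is the additive limb-difference offset; LRTs test
    limb, age and their interaction with 1 df each.
    """
    if response not in TIMING_RESPONSES:
        raise ValueError(f"response must be one of {TIMING_RESPONSES}")
    df = _analysis_frame(dataset, solved_only)
    df = df[df[response].notna()].reset_index(drop=True)
    _check_cells(df)
    return _lmm_result(response, df, df[response].to_numpy(float),
                       covariates=covariates)


def fit_attempts_model(dataset: Dataset, solved_only: bool = True,
                       covariates: bool = True,
                       family: str = "lognormal") -> FitResult:
    """Model of attempts-to-solution; the limb effect is multiplicative.

    Default: Gaussian mixed model of log(n_attempts); ``family="poisson"``
    switches to a Poisson GLMM (log link, Laplace ML).  Either way the
    limb effect is reported as exp(coefficient) with CI in
    ``extra["ratio"]``.
    """
    df = _analysis_frame(dataset, solved_only)
    df = df[df["n_attempts"] >= 1].reset_index(drop=True)
    _check_cells(df)
    if family == "lognormal":
        res = _lmm_result("n_attempts", df,
                          np.log(df["n_attempts"].to_numpy(float)),
                          covariates=covariates)
    elif family == "poisson":
        res = _glmm_result("n_attempts", df,
                           df["n_attempts"].to_numpy(float),
                           family="poisson", covariates=covariates)
    else:
        raise ValueError("family must be 'lognormal' or 'poisson'")
    if "limb_LD" in res.params.index:
        lo, hi = res.limb_effect_ci()
        res.extra["ratio"] = math.exp(res.limb_effect)
        res.extra["ratio_ci"] = (math.exp(lo), math.exp(hi))
    return res


def _glmm_result(response: str, df: pd.DataFrame, y: np.ndarray,
                 family: str, covariates: bool = True) -> FitResult:
    def fit(interaction, drop=None):
        X = _design(df, interaction=interaction, covariates=covariates,
                    drop=drop)
        return MixedGLM(y, X, {"participant": df["participant_id"],
                               "level": df["level_id"]},
                        family=family).fit()

    mains = fit(False)
    full = fit(True)
    rows = []
    if df["limb_group"].nunique() == 2:
        c, d, p = lr_test(mains, fit(False, drop="limb"), df=1)
        rows.append(("limb", c, d, p))
    if df["age_group"].nunique() == 2:
        c, d, p = lr_test(mains, fit(False, drop="age"), df=1)
        rows.append(("age", c, d, p))
    if df["limb_group"].nunique() == 2 and df["age_group"].nunique() == 2:
        c, d, p = lr_test(full, mains, df=1)
        rows.append(("limb:age", c, d, p))
    return FitResult(
        response=response, method=f"{family} mixed (Laplace ML)",
        params=mains.params, conf_int=mains.conf_int(),
        lrt=pd.DataFrame(rows, columns=["term", "stat", "df", "p"]),
        n_obs=mains.n_obs,
        converged=mains.converged and not mains.separation,
        extra={"re_sd": mains.re_sd, "llf": mains.llf,
               "separation": mains.separation,
               "fitted_mean": mains.fitted_mean()})


def fit_solution_model(dataset: Dataset, covariates: bool = True) -> FitResult:
    """Logistic mixed model of level solving (all levels, no conditioning)."""
    df = _analysis_frame(dataset, solved_only=False)
    _check_cells(df)
    y = df["solved"].astype(float).to_numpy()
    res = _glmm_result("solved", df, y, family="binomial",
                       covariates=covariates)
    # per-year age slopes (log-odds) are of direct interest here
    for col in ("age_c:child", "age_c:adult"):
        if col in res.params.index:
            res.extra[f"log_odds_{col}"] = float(res.params[col])
    return res


def fit_motor_lm(dataset: Dataset, response: str = "median_rt",
                 interaction: bool = False) -> FitResult:
    """Ordinary linear model of a motor pre-test summary.

    Response is the participant's median reaction time (s) or median click
    error (px); predictors are limb group, age group and age in years with
    separate slopes per age group.  F statistics come from nested-model
    comparisons.
    """
    if response not in ("median_rt", "median_error"):
        raise ValueError("response must be 'median_rt' or 'median_error'")
    df = motor_summary_frame(dataset)
    if len(df) == 0:
        raise ValueError("dataset has no motor trials")

    def fit(inter, drop=None):
        X = _design(df, interaction=inter, covariates=True, drop=drop)
        # motor models do not include the motor covariate columns
        X = X[[c for c in X.columns if not c.startswith("rt_c")]]
        model = sm.OLS(df[response].to_numpy(float), X)
        return model.fit()

    mains = fit(interaction)
    rows = []

    def ftest(full_res, red_res, term):
        f, p, d = full_res.compare_f_test(red_res)
        rows.append((term, float(f), float(full_res.df_resid), float(p)))

    if df["limb_group"].nunique() == 2:
        ftest(mains, fit(interaction, drop="limb"), "limb")
    if df["age_group"].nunique() == 2:
        ftest(mains, fit(interaction, drop="age"), "age")
    if (not interaction and df["limb_group"].nunique() == 2
            and df["age_group"].nunique() == 2):
        inter_res = fit(True)
        ftest(inter_res, mains, "limb:age")
    ci = mains.conf_int()
    ci.columns = ["lower", "upper"]
    return FitResult(
        response=response, method="OLS",
        params=mains.params, conf_int=ci,
        lrt=pd.DataFrame(rows, columns=["term", "stat", "df", "p"]),
        n_obs=int(mains.nobs), converged=True,
        extra={"df_resid": float(mains.df_resid),
               "rank_deficient": bool(np.linalg.matrix_rank(
                   mains.model.exog) < mains.model.exog.shape[1])})


def _check_cells(df: pd.DataFrame) -> None:
    if df["level_id"].nunique() < 2:
        raise ValueError("need at least 2 levels")
    counts = df.groupby(["age_group", "limb_group"])["participant_id"].nunique()
    if (counts < 2).any():
        raise ValueError(
            f"need >= 2 participants per group cell, got:\n{counts}")
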