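"""Strategy-covariate inference on performance and performance deviance.

Covariates (entropy score S, patch residence time, activity, vessel length,
displacement) are standardized to zero mean and unit SD; quadratic terms
are squares of the standardized linear terms so the "humped strategy" test
is interpretable around the fleet mean.  Pre-disturbance performance is
regressed on strategy by OLS; post-disturbance performance deviance by a
linear mixed model with a per-vessel random intercept (trips are nested in
vessels).  Stepwise backward selection drops terms only when both AIC and
BIC do not increase, and never drops a linear term while its quadratic
partner remains.  The growing-window analysis refits the deviance model on
nested post-closure subsets to trace effect dissipation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

log = logging.getLogger(__name__)

#: linear covariates of the strategy models, in canonical order
LINEAR_TERMS = ["S", "prt", "activity", "length_m", "displacement"]
#: terms carrying a quadratic partner
QUADRATIC_OF = {"S_sq": "S_z", "prt_sq": "prt_z"}

EQ5_TERMS = ["S_z", "S_sq", "prt_z", "prt_sq", "activity_z", "length_m_z"]
EQ6_TERMS = [*EQ5_TERMS, "displacement_z"]


def scale_covariates(profiles: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Standardize covariates; quadratics are squares of the z-scores.

    Each listed column ``c`` present in ``profiles`` gains ``c_z`` with
    sample mean 0 and sample SD 1 (ddof=1); ``S`` and ``prt`` additionally
    gain ``S_sq`` / ``prt_sq``.  Original values are retained alongside.
    Zero-variance columns raise, naming the column.
    """
    if len(profiles) < 3:
        raise ValueError("covariate scaling needs at least 3 vessels")
    columns = [c for c in (columns or LINEAR_TERMS) if c in profiles.columns]
    out = profiles.copy()
    for c in columns:
        x = out[c].to_numpy(float)
        sd = np.std(x, ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"covariate {c!r} has zero variance; cannot standardize")
        out[f"{c}_z"] = (x - x.mean()) / sd
    for quad, lin in QUADRATIC_OF.items():
        if lin in out.columns:
            out[quad] = out[lin] ** 2
    return out


class CovariateScaler(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer wrapping :func:`scale_covariates`.

    Stores per-column means and SDs at ``fit`` so new vessels can be placed
    on the fitted scale.
    """

    def __init__(self, columns=None):
        self.columns = columns

    def fit(self, X: pd.DataFrame, y=None):
        cols = [c for c in (self.columns or LINEAR_TERMS) if c in X.columns]
        if len(X) < 3:
            raise ValueError("covariate scaling needs at least 3 vessels")
        self.means_ = {}
        self.sds_ = {}
        for c in cols:
            x = X[c].to_numpy(float)
            sd = np.std(x, ddof=1)
            if sd == 0 or not np.isfinite(sd):
                raise ValueError(f"covariate {c!r} has zero variance; cannot standardize")
            self.means_[c] = float(x.mean())
            self.sds_[c] = float(sd)
        self.columns_ = cols
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "means_")
        out = X.copy()
        for c in self.columns_:
            out[f"{c}_z"] = (out[c].to_numpy(float) - self.means_[c]) / self.sds_[c]
        for quad, lin in QUADRATIC_OF.items():
            if lin in out.columns:
                out[quad] = out[lin] ** 2
        return out


@dataclass
class RegressionResult:
    """Tidy fixed-effect table plus information criteria for one fit."""

    terms: list
    table: pd.DataFrame  # term, estimate, se, stat, p, lo95, hi95
    aic: float
    bic: float
    n: int
    df_resid: float
    random_intercept_var: float | None = None
    singular: bool = False
    raw: object = field(default=None, repr=False)

    def coef(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "estimate"])

    def pvalue(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "p"])

    def conf_int(self, term: str) -> tuple:
        row = self.table.set_index("term").loc[term]
        return (float(row["lo95"]), float(row["hi95"]))


def _ols_result(y: np.ndarray, X: pd.DataFrame, terms: list) -> RegressionResult:
    design = sm.add_constant(X[terms].to_numpy(float)) if terms else np.ones((len(y), 1))
    res = sm.OLS(y, design).fit()
    names = ["const", *terms]
    ci = res.conf_int()
    table = pd.DataFrame(
        {
            "term": names,
            "estimate": res.params,
            "se": res.bse,
            "stat": res.tvalues,
            "p": res.pvalues,
            "lo95": ci[:, 0],
            "hi95": ci[:, 1],
        }
    )
    return RegressionResult(
        terms=list(terms),
        table=table,
        aic=float(res.aic),
        bic=float(res.bic),
        n=int(res.nobs),
        df_resid=float(res.df_resid),
        raw=res,
    )


def fit_strategy_performance(profiles: pd.DataFrame, performance: pd.Series, terms=None) -> RegressionResult:
    """OLS of undisturbed vessel performance on strategy covariates.

    One row per vessel: ``P_i = a + b1*S + b2*S^2 + b3*prt + b4*prt^2 +
    b5*activity + b6*length + eps`` on the standardized scale.
    """
    terms = list(terms) if terms is not None else [t for t in EQ5_TERMS if t in profiles.columns]
    data = profiles.copy()
    P = performance.reindex(data["vessel_id"]) if isinstance(performance, pd.Series) else pd.Series(
        np.asarray(performance, float), index=data.index
    )
    y = np.asarray(P, float)
    ok = np.isfinite(y)
    data = data.loc[ok]
    y = y[ok]
    if len(data) <= len(terms) + 1:
        raise ValueError("too few vessels for the requested model")
    return _ols_result(y, data, terms)


def fit_eq5(profiles: pd.DataFrame, performance) -> RegressionResult:
    """Alias for :func:`fit_strategy_performance` with the full term set."""
    return fit_strategy_performance(profiles, performance)


class DevianceMixedModel(BaseEstimator):
    """Linear mixed model for trip-level deviance with vessel random intercepts.

    Fixed effects: the strategy covariates (entropy and PRT with quadratic
    partners, activity, length, displacement).  Random: a per-vessel
    intercept ``b_0i ~ Normal(0, sigma_i^2)`` absorbing repeated trips.
    Fitted by restricted maximum likelihood (``reml=True``) for reporting;
    maximum likelihood is used when AIC/BIC comparisons are needed.  A
    singular (boundary) random-intercept variance triggers an OLS fallback
    with the variance pinned at zero, flagged via ``singular_``.

    Wald z statistics, p values and 95% CIs are reported for fixed effects.
    """

    def __init__(self, terms=None, reml: bool = True):
        self.terms = terms
        self.reml = reml

    def fit(self, data: pd.DataFrame, response: str = "deltaP", groups: str = "vessel_id"):
        terms = list(self.terms) if self.terms is not None else [t for t in EQ6_TERMS if t in data.columns]
        data = data.dropna(subset=[response, *terms])
        if data[groups].nunique() < 2:
            raise ValueError("mixed model needs at least 2 vessels")
        y = data[response].to_numpy(float)
        X = sm.add_constant(data[terms].to_numpy(float))
        names = ["const", *terms]
        singular = False
        res = None
        try:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                md = sm.MixedLM(y, X, groups=data[groups].to_numpy())
                res = md.fit(reml=self.reml, method="lbfgs")
            re_var = float(res.cov_re.iloc[0, 0])
            if not np.isfinite(re_var) or re_var < 1e-10 or not res.converged:
                singular = True
        except Exception:  # singular fit or optimizer failure
            singular = True
        if singular:
            ols = _ols_result(y, data, terms)
            ols.random_intercept_var = 0.0
            ols.singular = True
            self.result_ = ols
            self._store(ols, names, data, terms, groups)
            return self
        params = np.asarray(res.fe_params)
        se = np.asarray(res.bse_fe)
        z = params / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        lo = params - 1.959963984540054 * se
        hi = params + 1.959963984540054 * se
        table = pd.DataFrame(
            {"term": names, "estimate": params, "se": se, "stat": z, "p": p, "lo95": lo, "hi95": hi}
        )
        # per-vessel predicted intercepts
        ranef = pd.Series({k: float(v.iloc[0]) for k, v in res.random_effects.items()}, name="b0")
        rr = RegressionResult(
            terms=terms,
            table=table,
            aic=float(res.aic) if np.isfinite(res.aic) else np.nan,
            bic=float(res.bic) if np.isfinite(res.bic) else np.nan,
            n=int(res.nobs),
            df_resid=float(res.df_resid),
            random_intercept_var=float(res.cov_re.iloc[0, 0]),
            raw=res,
        )
        self.result_ = rr
        self.ranef_ = ranef
        self._store(rr, names, data, terms, groups)
        return self

    def _store(self, rr: RegressionResult, names, data, terms, groups):
        self.fixef_ = rr.table
        self.terms_ = terms
        self.re_var_ = rr.random_intercept_var
        self.singular_ = rr.singular
        self.aic_ = rr.aic
        self.bic_ = rr.bic
        self.n_vessels_ = int(data[groups].nunique())
        self.n_trips_ = len(data)


def fit_deviance_model(data: pd.DataFrame, terms=None, reml: bool = True) -> RegressionResult:
    """Thin functional wrapper over :class:`DevianceMixedModel`."""
    return DevianceMixedModel(terms=terms, reml=reml).fit(data).result_


def fit_eq6(deviance_records: pd.DataFrame, covariates: pd.DataFrame) -> RegressionResult:
    """Full deviance model on merged records and standardized covariates."""
    merged = deviance_records.merge(covariates, on="vessel_id", how="inner")
    return fit_deviance_model(merged)


def stepwise_select(
    fit_fn,
    terms: list,
    protected=(),
    hierarchy: dict | None = None,
) -> tuple:
    """Backward stepwise selection requiring both AIC and BIC not to increase.

    ``fit_fn(terms) -> object with .aic and .bic`` (a
    :class:`RegressionResult` works).  At each round every droppable term is
    tried; drops qualify when neither criterion increases, and the drop
    with the lowest AIC (ties: the earlier term) is taken.  ``hierarchy``
    maps quadratic terms to their linear partners: a linear term is only
    droppable once its quadratic partner is gone.  Returns
    ``(selected_terms, fitted)``.
    """
    hierarchy = hierarchy if hierarchy is not None else QUADRATIC_OF
    linear_of = {lin: quad for quad, lin in hierarchy.items()}
    current = list(terms)
    fitted = fit_fn(current)
    while True:
        best = None
        for term in current:
            if term in protected:
                continue
            quad = linear_of.get(term)
            if quad is not None and quad in current:
                continue  # keep the linear term while its quadratic remains
            cand_terms = [t for t in current if t != term]
            try:
                cand = fit_fn(cand_terms)
            except Exception:
                continue
            if cand.aic <= fitted.aic + 1e-9 and cand.bic <= fitted.bic + 1e-9:
                if best is None or cand.aic < best[1].aic:
                    best = (term, cand)
        if best is None:
            return current, fitted
        term, fitted = best
        current = [t for t in current if t != term]
        log.info("stepwise: dropped %s (AIC %.2f, BIC %.2f)", term, fitted.aic, fitted.bic)


def fleet_shift_test(metric_before, metric_during) -> dict:
    """One-way ANOVA comparing a strategy metric before vs during the closure.

    Returns F, degrees of freedom, p and the two group means.  Used to test
    whether entropy-dependent exit raises the mean entropy of the active
    fleet during the disturbance.
    """
    a = np.asarray(metric_before, float)
    b = np.asarray(metric_during, float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if np.array_equal(a, b):
        F, p = 0.0, 1.0
    else:
        F, p = stats.f_oneway(a, b)
    return {
        "F": float(F),
        "df": (1, len(a) + len(b) - 2),
        "p": float(p),
        "mean_before": float(a.mean()),
        "mean_during": float(b.mean()),
        "n_before": len(a),
        "n_during": len(b),
    }


def growing_window(
    deviance_records: pd.DataFrame,
    covariates: pd.DataFrame,
    step: float = 10.0,
    horizon: float = 50.0,
    terms=None,
    reml: bool = True,
) -> pd.DataFrame:
    """Refit the deviance model on nested post-closure windows.

    Windows are ``[0, step], [0, 2*step], ..., [0, horizon]`` days since
    closure; each refit reports every term's estimate, SE and 95% CI plus
    the window's trip count.  Windows with too few trips or vessels to fit
    are skipped with a flag row (NaN estimates).
    """
    merged = deviance_records.merge(covariates, on="vessel_id", how="inner")
    if "days_since_closure" not in merged.columns:
        raise ValueError("deviance records need a days_since_closure column")
    terms = list(terms) if terms is not None else [t for t in EQ6_TERMS if t in merged.columns]
    rows = []
    ends = np.arange(step, horizon + 1e-9, step)
    for end in ends:
        sub = merged.loc[merged["days_since_closure"] <= end]
        if sub["vessel_id"].nunique() < 2 or len(sub) < len(terms) + 3:
            log.warning("growing window [0, %g]: too few trips to fit; skipped", end)
            rows.append(
                {
                    "window_end_day": float(end),
                    "term": None,
                    "estimate": np.nan,
                    "se": np.nan,
                    "lo95": np.nan,
                    "hi95": np.nan,
                    "n_trips": len(sub),
                    "singular": True,
                }
            )
            continue
        res = DevianceMixedModel(terms=terms, reml=reml).fit(sub).result_
        for _, r in res.table.iterrows():
            rows.append(
                {
                    "window_end_day": float(end),
                    "term": r["term"],
                    "estimate": float(r["estimate"]),
                    "se": float(r["se"]),
                    "lo95": float(r["lo95"]),
                    "hi95": float(r["hi95"]),
                    "n_trips": res.n,
                    "singular": res.singular,
                }
            )
    return pd.DataFrame(rows)


def plot_growing_window(window_table: pd.DataFrame, terms=("S_z", "displacement_z"), ax=None):
    """Ribbon plot of coefficient trajectories across growing windows."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for term in terms:
        sub = window_table.loc[window_table["term"] == term].sort_values("window_end_day")
        if not len(sub):
            continue
        ax.plot(sub["window_end_day"], sub["estimate"], marker="o", label=term)
        ax.fill_between(sub["window_end_day"], sub["lo95"], sub["hi95"], alpha=0.25)
    ax.axhline(0.0, color="k", lw=0.8, ls="--")
    ax.set_xlabel("days since closure (window end)")
    ax.set_ylabel("coefficient (deviance per SD)")
    ax.legend()
    return ax
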