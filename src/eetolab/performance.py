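"""Business-as-usual revenue model and counterfactual performance deviance.

Trip revenue during the undisturbed period is modeled as

    Ru_it = P_i + beta1 * D_it + beta2 * F_-it + eps_it

where ``P_i`` is a vessel-identity fixed effect (the vessel's mean
performance), ``D_it`` the trip duration in days and ``F_-it`` the
leave-one-out fleet performance index: the mean revenue of all other
vessels' trips landing in the two weeks after trip ``t``, which absorbs
shared temporal shocks (seasonality, weather, prices).

During the disturbance the measured performance strips the duration and
fleet terms from observed revenue,

    Md_it = Rd_it - beta1_hat * D_it - beta2_hat * F_-it,

and is compared with the expected performance ``Ed_it`` (the vessel's
business-as-usual performance component) through the standardized deviance

    dP_it = Md_it / Ed_it - 1,

which is zero in expectation when the vessel performs exactly as the
business-as-usual model predicts.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from eetolab.errors import SchemaError

log = logging.getLogger(__name__)

_TRIP_COLS = ["vessel_id", "trip_id", "landing_date", "duration_days", "revenue"]


def _check_trips(trips: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _TRIP_COLS if c not in trips.columns]
    if missing:
        raise SchemaError(f"trip table is missing columns: {missing}")
    out = trips.copy()
    out["landing_date"] = pd.to_datetime(out["landing_date"], utc=True)
    return out


def fleet_performance(
    trips: pd.DataFrame,
    window_days: float = 14.0,
    reference: pd.DataFrame | None = None,
    symmetric: bool = False,
) -> pd.Series:
    """Leave-one-out fleet performance index ``F_-it`` per trip.

    For trip ``t`` of vessel ``i``: the mean raw revenue of all trips by
    *other* vessels landing in the half-open window ``(t, t + window_days]``
    (or ``[t - window_days/2, t + window_days/2]`` when ``symmetric``).
    ``reference`` supplies the pool of trips the index is computed over
    (defaults to ``trips`` itself), so disturbed trips can be indexed
    against the full logbook.  Trips with no qualifying contemporaneous trip
    get NaN and are dropped from modeling downstream (logged).
    """
    trips = _check_trips(trips)
    pool = _check_trips(reference) if reference is not None else trips

    t_days = trips["landing_date"].astype("int64").to_numpy() / 86.4e12
    p_days = pool["landing_date"].astype("int64").to_numpy() / 86.4e12
    p_rev = pool["revenue"].to_numpy()
    p_vid = pool["vessel_id"].to_numpy()

    order = np.argsort(p_days, kind="mergesort")
    p_days_s = p_days[order]
    p_rev_s = p_rev[order]
    p_vid_s = p_vid[order]
    csum = np.concatenate([[0.0], np.cumsum(p_rev_s)])

    if symmetric:
        lo_t = t_days - window_days / 2.0
        hi_t = t_days + window_days / 2.0
        lo_side = "left"
    else:
        lo_t = t_days
        hi_t = t_days + window_days
        lo_side = "right"  # half-open (t, t + w]

    lo = np.searchsorted(p_days_s, lo_t, side=lo_side)
    hi = np.searchsorted(p_days_s, hi_t, side="right")
    tot_sum = csum[hi] - csum[lo]
    tot_n = hi - lo

    # subtract vessel i's own trips inside the window
    own_sum = np.zeros(len(trips))
    own_n = np.zeros(len(trips), dtype=int)
    by_vessel = {}
    for vid in np.unique(p_vid_s):
        m = p_vid_s == vid
        d = p_days_s[m]
        r = p_rev_s[m]
        by_vessel[vid] = (d, np.concatenate([[0.0], np.cumsum(r)]))
    t_vid = trips["vessel_id"].to_numpy()
    for j in range(len(trips)):
        entry = by_vessel.get(t_vid[j])
        if entry is None:
            continue
        d, c = entry
        a = np.searchsorted(d, lo_t[j], side=lo_side)
        b = np.searchsorted(d, hi_t[j], side="right")
        own_sum[j] = c[b] - c[a]
        own_n[j] = b - a

    n_other = tot_n - own_n
    with np.errstate(invalid="ignore", divide="ignore"):
        F = np.where(n_other > 0, (tot_sum - own_sum) / np.where(n_other == 0, 1, n_other), np.nan)
    n_missing = int(np.isnan(F).sum())
    if n_missing:
        log.info("%d trip(s) have no contemporaneous trips; fleet index undefined", n_missing)
    return pd.Series(F, index=trips.index, name="fleet_index")


def window_bias_check(trips: pd.DataFrame, window_days: float = 14.0) -> dict:
    """Correlation between the skewed- and symmetric-window fleet indices.

    Computes ``F_-it`` with the trailing window and with a centred window of
    the same total width, and returns the Pearson r, t statistic and df over
    trips where both are defined.  Degenerate (constant) indices yield
    ``r = nan``.
    """
    skew = fleet_performance(trips, window_days=window_days)
    symm = fleet_performance(trips, window_days=window_days, symmetric=True)
    ok = skew.notna() & symm.notna()
    a = skew[ok].to_numpy()
    b = symm[ok].to_numpy()
    if len(a) < 3:
        raise ValueError("window bias check needs at least 3 paired values")
    if np.std(a) == 0 or np.std(b) == 0:
        return {"r": float("nan"), "t": float("nan"), "df": len(a) - 2, "n": len(a)}
    r, p = stats.pearsonr(a, b)
    df = len(a) - 2
    t = r * np.sqrt(df / max(1e-300, 1.0 - r**2))
    return {"r": float(r), "t": float(t), "df": df, "p": float(p), "n": len(a)}


def prune_boundary_trips(trips: pd.DataFrame, closure_start, window_days: float = 14.0) -> pd.DataFrame:
    """Drop trips landing in the ``window_days`` immediately before the closure.

    Their trailing fleet-index windows would straddle the closure onset and
    mix disturbed revenues into the undisturbed index.
    """
    trips = _check_trips(trips)
    start = pd.Timestamp(closure_start)
    if start.tzinfo is None:
        start = start.tz_localize("UTC")
    lo = start - pd.Timedelta(days=window_days)
    drop = (trips["landing_date"] >= lo) & (trips["landing_date"] < start)
    if drop.any():
        log.info("pruned %d boundary trip(s) landing within %s days before the closure", int(drop.sum()), window_days)
    return trips.loc[~drop].copy()


def remove_revenue_outliers(trips: pd.DataFrame, factor: float = 5.0) -> tuple:
    """Iteratively remove top revenues exceeding ``factor`` x the next largest.

    Returns ``(trips, removed)``.  Generalizes a manual single-outlier
    screen into an unattended rule: while the largest revenue exceeds
    ``factor`` times the second largest, it is removed.
    """
    trips = trips.copy()
    removed = []
    while len(trips) >= 2:
        top2 = trips["revenue"].nlargest(2)
        if top2.iloc[0] > factor * top2.iloc[1]:
            removed.append(trips.loc[top2.index[0]])
            trips = trips.drop(index=top2.index[0])
        else:
            break
    if removed:
        log.info("removed %d revenue outlier(s) (> %.1fx the next largest)", len(removed), factor)
    removed_df = pd.DataFrame(removed) if removed else trips.iloc[0:0]
    return trips, removed_df


class UndisturbedRevenueModel(BaseEstimator, RegressorMixin):
    """Linear business-as-usual revenue model with vessel fixed effects.

    ``fit`` estimates ``Ru_it = P_i + beta1 * D_it + beta2 * F_-it + eps``
    by OLS with vessel-identity dummies.  Absolute per-vessel performance
    ``P_i`` is the reference-coded estimate plus the intercept, exposed in
    ``performance_``.  With ``link='log'`` the model is fitted to
    ``log(revenue)`` and all downstream deviance arithmetic stays on the
    log scale.

    Parameters
    ----------
    window_days : float
        Trailing fleet-index window (days), used when no index is supplied.
    link : str
        'identity' (default) or 'log'.
    min_trips : int
        Vessels with fewer undisturbed trips are excluded (logged).
    """

    def __init__(self, window_days: float = 14.0, link: str = "identity", min_trips: int = 2):
        self.window_days = window_days
        self.link = link
        self.min_trips = min_trips

    def fit(self, trips: pd.DataFrame, fleet_index: pd.Series | None = None):
        trips = _check_trips(trips)
        if fleet_index is None:
            fleet_index = fleet_performance(trips, window_days=self.window_days)
        F = pd.Series(np.asarray(fleet_index, float), index=trips.index)
        ok = F.notna()
        n_noF = int((~ok).sum())
        counts = trips.loc[ok, "vessel_id"].value_counts()
        keep_vessels = counts[counts >= self.min_trips].index
        dropped = counts[counts < self.min_trips]
        ok &= trips["vessel_id"].isin(keep_vessels)
        if n_noF or len(dropped):
            log.info(
                "undisturbed fit: dropped %d trips without fleet index, %d vessel(s) with < %d trips",
                n_noF,
                len(dropped),
                self.min_trips,
            )
        data = trips.loc[ok]
        if data["vessel_id"].nunique() < 2:
            raise ValueError("undisturbed model needs at least 2 vessels with enough trips")
        y = data["revenue"].to_numpy(float)
        if self.link == "log":
            if np.any(y <= 0):
                raise ValueError("log link requires strictly positive revenues")
            y = np.log(y)
        elif self.link != "identity":
            raise ValueError(f"unknown link {self.link!r}")
        vessels = pd.Categorical(data["vessel_id"])
        dummies = pd.get_dummies(vessels, drop_first=True, dtype=float)
        X = pd.concat(
            [
                pd.Series(1.0, index=data.index, name="const"),
                dummies.set_axis(data.index),
                data["duration_days"].rename("duration"),
                pd.Series(F.loc[data.index].to_numpy(), index=data.index, name="fleet"),
            ],
            axis=1,
        )
        res = sm.OLS(y, X.to_numpy()).fit()
        names = list(X.columns)
        params = pd.Series(res.params, index=names)
        self.result_ = res
        self.beta_duration_ = float(params["duration"])
        self.beta_fleet_ = float(params["fleet"])
        self.intercept_ = float(params["const"])
        levels = list(vessels.categories)
        perf = {levels[0]: self.intercept_}
        for lvl in levels[1:]:
            perf[lvl] = self.intercept_ + float(params[lvl])
        self.performance_ = pd.Series(perf, name="P")
        self.performance_.index.name = "vessel_id"
        self.resid_var_ = float(res.mse_resid)
        self.n_vessels_ = len(levels)
        self.n_trips_ = len(data)
        self.dropped_vessels_ = list(dropped.index)
        self.link_ = self.link
        return self

    def predict(self, trips: pd.DataFrame, fleet_index: pd.Series | None = None) -> np.ndarray:
        """Predicted revenue (or log revenue) per trip under business as usual."""
        check_is_fitted(self, "performance_")
        trips = _check_trips(trips)
        if fleet_index is None:
            raise ValueError("predict requires the trips' fleet index")
        P = self.performance_.reindex(trips["vessel_id"]).to_numpy()
        return (
            P
            + self.beta_duration_ * trips["duration_days"].to_numpy(float)
            + self.beta_fleet_ * np.asarray(fleet_index, float)
        )

    def summary_dict(self) -> dict:
        check_is_fitted(self, "performance_")
        ci = self.result_.conf_int()
        return {
            "link": self.link_,
            "beta_duration": self.beta_duration_,
            "beta_fleet": self.beta_fleet_,
            "beta_duration_ci": [float(ci[-2][0]), float(ci[-2][1])],
            "beta_fleet_ci": [float(ci[-1][0]), float(ci[-1][1])],
            "intercept": self.intercept_,
            "resid_var": self.resid_var_,
            "n_vessels": self.n_vessels_,
            "n_trips": self.n_trips_,
            "aic": float(self.result_.aic),
            "bic": float(self.result_.bic),
        }


def fit_undisturbed(trips: pd.DataFrame, fleet_index=None, window_days: float = 14.0, link: str = "identity") -> UndisturbedRevenueModel:
    """Thin functional wrapper over :class:`UndisturbedRevenueModel`."""
    return UndisturbedRevenueModel(window_days=window_days, link=link).fit(trips, fleet_index)


def compute_deviance(
    model: UndisturbedRevenueModel,
    disturbed_trips: pd.DataFrame,
    fleet_index: pd.Series | None = None,
    closure_start=None,
    include_trip_terms: bool = False,
) -> pd.DataFrame:
    """Standardized business-as-usual performance deviance per disturbed trip.

    ``Md = Rd - beta1_hat * D - beta2_hat * F`` (on the model's link scale);
    ``Ed`` is the vessel's absolute business-as-usual performance ``P_i``
    (the expected value of ``Md`` absent disturbance), so ``dP = Md/Ed - 1``
    is centred on zero under business as usual.  With
    ``include_trip_terms=True``, ``Ed`` is instead the full revenue
    prediction ``P_i + beta1*D + beta2*F`` (not centred; diagnostic only).

    Trips by vessels absent from the fitted model, or with non-positive
    ``Ed``, are excluded (logged).
    """
    check_is_fitted(model, "performance_")
    trips = _check_trips(disturbed_trips)
    if fleet_index is None:
        raise ValueError("compute_deviance requires the disturbed trips' fleet index")
    F = np.asarray(fleet_index, float)

    known = trips["vessel_id"].isin(model.performance_.index)
    ok = known & ~np.isnan(F)
    n_unknown = int((~known).sum())
    if n_unknown:
        log.info("excluded %d disturbed trip(s) by vessels absent from the undisturbed model", n_unknown)

    data = trips.loc[ok]
    Fd = F[np.asarray(ok)]
    rev = data["revenue"].to_numpy(float)
    if model.link_ == "log":
        rev = np.log(np.maximum(rev, 1e-12))
    D = data["duration_days"].to_numpy(float)
    Md = rev - model.beta_duration_ * D - model.beta_fleet_ * Fd
    P = model.performance_.reindex(data["vessel_id"]).to_numpy(float)
    Ed = P + (model.beta_duration_ * D + model.beta_fleet_ * Fd if include_trip_terms else 0.0)
    pos = Ed > 0
    if (~pos).any():
        log.info("excluded %d disturbed trip(s) with non-positive expected performance", int((~pos).sum()))
    out = pd.DataFrame(
        {
            "vessel_id": data["vessel_id"].to_numpy()[pos],
            "trip_id": data["trip_id"].to_numpy()[pos],
            "landing_date": data["landing_date"].to_numpy()[pos],
            "Md": Md[pos],
            "Ed": Ed[pos],
            "deltaP": Md[pos] / Ed[pos] - 1.0,
        }
    )
    if closure_start is not None:
        start = pd.Timestamp(closure_start)
        if start.tzinfo is None:
            start = start.tz_localize("UTC")
        out["days_since_closure"] = (
            (pd.to_datetime(out["landing_date"], utc=True) - start) / pd.Timedelta(days=1)
        )
    elif "days_since_closure" in disturbed_trips.columns:
        out["days_since_closure"] = disturbed_trips.loc[ok, "days_since_closure"].to_numpy()[pos]
    return out
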