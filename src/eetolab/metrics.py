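"""Explore-exploit strategy metrics and their diagnostics.

Two metrics summarize each vessel's strategy along its visitation series:

* **choice entropy** ``S`` — the Shannon entropy (base 2) of the empirical
  fished-location frequencies, computed cumulatively over the sequence; the
  trajectory's second-half mean (after a burn-in) is the strategy score;
* **patch residence time** ``prt`` — the mean duration of a fishing bout.

Supporting covariates: displacement (fraction of pre-closure fished cells
inside the closure polygon), activity (fishing days in a lagged window) and
vessel length.  Diagnostics: grid-size sensitivity of the entropy score,
the depth-confound regression, and the travel-cost (revenue per km)
regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from shapely import contains_xy
from shapely.geometry import Polygon

import statsmodels.api as sm

from eetolab.errors import ConfigurationError
from eetolab.grounds import GridSpec, build_grid, build_visitation_series
from eetolab.tracks import rhumb_distance

log = logging.getLogger(__name__)


@dataclass
class EntropyTrajectory:
    """Cumulative choice-entropy trajectory of one vessel.

    ``S[m-1]`` is the base-2 Shannon entropy of the location frequencies in
    the first ``m`` elements of the visitation series; ``N[m-1]`` counts the
    unique locations seen so far.
    """

    vessel_id: object
    S: np.ndarray
    N: np.ndarray

    def __len__(self) -> int:
        return len(self.S)


def entropy_trajectory(sequence, vessel_id=None) -> EntropyTrajectory:
    """Cumulative Shannon entropy (bits) over every prefix of a sequence.

    For each prefix length ``m`` the empirical frequencies ``f(j)`` of the
    distinct locations are formed and ``S_m = -sum_j f(j) log2 f(j)``.
    Computed incrementally in O(total prefix work) with exact frequency
    counts; matches a brute-force per-prefix computation bit-for-bit.
    """
    seq = list(sequence)
    if len(seq) == 0:
        raise ValueError("entropy trajectory of an empty sequence is undefined")
    counts: dict = {}
    S = np.empty(len(seq))
    N = np.empty(len(seq), dtype=int)
    # running sum of c*log2(c) over locations; S_m = log2(m) - sum/m
    clogc = 0.0
    for m, loc in enumerate(seq, start=1):
        c = counts.get(loc, 0)
        if c:
            clogc += (c + 1) * np.log2(c + 1) - c * np.log2(c)
        counts[loc] = c + 1
        N[m - 1] = len(counts)
        S[m - 1] = np.log2(m) - clogc / m
    S = np.maximum(S, 0.0)  # clip -0.0 / rounding at single-location prefixes
    return EntropyTrajectory(vessel_id=vessel_id, S=S, N=N)


def entropy_score(trajectory, burn_in_fraction: float = 0.5) -> float:
    """Mean of the entropy trajectory after the burn-in prefix.

    The first ``floor(len * burn_in_fraction)`` values are discarded as
    burn-in and the remainder averaged.  Trajectories shorter than 2
    elements cannot be scored and raise, flagging the vessel for exclusion.
    """
    S = trajectory.S if isinstance(trajectory, EntropyTrajectory) else np.asarray(trajectory, float)
    n = len(S)
    if n < 2:
        raise ValueError("entropy score needs a trajectory of length >= 2 (vessel excluded)")
    cut = int(np.floor(n * burn_in_fraction))
    return float(np.mean(S[cut:]))


def patch_residence_time(series: pd.DataFrame) -> float:
    """Arithmetic mean bout duration (hours) of a visitation series."""
    if series is None or len(series) == 0:
        raise ValueError("patch residence time undefined for an empty series (vessel excluded)")
    return float(series["duration_h"].mean())


def displacement_from_points(xs, ys, polygon: Polygon) -> float:
    """Fraction of points strictly inside the polygon."""
    xs = np.atleast_1d(np.asarray(xs, float))
    ys = np.atleast_1d(np.asarray(ys, float))
    if xs.size == 0:
        raise ValueError("displacement undefined for an empty portfolio")
    inside = contains_xy(polygon, xs, ys)
    return float(inside.sum() / xs.size)


def displacement(portfolio: pd.DataFrame, grid: GridSpec, closure: Polygon) -> float:
    """Proportion of a vessel's pre-closure fished cells lost to the closure.

    Each portfolio cell is represented by its center; the score is the
    fraction of centers falling inside the closure polygon, so 0.8 means the
    vessel lost 80% of its pre-disturbance fishing locations.
    """
    if portfolio is None or len(portfolio) == 0:
        raise ValueError("displacement undefined for an empty portfolio")
    lon, lat = grid.cell_center(portfolio["cell_col"].to_numpy(), portfolio["cell_row"].to_numpy())
    return displacement_from_points(lon, lat, closure)


def activity_days(trips: pd.DataFrame, window_start, window_end) -> pd.Series:
    """Fishing days per vessel: summed trip durations landing in the window.

    The window is a lagged period preceding the study data so the covariate
    is exogenous to the modeled revenues.  Vessels present in ``trips`` but
    without trips in the window score 0 (with a warning).
    """
    t = pd.to_datetime(trips["landing_date"], utc=True)
    lo = pd.Timestamp(window_start, tz="UTC") if pd.Timestamp(window_start).tzinfo is None else pd.Timestamp(window_start)
    hi = pd.Timestamp(window_end, tz="UTC") if pd.Timestamp(window_end).tzinfo is None else pd.Timestamp(window_end)
    in_win = (t >= lo) & (t <= hi)
    per = trips.loc[in_win].groupby("vessel_id")["duration_days"].sum()
    out = per.reindex(trips["vessel_id"].unique(), fill_value=0.0)
    n_zero = int((out == 0).sum())
    if n_zero:
        log.warning("%d vessel(s) have no trips in the activity window; activity set to 0", n_zero)
    out.index.name = "vessel_id"
    out.name = "activity"
    return out


def build_profiles(
    visitation: dict,
    grid: GridSpec,
    closure: Polygon,
    trips: pd.DataFrame | None = None,
    activity_window: tuple | None = None,
    burn_in_fraction: float = 0.5,
    min_bouts: int = 20,
) -> pd.DataFrame:
    """Assemble the per-vessel strategy-covariate table.

    Vessels with fewer than ``min_bouts`` visitation elements are excluded
    as sparse (logged).  Columns: ``S`` (bits), ``prt`` (hours),
    ``displacement`` (proportion), ``activity`` (days, if trips given),
    ``length_m`` (if present in trips), ``n_bouts``.
    """
    from eetolab.grounds import portfolio_from_series

    act = None
    length = None
    if trips is not None:
        if activity_window is not None:
            act = activity_days(trips, *activity_window)
        else:
            act = trips.groupby("vessel_id")["duration_days"].sum().rename("activity")
        if "length_m" in trips.columns:
            length = trips.groupby("vessel_id")["length_m"].first()
    rows = []
    n_sparse = 0
    for vid, series in visitation.items():
        if len(series) < min_bouts:
            n_sparse += 1
            continue
        traj = entropy_trajectory(series["cell_col"].astype(str) + "_" + series["cell_row"].astype(str), vessel_id=vid)
        row = {
            "vessel_id": vid,
            "S": entropy_score(traj, burn_in_fraction),
            "prt": patch_residence_time(series),
            "displacement": displacement(portfolio_from_series(series), grid, closure),
            "n_bouts": len(series),
        }
        if act is not None:
            row["activity"] = float(act.get(vid, 0.0))
        if length is not None and vid in length.index:
            row["length_m"] = float(length.loc[vid])
        rows.append(row)
    if n_sparse:
        log.info("excluded %d sparse vessel(s) with < %d visitation elements", n_sparse, min_bouts)
    return pd.DataFrame(rows)


def grid_sensitivity(
    classified_pings: pd.DataFrame,
    sizes=tuple(range(20, 100, 5)),
    base_size: int = 30,
    burn_in_fraction: float = 0.5,
    min_bouts: int = 2,
) -> pd.DataFrame:
    """Spearman correlation of entropy scores across grid resolutions.

    Entropy scores are recomputed on square grids of each candidate size and
    rank-correlated against the base-size scores over the common vessel set.
    A constant score vector leaves rho undefined (reported as NaN).
    """

    fishing_only = classified_pings.loc[classified_pings["activity"] == "fishing"]

    def scores_at(n: int) -> pd.Series:
        grid = build_grid(fishing_only, n=n)
        vis = build_visitation_series(classified_pings, grid)
        out = {}
        for vid, series in vis.items():
            if len(series) >= max(min_bouts, 2):
                traj = entropy_trajectory(
                    series["cell_col"].astype(str) + "_" + series["cell_row"].astype(str)
                )
                out[vid] = entropy_score(traj, burn_in_fraction)
        return pd.Series(out)

    base = scores_at(base_size)
    if len(base) < 3:
        raise ValueError("grid sensitivity needs at least 3 vessels with scores")
    rows = []
    for n in sizes:
        other = scores_at(n)
        common = base.index.intersection(other.index)
        a = base.loc[common].to_numpy()
        b = other.loc[common].to_numpy()
        if len(common) < 3 or np.std(a) == 0 or np.std(b) == 0:
            rho, p = np.nan, np.nan
        else:
            rho, p = stats.spearmanr(a, b)
        rows.append({"grid_size": n, "rho": rho, "p": p, "n_vessels": len(common)})
    return pd.DataFrame(rows)


def depth_entropy_check(profiles: pd.DataFrame, mean_depth: pd.Series) -> dict:
    """Regression of the entropy score on mean fishing depth (reported, not asserted).

    Returns slope, t, p, intercept and n.  Used to check that the entropy
    metric is not a disguised depth (inshore/offshore) gradient.
    """
    merged = profiles.set_index("vessel_id").join(mean_depth.rename("mean_depth"), how="inner")
    merged = merged.dropna(subset=["S", "mean_depth"])
    if len(merged) < 3:
        raise ValueError("depth-entropy check needs at least 3 vessels")
    X = sm.add_constant(merged["mean_depth"].to_numpy())
    res = sm.OLS(merged["S"].to_numpy(), X).fit()
    return {
        "slope": float(res.params[1]),
        "t": float(res.tvalues[1]),
        "p": float(res.pvalues[1]),
        "intercept": float(res.params[0]),
        "n": int(len(merged)),
    }


def trip_distances(pings: pd.DataFrame) -> pd.Series:
    """Track length (km) per trip: summed inter-ping rhumb distances.

    Requires a ``trip_id`` column on the ping table.
    """
    if "trip_id" not in pings.columns:
        raise ValueError("trip distances need a trip_id column on the ping table")
    out = {}
    df = pings.sort_values(["trip_id", "timestamp"], kind="mergesort")
    for tid, grp in df.groupby("trip_id", sort=False):
        if len(grp) < 2 or tid == -1:
            continue
        lon = grp["lon"].to_numpy()
        lat = grp["lat"].to_numpy()
        out[tid] = float(np.sum(rhumb_distance(lon[:-1], lat[:-1], lon[1:], lat[1:]))) / 1000.0
    s = pd.Series(out, name="distance_km")
    s.index.name = "trip_id"
    return s


def revenue_per_km(trips: pd.DataFrame, pings: pd.DataFrame, profiles: pd.DataFrame) -> dict:
    """Travel-cost diagnostic: regress entropy score on revenue per km traveled.

    Per-vessel revenue per kilometre is total trip revenue over total track
    length; zero-distance trips are excluded (logged).  Returns the OLS
    slope, F statistic, p value and the sign of the relationship.
    """
    dist = trip_distances(pings)
    merged = trips.join(dist, on="trip_id", how="inner")
    n_zero = int((merged["distance_km"] <= 0).sum())
    if n_zero:
        log.info("excluding %d zero-distance trip(s) from revenue/km", n_zero)
    merged = merged.loc[merged["distance_km"] > 0]
    per_vessel = merged.groupby("vessel_id").agg(
        revenue=("revenue", "sum"), distance_km=("distance_km", "sum")
    )
    per_vessel["revenue_per_km"] = per_vessel["revenue"] / per_vessel["distance_km"]
    data = profiles.set_index("vessel_id").join(per_vessel["revenue_per_km"], how="inner").dropna(
        subset=["S", "revenue_per_km"]
    )
    if len(data) < 3:
        raise ValueError("revenue/km regression needs at least 3 vessels")
    X = sm.add_constant(data["revenue_per_km"].to_numpy())
    res = sm.OLS(data["S"].to_numpy(), X).fit()
    slope = float(res.params[1])
    return {
        "slope": slope,
        "F": float(res.fvalue),
        "p": float(res.f_pvalue),
        "sign": int(np.sign(slope)),
        "n": int(len(data)),
    }
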