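"""Position-record cleaning, movement features and activity classification.

Raw hourly pings (vessel id, UTC timestamp, lon, lat) are cleaned by an
extent filter and an iterative speed filter, enriched with loxodromic
(rhumb-line) speed and depth, converted into per-ping movement features, and
classified into fishing / transit / port activity with a random-forest
ensemble validated on held-out observer-labeled trips.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from eetolab.errors import SchemaError

log = logging.getLogger(__name__)

EARTH_RADIUS_M = 6_371_000.0

#: canonical movement-feature columns, in training order
FEATURE_COLUMNS = [
    "speed",
    "turn_angle",
    "depth",
    "hour",
    "dist_port_km",
    "speed_ma3",
]

ACTIVITIES = ("fishing", "transit", "port")


def rhumb_distance(lon1, lat1, lon2, lat2, radius: float = EARTH_RADIUS_M):
    """Loxodromic (constant-bearing) distance between points, in metres.

    Vectorized over numpy arrays.  Longitude differences are wrapped across
    the antimeridian.  Latitudes at the poles are rejected because the
    Mercator stretch diverges there.
    """
    lon1, lat1, lon2, lat2 = (np.asarray(a, dtype=float) for a in (lon1, lat1, lon2, lat2))
    for la in (lat1, lat2):
        if np.any(~np.isfinite(la)) or np.any(np.abs(la) >= 90.0):
            raise ValueError("latitudes must be finite and strictly between -90 and 90")
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2 - lon1)
    dlam = (dlam + np.pi) % (2.0 * np.pi) - np.pi
    dpsi = np.log(np.tan(np.pi / 4.0 + phi2 / 2.0) / np.tan(np.pi / 4.0 + phi1 / 2.0))
    # q -> cos(phi) as dphi -> 0 (east-west course)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(np.abs(dpsi) > 1e-12, dphi / np.where(dpsi == 0, 1.0, dpsi), np.cos(phi1))
    dist = np.sqrt(dphi**2 + (q * dlam) ** 2) * radius
    return dist if dist.ndim else float(dist)


def _bearing(lon1, lat1, lon2, lat2):
    """Local planar course in degrees from north, adequate for hourly steps."""
    dx = np.radians(lon2 - lon1) * np.cos(np.radians(0.5 * (lat1 + lat2)))
    dy = np.radians(lat2 - lat1)
    return np.degrees(np.arctan2(dx, dy))


@dataclass
class CleaningLog:
    """Counts of records removed at each cleaning filter."""

    n_input: int = 0
    n_duplicate: int = 0
    n_out_of_extent: int = 0
    n_speed_outliers: int = 0
    n_nonmonotone_sorted: int = 0
    n_output: int = 0


def _require_columns(df: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required columns: {missing}")


def _per_vessel_speeds(lon: np.ndarray, lat: np.ndarray, t_s: np.ndarray) -> np.ndarray:
    """Arrival speed (m/s) per ping; NaN for the first ping."""
    sp = np.full(lon.shape, np.nan)
    if lon.size >= 2:
        d = rhumb_distance(lon[:-1], lat[:-1], lon[1:], lat[1:])
        dt = np.diff(t_s)
        sp[1:] = np.where(dt > 0, d / np.where(dt == 0, 1.0, dt), np.inf)
    return sp


def clean_pings(
    pings: pd.DataFrame,
    extent: tuple,
    speed_threshold: float = 20.0,
    depth_fn=None,
    cleaning_log: CleaningLog | None = None,
) -> pd.DataFrame:
    """Clean raw position records and derive per-ping speed (and depth).

    Steps, in order: parse timestamps as UTC; drop duplicate
    (vessel, timestamp) records keeping the first; sort per vessel by time;
    drop pings outside ``extent = (lon_min, lon_max, lat_min, lat_max)``;
    iteratively delete pings whose arrival speed exceeds ``speed_threshold``
    (m/s), recomputing the successor's speed after each deletion round.
    ``depth_fn(lon, lat)``, when given, attaches a ``depth`` column.

    The operation is idempotent: cleaning an already-clean table returns it
    unchanged (up to the derived columns).
    """
    _require_columns(pings, ["vessel_id", "timestamp", "lon", "lat"], "ping table")
    clog = cleaning_log if cleaning_log is not None else CleaningLog()
    clog.n_input = len(pings)

    df = pings.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    n0 = len(df)
    dup = df.duplicated(subset=["vessel_id", "timestamp"], keep="first")
    if dup.any():
        log.info("dropping %d duplicate (vessel, timestamp) pings", int(dup.sum()))
    df = df.loc[~dup]
    clog.n_duplicate = n0 - len(df)

    unsorted = (
        df.groupby("vessel_id", sort=False)["timestamp"].apply(lambda s: (s.diff() < pd.Timedelta(0)).sum()).sum()
    )
    if unsorted:
        log.info("sorting %d non-monotone timestamps", int(unsorted))
    clog.n_nonmonotone_sorted = int(unsorted)
    df = df.sort_values(["vessel_id", "timestamp"], kind="mergesort").reset_index(drop=True)

    lon_min, lon_max, lat_min, lat_max = extent
    in_ext = (
        (df["lon"] >= lon_min) & (df["lon"] <= lon_max) & (df["lat"] >= lat_min) & (df["lat"] <= lat_max)
    )
    clog.n_out_of_extent = int((~in_ext).sum())
    if clog.n_out_of_extent:
        log.info("dropping %d pings outside the study extent", clog.n_out_of_extent)
    df = df.loc[in_ext].reset_index(drop=True)

    kept_parts = []
    n_speed = 0
    for _, grp in df.groupby("vessel_id", sort=False):
        lon = grp["lon"].to_numpy()
        lat = grp["lat"].to_numpy()
        t_s = grp["timestamp"].astype("int64").to_numpy() / 1e9
        keep = np.ones(len(grp), dtype=bool)
        while True:
            sp = _per_vessel_speeds(lon[keep], lat[keep], t_s[keep])
            bad = sp > speed_threshold
            if not bad.any():
                break
            # delete only the first ping of each consecutive bad run; the
            # successors' speeds are recomputed against the new predecessor
            first_bad = bad & ~np.roll(bad, 1)
            first_bad[0] = bad[0]
            idx = np.flatnonzero(keep)
            keep[idx[first_bad]] = False
            n_speed += int(first_bad.sum())
        out = grp.loc[keep].copy()
        out["speed"] = _per_vessel_speeds(lon[keep], lat[keep], t_s[keep])
        kept_parts.append(out)
    clog.n_speed_outliers = n_speed
    if n_speed:
        log.info("deleted %d speed-outlier pings (> %.1f m/s, iterative)", n_speed, speed_threshold)

    result = (
        pd.concat(kept_parts, ignore_index=True)
        if kept_parts
        else df.iloc[0:0].assign(speed=pd.Series(dtype=float))
    )
    if depth_fn is not None and len(result):
        result["depth"] = np.asarray(depth_fn(result["lon"].to_numpy(), result["lat"].to_numpy()))
    clog.n_output = len(result)
    return result


def derive_features(pings: pd.DataFrame, port: tuple, ma_window: int = 3) -> pd.DataFrame:
    """Per-ping movement features for interior pings.

    A feature row needs both a predecessor (speed) and a successor (turning
    angle), so the first and last ping of each vessel are dropped.  Features:
    arrival speed (m/s), turning angle in [0, 180] degrees, depth (m), hour
    of day (UTC), rhumb displacement from port (km), and a centred 3-ping
    moving average of speed.

    Returns a frame with ``vessel_id``/``timestamp`` identifiers plus the
    :data:`FEATURE_COLUMNS`.  Vessels with fewer than three pings contribute
    nothing (with a warning).
    """
    _require_columns(pings, ["vessel_id", "timestamp", "lon", "lat", "speed"], "cleaned ping table")
    rows = []
    for vid, grp in pings.groupby("vessel_id", sort=False):
        if len(grp) < 3:
            log.warning("vessel %s has fewer than 3 pings; no features derived", vid)
            continue
        lon = grp["lon"].to_numpy()
        lat = grp["lat"].to_numpy()
        speed = grp["speed"].to_numpy()
        b = _bearing(lon[:-1], lat[:-1], lon[1:], lat[1:])
        turn = np.abs((b[1:] - b[:-1] + 180.0) % 360.0 - 180.0)  # interior pings only
        sp_ma = pd.Series(speed).rolling(ma_window, center=True, min_periods=1).mean().to_numpy()
        ts = pd.to_datetime(grp["timestamp"], utc=True)
        hour = ts.dt.hour.to_numpy() + ts.dt.minute.to_numpy() / 60.0
        dist_port = rhumb_distance(lon, lat, port[0], port[1]) / 1000.0
        depth = grp["depth"].to_numpy() if "depth" in grp else np.zeros(len(grp))
        sl = slice(1, -1)
        rows.append(
            pd.DataFrame(
                {
                    "vessel_id": vid,
                    "timestamp": ts.to_numpy()[sl],
                    "speed": speed[sl],
                    "turn_angle": turn,
                    "depth": depth[sl],
                    "hour": hour[sl],
                    "dist_port_km": np.atleast_1d(dist_port)[sl],
                    "speed_ma3": sp_ma[sl],
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=["vessel_id", "timestamp", *FEATURE_COLUMNS])
    out = pd.concat(rows, ignore_index=True)
    return out.dropna(subset=FEATURE_COLUMNS).reset_index(drop=True)


def balanced_accuracy(truth, predicted, positive: str = "fishing") -> float:
    """Mean of the true-positive and true-negative rates, fishing vs rest.

    Activities are collapsed to the binary fishing / non-fishing distinction
    before scoring, so the score is penalized for incorrect labels of either
    class and is insensitive to class imbalance.
    """
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValueError("truth and predicted must have equal length")
    t_pos = truth == positive
    p_pos = predicted == positive
    if t_pos.all() or (~t_pos).all():
        raise ValueError("balanced accuracy undefined: truth contains a single class")
    tpr = float((p_pos & t_pos).sum() / t_pos.sum())
    tnr = float((~p_pos & ~t_pos).sum() / (~t_pos).sum())
    return 0.5 * (tpr + tnr)


class ActivityClassifier(BaseEstimator, ClassifierMixin):
    """Random-forest activity classifier with a built-in held-out validation.

    ``fit`` splits the observer-labeled rows into equal training and testing
    halves (stratified), fits the forest on the training half and stores the
    held-out fishing/non-fishing balanced accuracy in ``balanced_accuracy_``
    before the model is used for deployment.  Pings within
    ``port_radius_km`` of the port are labeled ``port`` by rule at
    prediction time.

    Parameters
    ----------
    n_estimators : int
        Trees in the forest.
    test_size : float
        Fraction held out for validation (default: an even split).
    port_radius_km : float
        Rule-based port radius applied at prediction.
    random_state : int
        Seed for the split and the forest.
    """

    def __init__(
        self,
        n_estimators: int = 500,
        test_size: float = 0.5,
        port_radius_km: float = 2.0,
        random_state: int = 0,
    ):
        self.n_estimators = n_estimators
        self.test_size = test_size
        self.port_radius_km = port_radius_km
        self.random_state = random_state

    def _validate_features(self, X: pd.DataFrame) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise SchemaError("features must be a DataFrame with named columns")
        missing = [c for c in FEATURE_COLUMNS if c not in X.columns]
        if missing:
            raise SchemaError(f"feature table is missing columns: {missing}")
        return X[FEATURE_COLUMNS]

    def fit(self, X: pd.DataFrame, y):
        """Fit on half of the labeled rows; validate on the other half."""
        Xf = self._validate_features(X)
        y = np.asarray(y)
        classes = np.unique(y)
        if not set(("fishing",)) <= set(classes) or len(classes) < 2:
            raise ValueError("labels must contain 'fishing' and at least one other activity")
        X_tr, X_te, y_tr, y_te = train_test_split(
            Xf,
            y,
            test_size=self.test_size,
            random_state=self.random_state,
            stratify=y,
        )
        if set(np.unique(y_tr)) != set(classes):  # pragma: no cover - stratify guards this
            raise ValueError("a class is absent from the training half")
        self.model_ = RandomForestClassifier(
            n_estimators=self.n_estimators, random_state=self.random_state, n_jobs=1
        )
        self.model_.fit(X_tr.to_numpy(), y_tr)
        pred = self.model_.predict(X_te.to_numpy())
        self.balanced_accuracy_ = balanced_accuracy(y_te, pred)
        self.classes_ = self.model_.classes_
        self.feature_names_ = list(FEATURE_COLUMNS)
        self.n_features_in_ = len(FEATURE_COLUMNS)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Predict activity per feature row; port-radius rule applied last."""
        check_is_fitted(self, "model_")
        Xf = self._validate_features(X)
        labels = self.model_.predict(Xf.to_numpy()).astype(object)
        near_port = Xf["dist_port_km"].to_numpy() <= self.port_radius_km
        labels[near_port] = "port"
        return np.asarray(labels, dtype=object)


def train_activity_classifier(
    features: pd.DataFrame,
    labels,
    split: float = 0.5,
    seed: int = 0,
    n_estimators: int = 500,
    port_radius_km: float = 2.0,
) -> ActivityClassifier:
    """Thin functional wrapper over :class:`ActivityClassifier`."""
    clf = ActivityClassifier(
        n_estimators=n_estimators,
        test_size=split,
        port_radius_km=port_radius_km,
        random_state=seed,
    )
    return clf.fit(features, labels)


def classify_activity(classifier: ActivityClassifier, features: pd.DataFrame) -> np.ndarray:
    """Predict one activity label per feature row."""
    return classifier.predict(features)
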