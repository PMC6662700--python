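"""Seeded synthetic fleet, tracks, trips, observer labels and disturbance.

The generator emulates the structure of fleet monitoring data: a fleet of
heterogeneous vessels alternating port stays and multi-day trips, reporting
hourly positions that alternate port / transit (~5 m/s) / fishing (<2 m/s)
regimes, trip-level logbook revenue driven by a per-vessel performance
component plus trip duration and a seasonal fleet-wide factor, and an
abrupt spatial closure of the most-used fishing grounds with
entropy-dependent exit and a decaying deviance effect of entropy and
displacement on post-closure revenue.

Every random draw descends from one root seed, with independent per-vessel
sub-streams so fleets are reproducible bit-for-bit and stable under
fleet-size changes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely import contains_xy

from eetolab.config import EPOCH, FleetConfig
from eetolab.errors import ConfigurationError
from eetolab.world import SimWorld, default_world

log = logging.getLogger(__name__)

TRANSIT_SPEED_MS = 5.0  # nominal transit speed
FISHING_JITTER_DEG = 0.004  # positional scatter while fishing on a site
DEG_M = 111_194.926  # metres per degree of latitude on the 6371-km sphere


@dataclass
class VesselSpec:
    """Generative parameters of one vessel.

    ``skill`` is the vessel's true mean-performance component (revenue
    units); ``weights`` are its site-choice probabilities (sum to 1);
    ``true_entropy`` is the Shannon entropy (bits) of those weights.
    """

    vessel_id: int
    site_ids: np.ndarray
    site_lon: np.ndarray
    site_lat: np.ndarray
    weights: np.ndarray
    prt_mean: float
    skill: float
    length: float
    concentration: float

    def __post_init__(self):
        if len(self.site_ids) == 0:
            raise ConfigurationError("vessel portfolio must be nonempty")
        if abs(float(np.sum(self.weights)) - 1.0) > 1e-9:
            raise ConfigurationError("choice weights must sum to 1")

    @property
    def true_entropy(self) -> float:
        w = self.weights[self.weights > 0]
        return float(-(w * np.log2(w)).sum())


def _vessel_rng(seed: int, vessel_id: int) -> np.random.Generator:
    return np.random.default_rng([seed, 1000 + vessel_id])


def generate_fleet(config: FleetConfig, world: SimWorld | None = None) -> list:
    """Draw a fleet of vessels spanning narrow-to-broad strategies.

    Portfolio size is uniform over ``portfolio_size_range``; choice weights
    are symmetric-Dirichlet with a log-uniform concentration, so the fleet
    spans skewed low-entropy choosers through even high-entropy ones.  Sites
    are drawn without replacement from the world's lattice around a random
    home center, with extra weight on the core (later closed) area and a
    spatial spread that grows with portfolio size: narrow specialists fish a
    tight cluster, broad explorers roam wider and hence travel farther.
    """
    world = world if world is not None else default_world()
    lo_n, hi_n = config.portfolio_size_range
    lo_c, hi_c = config.choice_concentration_range
    fleet = []
    for vid in range(config.n_vessels):
        rng = _vessel_rng(config.seed, vid)
        size = int(rng.integers(lo_n, hi_n + 1))
        conc = float(np.exp(rng.uniform(np.log(lo_c), np.log(hi_c))))
        weights = rng.dirichlet(np.full(size, conc))
        # guard against numerically zero weights from extreme concentrations
        weights = np.maximum(weights, 1e-12)
        weights = weights / weights.sum()
        home = int(rng.choice(len(world.site_lon), p=world.site_weight))
        spread = 0.25 + 0.08 * size  # degrees
        d2 = (world.site_lon - world.site_lon[home]) ** 2 + (world.site_lat - world.site_lat[home]) ** 2
        p = world.site_weight * np.exp(-d2 / (2.0 * spread**2))
        p = p / p.sum()
        sites = rng.choice(
            len(world.site_lon), size=min(size, len(world.site_lon)), replace=False, p=p
        )
        fleet.append(
            VesselSpec(
                vessel_id=vid,
                site_ids=sites,
                site_lon=world.site_lon[sites],
                site_lat=world.site_lat[sites],
                weights=weights,
                prt_mean=float(rng.uniform(*config.prt_mean_range)),
                skill=float(rng.normal(config.skill_mean, config.skill_sd)),
                length=float(rng.uniform(*config.vessel_length_range)),
                concentration=conc,
            )
        )
    return fleet


def fleet_factor_series(config: FleetConfig, n_days: int, offset_days: int = 0) -> np.ndarray:
    """Daily fleet-wide revenue factor: seasonal sinusoid plus AR(1) shocks.

    Deterministic given the config seed; day ``d`` of the series corresponds
    to study day ``offset_days + d``.
    """
    rng = np.random.default_rng([config.seed, 1])
    total = offset_days + n_days
    days = np.arange(total)
    seasonal = config.fleet_amplitude * np.sin(2.0 * np.pi * days / 365.0)
    shocks = np.empty(total)
    innov_sd = config.fleet_shock_sd * np.sqrt(max(1.0 - config.fleet_shock_corr**2, 1e-12))
    prev = 0.0
    for d in range(total):
        prev = config.fleet_shock_corr * prev + rng.normal(0.0, innov_sd)
        shocks[d] = prev
    return (seasonal + shocks)[offset_days:]


def sample_visitation(vessel: VesselSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample a visitation sequence of site ids from the vessel's weights."""
    idx = rng.choice(len(vessel.site_ids), size=n, p=vessel.weights)
    return vessel.site_ids[idx]


def _transit_leg(lon0, lat0, lon1, lat1, rng):
    """Hourly positions along a straight transit leg at ~5 m/s (excl. start)."""
    from eetolab.tracks import rhumb_distance

    dist = rhumb_distance(lon0, lat0, lon1, lat1)
    n_h = max(1, int(np.ceil(dist / (TRANSIT_SPEED_MS * 3600.0))))
    f = np.arange(1, n_h + 1) / n_h
    lon = lon0 + (lon1 - lon0) * f + rng.normal(0.0, 0.002, n_h)
    lat = lat0 + (lat1 - lat0) * f + rng.normal(0.0, 0.002, n_h)
    lon[-1], lat[-1] = lon1, lat1
    return lon, lat


def _epoch_start() -> pd.Timestamp:
    return pd.Timestamp(EPOCH)


class _TripAccumulator:
    """Collects ping/trip/label rows while a period is simulated."""

    def __init__(self):
        self.ping_rows = []
        self.trip_rows = []
        self.next_trip_id = 0

    def add_pings(self, vessel_id, trip_id, hours, lon, lat, activity, observed):
        self.ping_rows.append(
            {
                "vessel_id": vessel_id,
                "trip_id": trip_id,
                "hour": np.asarray(hours),
                "lon": np.asarray(lon),
                "lat": np.asarray(lat),
                "activity": np.asarray(activity, dtype=object),
                "observed": observed,
            }
        )

    def to_frames(self, start: pd.Timestamp):
        if self.ping_rows:
            parts = []
            for row in self.ping_rows:
                parts.append(
                    pd.DataFrame(
                        {
                            "vessel_id": row["vessel_id"],
                            "trip_id": row["trip_id"],
                            "timestamp": start + pd.to_timedelta(row["hour"], unit="h"),
                            "lon": row["lon"],
                            "lat": row["lat"],
                            "activity_true": row["activity"],
                            "observed": row["observed"],
                        }
                    )
                )
            pings = pd.concat(parts, ignore_index=True)
            pings = pings.sort_values(["vessel_id", "timestamp"], ignore_index=True)
        else:
            pings = pd.DataFrame(
                columns=["vessel_id", "trip_id", "timestamp", "lon", "lat", "activity_true", "observed"]
            )
        trips = pd.DataFrame(
            self.trip_rows,
            columns=[
                "vessel_id",
                "trip_id",
                "landing_date",
                "duration_days",
                "revenue",
                "length_m",
                "observer",
                "period",
                "skill_true",
                "fleet_factor_true",
                "delta_true",
                "days_since_closure",
            ],
        )
        labels = pings.loc[pings["observed"], ["vessel_id", "timestamp", "activity_true"]].rename(
            columns={"activity_true": "activity"}
        )
        return pings, trips, labels


def _simulate_vessel_period(
    vessel: VesselSpec,
    world: SimWorld,
    config: FleetConfig,
    rng: np.random.Generator,
    acc: _TripAccumulator,
    fleet_factor: np.ndarray,
    period: str,
    start_hour: float,
    n_days: int,
    site_lon: np.ndarray,
    site_lat: np.ndarray,
    weights: np.ndarray,
    deviance_fn=None,
    trip_id_offset: int = 0,
):
    """Simulate one vessel over one period, appending to the accumulator.

    ``deviance_fn(days_since_start) -> delta`` perturbs the vessel
    performance component of revenue during a disturbance.
    """
    horizon = start_hour + n_days * 24.0
    t = start_hour
    port_lon, port_lat = world.port
    sigma = 0.5  # lognormal shape of bout durations
    mu = np.log(vessel.prt_mean) - sigma**2 / 2.0
    trip_counter = trip_id_offset
    while t < horizon:
        # port stay
        gap_h = max(12.0, rng.exponential(config.port_gap_mean_days * 24.0))
        n_port = int(np.ceil(gap_h))
        hours = t + np.arange(n_port)
        keep = hours < horizon
        if keep.any():
            acc.add_pings(
                vessel.vessel_id,
                -1,
                hours[keep],
                port_lon + rng.normal(0, 2e-4, int(keep.sum())),
                port_lat + rng.normal(0, 2e-4, int(keep.sum())),
                ["port"] * int(keep.sum()),
                False,
            )
        t += n_port
        if t >= horizon:
            break
        # trip
        planned_h = rng.uniform(*config.trip_duration_range) * 24.0
        trip_id = acc.next_trip_id
        acc.next_trip_id += 1
        observed = bool(rng.random() < config.observer_fraction)
        lons, lats, acts, hrs = [], [], [], []
        cur_lon, cur_lat = port_lon, port_lat
        t_trip = 0.0
        depart = t
        prev_k = None
        while True:
            k = int(rng.choice(len(weights), p=weights))
            nlon, nlat = site_lon[k], site_lat[k]
            if prev_k == k:
                leg_lon = np.empty(0)
                leg_lat = np.empty(0)
            else:
                leg_lon, leg_lat = _transit_leg(cur_lon, cur_lat, nlon, nlat, rng)
            ret_lon, ret_lat = _transit_leg(nlon, nlat, port_lon, port_lat, rng)
            bout_h = max(1, int(np.round(rng.lognormal(mu, sigma))))
            if t_trip > 0 and t_trip + len(leg_lon) + bout_h + len(ret_lon) > planned_h:
                break
            if len(leg_lon):
                hrs.extend(depart + t_trip + np.arange(len(leg_lon)))
                lons.extend(leg_lon)
                lats.extend(leg_lat)
                acts.extend(["transit"] * len(leg_lon))
                t_trip += len(leg_lon)
            prev_k = k
            blon = nlon + rng.normal(0.0, FISHING_JITTER_DEG, bout_h)
            blat = nlat + rng.normal(0.0, FISHING_JITTER_DEG, bout_h)
            hrs.extend(depart + t_trip + np.arange(bout_h))
            lons.extend(blon)
            lats.extend(blat)
            acts.extend(["fishing"] * bout_h)
            t_trip += bout_h
            cur_lon, cur_lat = nlon, nlat
        leg_lon, leg_lat = _transit_leg(cur_lon, cur_lat, port_lon, port_lat, rng)
        hrs.extend(depart + t_trip + np.arange(len(leg_lon)))
        lons.extend(leg_lon)
        lats.extend(leg_lat)
        acts.extend(["transit"] * len(leg_lon))
        t_trip += len(leg_lon)
        hrs = np.asarray(hrs)
        keep = hrs < horizon
        if keep.any():
            acc.add_pings(
                vessel.vessel_id,
                trip_id,
                hrs[keep],
                np.asarray(lons)[keep],
                np.asarray(lats)[keep],
                np.asarray(acts, dtype=object)[keep],
                observed,
            )
        t = depart + t_trip
        landing_hour = min(t, horizon)
        landing_day = int(landing_hour // 24.0)
        duration_days = t_trip / 24.0
        ff = float(fleet_factor[min(landing_day, len(fleet_factor) - 1)])
        days_since = landing_hour / 24.0 - start_hour / 24.0 if period == "disturbed" else np.nan
        delta = float(deviance_fn(days_since)) if deviance_fn is not None else 0.0
        revenue = (
            (1.0 + delta) * vessel.skill
            + config.beta_duration * duration_days
            + config.beta_fleet * ff
            + rng.normal(0.0, config.noise_sd)
        )
        acc.trip_rows.append(
            {
                "vessel_id": vessel.vessel_id,
                "trip_id": trip_id,
                "landing_date": _epoch_start() + pd.to_timedelta(landing_hour, unit="h"),
                "duration_days": duration_days,
                "revenue": max(revenue, 0.0),
                "length_m": vessel.length,
                "observer": observed,
                "period": period,
                "skill_true": vessel.skill,
                "fleet_factor_true": ff,
                "delta_true": delta,
                "days_since_closure": days_since,
            }
        )
        trip_counter += 1


def simulate_tracks(fleet: list, world: SimWorld, config: FleetConfig):
    """Simulate the undisturbed period: hourly pings, trips, observer labels.

    Returns ``(pings, trips, labels)`` DataFrames.  Ping rows carry the
    ground-truth activity (``activity_true``) and trip id; ``labels``
    contains the observer-labeled subset only, as the processing stage would
    receive it.
    """
    if not fleet:
        raise ConfigurationError("fleet must be nonempty")
    acc = _TripAccumulator()
    ff = fleet_factor_series(config, config.undisturbed_days)
    for vessel in fleet:
        rng = np.random.default_rng([config.seed, 2000 + vessel.vessel_id])
        _simulate_vessel_period(
            vessel,
            world,
            config,
            rng,
            acc,
            ff,
            period="undisturbed",
            start_hour=0.0,
            n_days=config.undisturbed_days,
            site_lon=vessel.site_lon,
            site_lat=vessel.site_lat,
            weights=vessel.weights,
        )
    return acc.to_frames(_epoch_start())


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = np.std(x, ddof=1)
    return (x - np.mean(x)) / sd if sd > 0 else np.zeros_like(x)


def true_displacement(vessel: VesselSpec, world: SimWorld) -> float:
    """Fraction of the vessel's portfolio sites inside the closure polygon."""
    inside = contains_xy(world.closure, vessel.site_lon, vessel.site_lat)
    return float(inside.mean())


def draw_exits(fleet: list, config: FleetConfig, rng: np.random.Generator | None = None):
    """Entropy-dependent exit decisions at closure onset.

    Exit probability is ``logistic(exit_baseline - exit_entropy_coef *
    z(S_true))``: with a positive coefficient, broad explorers are more
    likely to remain in the fishery.  Returns ``(exits, p_exit, S_z)``.
    """
    rng = rng if rng is not None else np.random.default_rng([config.seed, 3])
    S_true = np.array([v.true_entropy for v in fleet])
    S_z = _standardize(S_true)
    logit = config.exit_baseline - config.exit_entropy_coef * S_z
    p_exit = 1.0 / (1.0 + np.exp(-logit))
    exits = rng.random(len(fleet)) < p_exit
    return exits, p_exit, S_z


def simulate_disturbance(fleet: list, world: SimWorld, config: FleetConfig, undisturbed_outputs):
    """Simulate the closure period given the undisturbed outputs.

    Each vessel exits the fishery with probability
    ``logistic(exit_baseline - exit_entropy_coef * z(S_true))``; survivors
    fish only outside the closure polygon (vessels whose whole portfolio is
    closed relocate to fresh sites outside).  Post-closure revenue carries a
    deviance ``delta = (a * z(S_true) - b * z(displacement)) *
    2**(-days/halflife) + noise`` applied to the vessel-performance
    component, so the generated effect is recoverable on the deviance scale.

    Returns ``(pings, trips, labels, exit_flags)`` where ``exit_flags`` is a
    per-vessel DataFrame with exit decision, true entropy and displacement.
    """
    if not fleet:
        raise ConfigurationError("fleet must be nonempty")
    und_pings = undisturbed_outputs[0]
    fishing = und_pings.loc[und_pings["activity_true"] == "fishing"]
    if len(fishing) == 0 or not contains_xy(
        world.closure, fishing["lon"].to_numpy(), fishing["lat"].to_numpy()
    ).any():
        raise ConfigurationError("closure polygon covers no fished cells of the undisturbed period")

    exits, p_exit, S_z = draw_exits(fleet, config)
    S_true = np.array([v.true_entropy for v in fleet])
    d_true = np.array([true_displacement(v, world) for v in fleet])
    d_z = _standardize(d_true)

    outside_mask = [~contains_xy(world.closure, v.site_lon, v.site_lat) for v in fleet]
    lattice_outside = ~contains_xy(world.closure, world.site_lon, world.site_lat)

    acc = _TripAccumulator()
    acc.next_trip_id = int(undisturbed_outputs[1]["trip_id"].max() + 1) if len(undisturbed_outputs[1]) else 0
    ff = fleet_factor_series(
        config, config.disturbed_days, offset_days=config.undisturbed_days
    )
    halflife = config.deviance_decay_halflife
    for i, vessel in enumerate(fleet):
        if exits[i]:
            continue
        rng = np.random.default_rng([config.seed, 3000 + vessel.vessel_id])
        mask = outside_mask[i]
        if mask.any():
            s_lon = vessel.site_lon[mask]
            s_lat = vessel.site_lat[mask]
            w = vessel.weights[mask]
            w = w / w.sum()
        else:
            # whole portfolio closed: relocate to fresh sites outside
            pool = np.flatnonzero(lattice_outside)
            pick = rng.choice(pool, size=min(len(vessel.site_ids), len(pool)), replace=False)
            s_lon = world.site_lon[pick]
            s_lat = world.site_lat[pick]
            w = np.full(len(pick), 1.0 / len(pick))
        base_effect = (
            config.deviance_entropy_coef * S_z[i] - config.deviance_displacement_coef * d_z[i]
        )

        def deviance_fn(days_since, _base=base_effect, _rng=rng):
            decay = 2.0 ** (-(max(days_since, 0.0)) / halflife)
            return _base * decay + _rng.normal(0.0, config.deviance_noise_sd)

        _simulate_vessel_period(
            vessel,
            world,
            config,
            rng,
            acc,
            ff,
            period="disturbed",
            start_hour=config.undisturbed_days * 24.0,
            n_days=config.disturbed_days,
            site_lon=s_lon,
            site_lat=s_lat,
            weights=w,
            deviance_fn=deviance_fn,
        )
    pings, trips, labels = acc.to_frames(_epoch_start())
    exit_flags = pd.DataFrame(
        {
            "vessel_id": [v.vessel_id for v in fleet],
            "exited": exits,
            "p_exit": p_exit,
            "true_entropy": S_true,
            "true_displacement": d_true,
        }
    )
    return pings, trips, labels, exit_flags


def simulate_trip_table(
    fleet: list,
    config: FleetConfig,
    n_days: int | None = None,
    rng: np.random.Generator | None = None,
    period: str = "undisturbed",
    deviance_terms: dict | None = None,
    start_day: int = 0,
) -> pd.DataFrame:
    """Trip-level fast path: logbook records without hourly track simulation.

    Uses the same cadence (exponential port gaps, uniform planned durations)
    and the same revenue model as the full simulator, so parameter-recovery
    studies over many seeds stay cheap.  ``deviance_terms`` may supply
    per-vessel arrays ``S_z`` / ``d_z`` (standardized) to apply the decaying
    disturbance deviance as in :func:`simulate_disturbance`.
    """
    n_days = n_days if n_days is not None else config.undisturbed_days
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    ff = fleet_factor_series(config, n_days, offset_days=start_day)
    halflife = config.deviance_decay_halflife
    rows = []
    trip_id = 0
    for i, vessel in enumerate(fleet):
        t = 0.0
        while True:
            t += max(0.5, rng.exponential(config.port_gap_mean_days))
            dur = rng.uniform(*config.trip_duration_range)
            t += dur
            if t >= n_days:
                break
            day = int(t)
            delta = 0.0
            if deviance_terms is not None:
                base = (
                    config.deviance_entropy_coef * deviance_terms["S_z"][i]
                    - config.deviance_displacement_coef * deviance_terms["d_z"][i]
                )
                delta = base * 2.0 ** (-t / halflife) + rng.normal(0.0, config.deviance_noise_sd)
            revenue = (
                (1.0 + delta) * vessel.skill
                + config.beta_duration * dur
                + config.beta_fleet * ff[day]
                + rng.normal(0.0, config.noise_sd)
            )
            rows.append(
                {
                    "vessel_id": vessel.vessel_id,
                    "trip_id": trip_id,
                    "landing_date": _epoch_start() + pd.to_timedelta(start_day + t, unit="D"),
                    "duration_days": dur,
                    "revenue": max(revenue, 0.0),
                    "length_m": vessel.length,
                    "observer": False,
                    "period": period,
                    "skill_true": vessel.skill,
                    "fleet_factor_true": float(ff[day]),
                    "delta_true": delta,
                    "days_since_closure": t if period == "disturbed" else np.nan,
                }
            )
            trip_id += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dataset round-trip

PING_COLUMNS = ["vessel_id", "trip_id", "timestamp", "lon", "lat"]
TRIP_COLUMNS = ["vessel_id", "trip_id", "landing_date", "duration_days", "revenue", "length_m", "period"]
LABEL_COLUMNS = ["vessel_id", "timestamp", "activity"]


def write_dataset(outputs: dict, directory) -> dict:
    """Write simulated outputs as plain-text artifacts.

    ``outputs`` maps names to objects: ``pings`` / ``trips`` / ``labels``
    DataFrames, ``world`` (for the closure polygon) and optionally
    ``config``.  Files written: ``pings.csv``, ``trips.csv``,
    ``labels.csv``, ``closure.geojson`` and ``config.yaml``.  Tables
    round-trip losslessly through :func:`read_dataset`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = {}

    def _ts(col):
        return col.dt.strftime("%Y-%m-%dT%H:%M:%SZ")

    pings = outputs["pings"].copy()
    pings["timestamp"] = _ts(pd.to_datetime(pings["timestamp"], utc=True))
    keep = [c for c in PING_COLUMNS + ["activity_true", "observed", "period"] if c in pings.columns]
    pings[keep].to_csv(directory / "pings.csv", index=False)
    written["pings"] = directory / "pings.csv"

    trips = outputs["trips"].copy()
    trips["landing_date"] = _ts(pd.to_datetime(trips["landing_date"], utc=True))
    trips.to_csv(directory / "trips.csv", index=False)
    written["trips"] = directory / "trips.csv"

    labels = outputs.get("labels")
    if labels is None:
        labels = pd.DataFrame(columns=LABEL_COLUMNS)
    labels = labels.copy()
    if len(labels):
        labels["timestamp"] = _ts(pd.to_datetime(labels["timestamp"], utc=True))
    labels.to_csv(directory / "labels.csv", index=False)
    written["labels"] = directory / "labels.csv"

    world = outputs.get("world")
    if world is not None:
        with open(directory / "closure.geojson", "w") as fh:
            json.dump(world.closure_geojson(), fh)
        written["closure"] = directory / "closure.geojson"

    cfg = outputs.get("config")
    if cfg is not None:
        import yaml

        with open(directory / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
        written["config"] = directory / "config.yaml"
    return written


def read_dataset(directory) -> dict:
    """Read the artifacts written by :func:`write_dataset`."""
    from eetolab.world import SimWorld

    directory = Path(directory)
    out = {}
    pings = pd.read_csv(directory / "pings.csv", comment="#")
    if len(pings):
        pings["timestamp"] = pd.to_datetime(pings["timestamp"], utc=True)
    out["pings"] = pings
    trips = pd.read_csv(directory / "trips.csv", comment="#")
    if len(trips):
        trips["landing_date"] = pd.to_datetime(trips["landing_date"], utc=True)
    out["trips"] = trips
    labels = pd.read_csv(directory / "labels.csv", comment="#")
    if len(labels):
        labels["timestamp"] = pd.to_datetime(labels["timestamp"], utc=True)
    out["labels"] = labels
    geo = directory / "closure.geojson"
    if geo.exists():
        with open(geo) as fh:
            out["closure"] = SimWorld.closure_from_geojson(json.load(fh))
    return out
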