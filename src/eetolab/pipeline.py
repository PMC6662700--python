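"""End-to-end pipeline stages with reproducible artifacts.

Stages run in dependency order:

``simulate`` -> ``process`` -> ``metrics`` -> ``model`` -> ``windows``

Every CSV artifact starts with a single comment line recording the config
hash and seed; package readers skip it (``comment='#'``).  No stage mutates
an upstream artifact, and rerunning a stage with the same configuration
reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from eetolab import grounds, inference, metrics, performance, synthetic, tracks
from eetolab.config import EPOCH, RunConfig
from eetolab.errors import ConfigurationError
from eetolab.world import SimWorld, default_world

log = logging.getLogger(__name__)

STAGES = ["simulate", "process", "metrics", "model", "windows"]

_STAGE_INPUTS = {
    "process": ["pings.csv", "trips.csv", "labels.csv", "closure.geojson"],
    "metrics": ["classified_pings.csv", "trips.csv", "closure.geojson"],
    "model": ["profiles.csv", "trips.csv"],
    "windows": ["deviance.csv", "profiles.csv"],
}


def _header(config: RunConfig) -> str:
    return f"# eetolab config_hash={config.config_hash()} seed={config.seed}\n"


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(_header(config))
        df.to_csv(fh, index=False)


def _read_csv(path: Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kw)


def _require(outdir: Path, stage: str) -> None:
    for name in _STAGE_INPUTS.get(stage, []):
        if not (outdir / name).exists():
            order = {s: i for i, s in enumerate(STAGES)}
            raise ConfigurationError(
                f"stage '{stage}' needs {name}; run an earlier stage first "
                f"(missing artifact produced by '{STAGES[max(order[stage] - 1, 0)]}')"
            )


def closure_start(config: RunConfig) -> pd.Timestamp:
    return pd.Timestamp(EPOCH) + pd.Timedelta(days=config.fleet.undisturbed_days)


def stage_simulate(config: RunConfig, outdir: Path, world: SimWorld | None = None) -> dict:
    """Generate the fleet, both periods of tracks/trips/labels, and write them."""
    world = world if world is not None else default_world()
    fleet = synthetic.generate_fleet(config.fleet, world)
    und = synthetic.simulate_tracks(fleet, world, config.fleet)
    dist = synthetic.simulate_disturbance(fleet, world, config.fleet, und)
    pings = pd.concat(
        [und[0].assign(period="undisturbed"), dist[0].assign(period="disturbed")], ignore_index=True
    )
    trips = pd.concat([und[1], dist[1]], ignore_index=True)
    labels = pd.concat([und[2], dist[2]], ignore_index=True)
    exit_flags = dist[3]
    outdir.mkdir(parents=True, exist_ok=True)
    synthetic.write_dataset(
        {"pings": pings, "trips": trips, "labels": labels, "world": world, "config": config.fleet},
        outdir,
    )
    # rewrite tables with the run header for provenance
    ds = synthetic.read_dataset(outdir)
    for name in ("pings", "trips", "labels"):
        df = ds[name].copy()
        for c in ("timestamp", "landing_date"):
            if c in df.columns:
                df[c] = pd.to_datetime(df[c], utc=True).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
        _write_csv(df, outdir / f"{name}.csv", config)
    _write_csv(exit_flags, outdir / "exit_flags.csv", config)
    log.info(
        "simulate: %d vessels, %d pings, %d trips, %d exits",
        len(fleet),
        len(pings),
        len(trips),
        int(exit_flags["exited"].sum()),
    )
    return {"pings": pings, "trips": trips, "labels": labels, "exit_flags": exit_flags, "world": world}


def stage_process(config: RunConfig, outdir: Path, world: SimWorld | None = None) -> dict:
    """Clean pings, derive features, train/validate the classifier, classify."""
    _require(outdir, "process")
    world = world if world is not None else default_world()
    pings = _read_csv(outdir / "pings.csv")
    labels = _read_csv(outdir / "labels.csv")
    clog = tracks.CleaningLog()
    cleaned = tracks.clean_pings(
        pings,
        extent=world.extent,
        speed_threshold=config.speed_threshold,
        depth_fn=world.depth_fn,
        cleaning_log=clog,
    )
    feats = tracks.derive_features(cleaned, port=world.port)
    labels["timestamp"] = pd.to_datetime(labels["timestamp"], utc=True)
    merged = feats.merge(labels, on=["vessel_id", "timestamp"], how="inner")
    clf = tracks.ActivityClassifier(
        n_estimators=config.classifier_trees,
        port_radius_km=config.port_radius_km,
        random_state=config.seed,
    ).fit(merged[tracks.FEATURE_COLUMNS], merged["activity"])
    predicted = clf.predict(feats[tracks.FEATURE_COLUMNS])
    out = feats[["vessel_id", "timestamp"]].copy()
    out["activity"] = predicted
    classified = cleaned.merge(out, on=["vessel_id", "timestamp"], how="inner")
    dfw = classified.copy()
    dfw["timestamp"] = pd.to_datetime(dfw["timestamp"], utc=True).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    _write_csv(dfw, outdir / "classified_pings.csv", config)
    report = {
        "balanced_accuracy": clf.balanced_accuracy_,
        "n_labeled": int(len(merged)),
        "cleaning": vars(clog),
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    with open(outdir / "classifier_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    log.info(
        "process: %d cleaned pings, balanced accuracy %.3f (n_labeled=%d)",
        len(cleaned),
        clf.balanced_accuracy_,
        len(merged),
    )
    return {"classified": classified, "classifier": clf, "report": report}


def stage_metrics(config: RunConfig, outdir: Path, world: SimWorld | None = None) -> dict:
    """Grid, visitation series, strategy profiles and diagnostics."""
    _require(outdir, "metrics")
    world = world if world is not None else default_world()
    classified = _read_csv(outdir / "classified_pings.csv")
    classified["timestamp"] = pd.to_datetime(classified["timestamp"], utc=True)
    trips = _read_csv(outdir / "trips.csv")
    trips["landing_date"] = pd.to_datetime(trips["landing_date"], utc=True)
    t0 = closure_start(config)

    pre = classified.loc[classified["timestamp"] < t0]
    post = classified.loc[classified["timestamp"] >= t0]
    fishing_pre = pre.loc[pre["activity"] == "fishing"]
    # grid spans the full dataset so displaced post-closure effort is assignable
    grid = grounds.build_grid(classified.loc[classified["activity"] == "fishing"], n=config.grid_n)
    vis_pre = grounds.build_visitation_series(pre, grid, config.fleet.ping_interval)
    vis_post = grounds.build_visitation_series(post, grid, config.fleet.ping_interval) if len(post) else {}

    profiles = metrics.build_profiles(
        vis_pre,
        grid,
        world.closure,
        trips=trips.loc[trips["period"] == "undisturbed"] if "period" in trips.columns else trips,
        burn_in_fraction=config.burn_in_fraction,
        min_bouts=config.min_bouts,
    )
    if "depth" in fishing_pre.columns:
        mean_depth = fishing_pre.groupby("vessel_id")["depth"].mean()
        profiles["mean_depth"] = profiles["vessel_id"].map(mean_depth)
    _write_csv(profiles, outdir / "profiles.csv", config)

    diagnostics = {}
    if "mean_depth" in profiles.columns and len(profiles) >= 3:
        diagnostics["depth_entropy"] = metrics.depth_entropy_check(
            profiles.drop(columns=["mean_depth"]),
            profiles.set_index("vessel_id")["mean_depth"],
        )
    if "trip_id" in pre.columns:
        try:
            diagnostics["revenue_per_km"] = metrics.revenue_per_km(
                trips.loc[trips["period"] == "undisturbed"], pre, profiles
            )
        except ValueError as exc:
            log.warning("revenue/km diagnostic skipped: %s", exc)
    if diagnostics:
        with open(outdir / "diagnostics.json", "w") as fh:
            json.dump(diagnostics, fh, indent=2, default=float)

    traj_rows = []
    vis_rows = []
    for vid, series in vis_pre.items():
        if len(series) == 0:
            continue
        seq = series["cell_col"].astype(str) + "_" + series["cell_row"].astype(str)
        traj = metrics.entropy_trajectory(seq, vessel_id=vid)
        traj_rows.append(pd.DataFrame({"vessel_id": vid, "m": np.arange(1, len(traj) + 1), "S_im": traj.S, "N_im": traj.N}))
        v = series.copy()
        v.insert(0, "vessel_id", vid)
        vis_rows.append(v)
    _write_csv(pd.concat(traj_rows, ignore_index=True) if traj_rows else pd.DataFrame(), outdir / "entropy_trajectories.csv", config)
    visw = pd.concat(vis_rows, ignore_index=True) if vis_rows else pd.DataFrame()
    for c in ("bout_start", "bout_end"):
        if c in visw.columns:
            visw[c] = pd.to_datetime(visw[c], utc=True).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    _write_csv(visw, outdir / "visitation.csv", config)

    # disturbance-period entropy (recomputed under the same burn-in rule)
    post_scores = {}
    for vid, series in vis_post.items():
        if len(series) >= 2:
            seq = series["cell_col"].astype(str) + "_" + series["cell_row"].astype(str)
            post_scores[vid] = metrics.entropy_score(
                metrics.entropy_trajectory(seq), config.burn_in_fraction
            )
    post_prt = {vid: metrics.patch_residence_time(s) for vid, s in vis_post.items() if len(s) > 0}
    during = pd.DataFrame(
        {"vessel_id": list(post_scores), "S_during": list(post_scores.values())}
    )
    during["prt_during"] = during["vessel_id"].map(post_prt)
    _write_csv(during, outdir / "profiles_during.csv", config)
    log.info("metrics: %d profiled vessels (%d during closure)", len(profiles), len(during))
    return {"grid": grid, "profiles": profiles, "during": during, "visitation": vis_pre}


def stage_model(config: RunConfig, outdir: Path) -> dict:
    """Fleet index, pruning, outlier removal, undisturbed fit, deviance, inference."""
    _require(outdir, "model")
    trips = _read_csv(outdir / "trips.csv")
    trips["landing_date"] = pd.to_datetime(trips["landing_date"], utc=True)
    profiles = _read_csv(outdir / "profiles.csv")
    t0 = closure_start(config)

    und = trips.loc[trips["period"] == "undisturbed"].copy()
    dis = trips.loc[trips["period"] == "disturbed"].copy()
    und = performance.prune_boundary_trips(und, t0, config.f_window_days)
    und, removed = performance.remove_revenue_outliers(und, config.outlier_factor)

    F_und = performance.fleet_performance(und, config.f_window_days)
    model = performance.UndisturbedRevenueModel(
        window_days=config.f_window_days, link=config.link
    ).fit(und, F_und)
    F_dis = performance.fleet_performance(dis, config.f_window_days, reference=trips)
    dev = performance.compute_deviance(model, dis, F_dis, closure_start=t0)
    devw = dev.copy()
    devw["landing_date"] = pd.to_datetime(devw["landing_date"], utc=True).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    _write_csv(devw, outdir / "deviance.csv", config)

    scaled = inference.scale_covariates(profiles)
    _write_csv(scaled, outdir / "profiles_scaled.csv", config)
    P = model.performance_
    eq5_terms = [t for t in inference.EQ5_TERMS if t in scaled.columns]
    common = scaled.loc[scaled["vessel_id"].isin(P.index)]
    eq5 = inference.fit_strategy_performance(common, P, terms=eq5_terms)
    sel_terms, eq5_sel = inference.stepwise_select(
        lambda ts: inference.fit_strategy_performance(common, P, terms=ts), eq5_terms
    )
    merged = dev.merge(scaled, on="vessel_id", how="inner")
    eq6_terms = [t for t in inference.EQ6_TERMS if t in merged.columns]
    eq6 = inference.DevianceMixedModel(terms=eq6_terms).fit(merged).result_
    shift = None
    during_path = outdir / "profiles_during.csv"
    if during_path.exists():
        during = _read_csv(during_path)
        both = profiles.merge(during, on="vessel_id", how="left")
        if during["S_during"].notna().sum() >= 2:
            shift = {
                "entropy": inference.fleet_shift_test(
                    profiles["S"], during["S_during"].dropna()
                ),
                "prt": inference.fleet_shift_test(profiles["prt"], during["prt_during"].dropna()),
            }

    summary = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "undisturbed": model.summary_dict(),
        "n_boundary_pruned": int(len(trips.loc[trips["period"] == "undisturbed"]) - len(und) - len(removed)),
        "n_outliers_removed": int(len(removed)),
        "eq5": {
            "aic": eq5.aic,
            "bic": eq5.bic,
            "n": eq5.n,
            "table": eq5.table.to_dict(orient="records"),
            "selected_terms": sel_terms,
        },
        "eq6": {
            "aic": eq6.aic,
            "bic": eq6.bic,
            "n": eq6.n,
            "random_intercept_var": eq6.random_intercept_var,
            "singular": bool(eq6.singular),
            "table": eq6.table.to_dict(orient="records"),
        },
        "fleet_shift": shift,
    }
    with open(outdir / "model_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    log.info(
        "model: beta_duration=%.2f beta_fleet=%.3f, %d deviance records",
        model.beta_duration_,
        model.beta_fleet_,
        len(dev),
    )
    return {"model": model, "deviance": dev, "eq5": eq5, "eq6": eq6, "summary": summary}


def stage_windows(config: RunConfig, outdir: Path) -> pd.DataFrame:
    """Growing-window coefficient trajectories."""
    _require(outdir, "windows")
    dev = _read_csv(outdir / "deviance.csv")
    scaled = _read_csv(outdir / "profiles_scaled.csv")
    table = inference.growing_window(
        dev, scaled, step=config.window_step, horizon=config.window_horizon
    )
    _write_csv(table, outdir / "growing_window.csv", config)
    log.info("windows: %d rows across %d windows", len(table), table["window_end_day"].nunique())
    return table


def run(stage: str, config: RunConfig, outdir) -> None:
    """Run one pipeline stage (or ``all``) into ``outdir``."""
    outdir = Path(outdir)
    stages = STAGES if stage == "all" else [stage]
    if stage != "all" and stage not in STAGES:
        raise ConfigurationError(f"unknown stage {stage!r}; choose from {STAGES + ['all']}")
    for s in stages:
        log.info("--- stage %s ---", s)
        if s == "simulate":
            stage_simulate(config, outdir)
        elif s == "process":
            stage_process(config, outdir)
        elif s == "metrics":
            stage_metrics(config, outdir)
        elif s == "model":
            stage_model(config, outdir)
        elif s == "windows":
            stage_windows(config, outdir)
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": stages,
        "artifacts": sorted(p.name for p in outdir.glob("*") if p.is_file()),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
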