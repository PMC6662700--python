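"""Configuration objects for the synthetic fleet and the pipeline.

All thresholds used by the analysis (speed cut-off, grid size, fleet-index
window, burn-in fraction, growing-window step/horizon) live here as defaults
so a run is fully described by one YAML file plus a seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from eetolab.errors import ConfigurationError

#: Study epoch: all simulated timestamps are hours since this UTC instant.
EPOCH = "2007-05-18T00:00:00Z"


def _check_range(name: str, rng: tuple) -> tuple:
    lo, hi = float(rng[0]), float(rng[1])
    if not lo <= hi:
        raise ConfigurationError(f"{name} must be ordered (low <= high), got {rng}")
    return (lo, hi)


@dataclass
class FleetConfig:
    """Parameters of the synthetic fleet generator.

    The defaults describe a fleet of 100 heterogeneous longline vessels
    reporting hourly positions over one undisturbed year followed by a
    50-day spatial closure.

    Parameters
    ----------
    n_vessels : int
        Fleet size.
    undisturbed_days, disturbed_days : int
        Length of the pre-closure and closure periods.
    ping_interval : float
        Hours between successive position reports.
    portfolio_size_range : (int, int)
        Number of fishing sites per vessel, sampled uniformly.
    choice_concentration_range : (float, float)
        Symmetric-Dirichlet concentration for per-site choice weights,
        sampled log-uniformly.  Low concentration produces skewed,
        low-entropy choosers; high concentration produces even, high-entropy
        choosers.
    prt_mean_range : (float, float)
        Mean fishing-bout duration per vessel (hours), sampled uniformly.
    vessel_length_range : (float, float)
        Vessel length (metres), sampled uniformly.
    skill_mean, skill_sd : float
        Per-vessel mean trip revenue (the vessel-performance component
        ``P_i``) is Normal(skill_mean, skill_sd).
    beta_duration : float
        Revenue per sea day.
    beta_fleet : float
        Loading of trip revenue on the fleet-wide temporal factor.
    fleet_amplitude, fleet_shock_sd, fleet_shock_corr : float
        Seasonal sinusoid amplitude and AR(1) daily-shock parameters of the
        fleet-wide revenue factor.
    noise_sd : float
        Trip-level revenue noise SD.
    trip_duration_range : (float, float)
        Planned trip length (days), sampled uniformly.
    port_gap_mean_days : float
        Mean of the exponential port stay between trips.
    observer_fraction : float
        Fraction of trips carrying per-ping observer activity labels.
    exit_baseline, exit_entropy_coef : float
        Each vessel exits at the closure with probability
        ``logistic(exit_baseline - exit_entropy_coef * z(S_true))``; positive
        ``exit_entropy_coef`` makes broad explorers more likely to remain.
    deviance_entropy_coef, deviance_displacement_coef : float
        Effect of standardized true entropy (positive) and displacement
        (negative) on relative performance deviance at closure onset.
    deviance_decay_halflife : float
        Days for the deviance effect to halve.
    deviance_noise_sd : float
        Trip-level noise on the relative deviance.
    seed : int
        Root seed; every random draw in the generator descends from it.
    """

    n_vessels: int = 100
    undisturbed_days: int = 365
    disturbed_days: int = 50
    ping_interval: float = 1.0
    portfolio_size_range: tuple = (2, 20)
    choice_concentration_range: tuple = (0.3, 6.0)
    prt_mean_range: tuple = (6.0, 48.0)
    vessel_length_range: tuple = (15.0, 30.0)
    skill_mean: float = 10_000.0
    skill_sd: float = 1_500.0
    beta_duration: float = 800.0
    beta_fleet: float = 1.0
    fleet_amplitude: float = 1_000.0
    fleet_shock_sd: float = 300.0
    fleet_shock_corr: float = 0.8
    noise_sd: float = 500.0
    trip_duration_range: tuple = (2.0, 15.0)
    port_gap_mean_days: float = 3.0
    observer_fraction: float = 0.2
    exit_baseline: float = 0.0
    exit_entropy_coef: float = 1.5
    deviance_entropy_coef: float = 0.20
    deviance_displacement_coef: float = 0.20
    deviance_decay_halflife: float = 20.0
    deviance_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vessels < 2:
            raise ConfigurationError(f"n_vessels must be >= 2, got {self.n_vessels}")
        if self.ping_interval <= 0:
            raise ConfigurationError("ping_interval must be > 0")
        lo, hi = self.portfolio_size_range
        if not (1 <= int(lo) <= int(hi)):
            raise ConfigurationError(
                f"portfolio_size_range must satisfy 1 <= low <= high, got {self.portfolio_size_range}"
            )
        self.portfolio_size_range = (int(lo), int(hi))
        for name in (
            "choice_concentration_range",
            "prt_mean_range",
            "vessel_length_range",
            "trip_duration_range",
        ):
            setattr(self, name, _check_range(name, getattr(self, name)))
        if self.choice_concentration_range[0] <= 0:
            raise ConfigurationError("choice_concentration_range must be positive")
        if self.prt_mean_range[0] <= 0:
            raise ConfigurationError("prt_mean_range must be positive")
        if not 0.0 <= self.observer_fraction <= 1.0:
            raise ConfigurationError("observer_fraction must lie in [0, 1]")
        if self.deviance_decay_halflife <= 0:
            raise ConfigurationError("deviance_decay_halflife must be > 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FleetConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ConfigurationError(f"unknown FleetConfig keys: {sorted(extra)}")
        d = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        return cls(**d)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (one YAML file per run)."""

    fleet: FleetConfig = field(default_factory=FleetConfig)
    grid_n: int = 30
    burn_in_fraction: float = 0.5
    min_bouts: int = 20
    speed_threshold: float = 20.0
    port_radius_km: float = 2.0
    classifier_trees: int = 500
    f_window_days: float = 14.0
    outlier_factor: float = 5.0
    link: str = "identity"
    window_step: float = 10.0
    window_horizon: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.fleet, dict):
            self.fleet = FleetConfig.from_dict(self.fleet)
        if not 0.0 < self.burn_in_fraction < 1.0:
            raise ConfigurationError("burn_in_fraction must lie in (0, 1)")
        if self.link not in ("identity", "log"):
            raise ConfigurationError(f"link must be 'identity' or 'log', got {self.link!r}")
        if self.grid_n < 2:
            raise ConfigurationError("grid_n must be >= 2")
        # keep the fleet seed in lock-step with the run seed unless set apart
        self.fleet.seed = self.fleet.seed or self.seed

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ConfigurationError(f"unknown RunConfig keys: {sorted(extra)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        """Stable short hash identifying the configuration (seed included)."""
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
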