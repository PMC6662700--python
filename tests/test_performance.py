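"""Fleet index, trip filters, the business-as-usual model and deviance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eetolab import synthetic
from eetolab.config import FleetConfig
from eetolab.performance import (
    UndisturbedRevenueModel,
    compute_deviance,
    fleet_performance,
    prune_boundary_trips,
    remove_revenue_outliers,
    window_bias_check,
)


def _trips(rows):
    df = pd.DataFrame(rows, columns=["vessel_id", "trip_id", "landing_date", "duration_days", "revenue"])
    return df


class TestFleetPerformance:
    def test_toy_window_mean(self):
        trips = _trips(
            [
                ("i", 0, "2007-01-01", 5.0, 100.0),
                ("a", 1, "2007-01-05", 5.0, 20.0),
                ("b", 2, "2007-01-10", 5.0, 40.0),
                ("c", 3, "2007-01-21", 5.0, 999.0),  # outside the 14-day window
            ]
        )
        F = fleet_performance(trips)
        assert F.iloc[0] == pytest.approx(30.0)

    def test_single_other_trip(self):
        trips = _trips(
            [("i", 0, "2007-01-01", 5.0, 100.0), ("a", 1, "2007-01-03", 5.0, 77.0)]
        )
        assert fleet_performance(trips).iloc[0] == pytest.approx(77.0)

    def test_leave_one_out_invariance(self):
        trips = _trips(
            [
                ("i", 0, "2007-01-01", 5.0, 100.0),
                ("i", 1, "2007-01-06", 5.0, 500.0),
                ("a", 2, "2007-01-05", 5.0, 20.0),
                ("b", 3, "2007-01-10", 5.0, 40.0),
            ]
        )
        F1 = fleet_performance(trips).iloc[0]
        trips2 = trips.copy()
        trips2.loc[trips2["vessel_id"] == "i", "revenue"] = [9e9, 8e8]
        assert fleet_performance(trips2).iloc[0] == pytest.approx(F1)

    def test_window_is_half_open_after_landing(self):
        trips = _trips(
            [
                ("i", 0, "2007-01-01", 5.0, 100.0),
                ("a", 1, "2007-01-01", 5.0, 11.0),  # same day: excluded, (t, t+14]
                ("b", 2, "2007-01-15", 5.0, 33.0),  # day t+14: included
            ]
        )
        assert fleet_performance(trips).iloc[0] == pytest.approx(33.0)

    def test_no_contemporaneous_trips_gives_nan(self):
        trips = _trips(
            [("i", 0, "2007-01-01", 5.0, 100.0), ("a", 1, "2007-06-01", 5.0, 20.0)]
        )
        assert np.isnan(fleet_performance(trips).iloc[0])

    def test_skewed_vs_symmetric_window_agree_on_seasonal_fleet(self):
        cfg = FleetConfig(n_vessels=100, undisturbed_days=365, seed=21)
        fleet = synthetic.generate_fleet(cfg)
        trips = synthetic.simulate_trip_table(fleet, cfg, rng=np.random.default_rng(21))
        out = window_bias_check(trips)
        assert out["r"] > 0.8
        assert out["df"] == out["n"] - 2

    def test_constant_revenue_degenerate(self):
        rows = [("v%d" % (i % 5), i, f"2007-01-{1 + i % 27:02d}", 5.0, 50.0) for i in range(30)]
        out = window_bias_check(_trips(rows))
        assert np.isnan(out["r"])


class TestTripFilters:
    def test_boundary_pruning_window(self):
        trips = _trips(
            [
                ("a", 0, "2007-05-05", 5.0, 10.0),  # 13 days before: removed
                ("b", 1, "2007-05-03", 5.0, 10.0),  # 15 days before: retained
                ("c", 2, "2007-05-18", 5.0, 10.0),  # on closure start: retained
            ]
        )
        out = prune_boundary_trips(trips, "2007-05-18")
        assert sorted(out["vessel_id"]) == ["b", "c"]

    def test_pruned_count_matches_date_filter_oracle(self, sim, small_config):
        _, trips, _ = sim
        closure = pd.Timestamp("2007-05-18", tz="UTC") + pd.Timedelta(days=small_config.undisturbed_days)
        out = prune_boundary_trips(trips, closure)
        land = pd.to_datetime(trips["landing_date"], utc=True)
        expected = ((land >= closure - pd.Timedelta(days=14)) & (land < closure)).sum()
        assert len(trips) - len(out) == expected

    def test_outlier_removed(self):
        trips = _trips([("a", i, "2007-01-01", 1.0, r) for i, r in enumerate([1, 1, 1, 10])])
        kept, removed = remove_revenue_outliers(trips, factor=5)
        assert len(kept) == 3 and removed["revenue"].iloc[0] == 10

    def test_no_outlier_retained(self):
        trips = _trips([("a", i, "2007-01-01", 1.0, r) for i, r in enumerate([1, 1, 1, 4])])
        kept, removed = remove_revenue_outliers(trips, factor=5)
        assert len(kept) == 4 and len(removed) == 0

    def test_eightfold_outlier_removed(self):
        trips = _trips(
            [("a", i, "2007-01-01", 1.0, r) for i, r in enumerate([100.0, 12.0, 11.0, 9.0])]
        )
        kept, removed = remove_revenue_outliers(trips, factor=5)
        assert 100.0 not in kept["revenue"].to_numpy()
        assert len(removed) == 1


def _bau_fleet(n_vessels=40, seed=0, **over):
    cfg = FleetConfig(
        n_vessels=n_vessels,
        undisturbed_days=over.pop("undisturbed_days", 365),
        seed=seed,
        **over,
    )
    fleet = synthetic.generate_fleet(cfg)
    return cfg, fleet


class TestUndisturbedModel:
    def test_noiseless_exact_recovery(self):
        cfg, fleet = _bau_fleet(n_vessels=10, seed=2, noise_sd=0.0)
        trips = synthetic.simulate_trip_table(fleet, cfg, rng=np.random.default_rng(2))
        model = UndisturbedRevenueModel().fit(trips, trips["fleet_factor_true"])
        assert model.beta_duration_ == pytest.approx(cfg.beta_duration, rel=1e-8)
        assert model.beta_fleet_ == pytest.approx(cfg.beta_fleet, rel=1e-8)
        skills = trips.groupby("vessel_id")["skill_true"].first()
        for vid, p in model.performance_.items():
            assert p == pytest.approx(skills.loc[vid], rel=1e-8)

    def test_trip_order_invariance(self):
        cfg, fleet = _bau_fleet(n_vessels=8, seed=3)
        trips = synthetic.simulate_trip_table(fleet, cfg, rng=np.random.default_rng(3))
        F = trips["fleet_factor_true"]
        m1 = UndisturbedRevenueModel().fit(trips, F)
        perm = np.random.default_rng(0).permutation(len(trips))
        m2 = UndisturbedRevenueModel().fit(trips.iloc[perm], F.iloc[perm])
        assert m1.beta_duration_ == pytest.approx(m2.beta_duration_)
        pd.testing.assert_series_equal(m1.performance_.sort_index(), m2.performance_.sort_index())

    def test_single_trip_vessel_excluded(self):
        cfg, fleet = _bau_fleet(n_vessels=6, seed=4)
        trips = synthetic.simulate_trip_table(fleet, cfg, rng=np.random.default_rng(4))
        lone = trips.iloc[:1].copy()
        lone["vessel_id"] = 999
        lone["trip_id"] = 10_000
        all_trips = pd.concat([trips, lone], ignore_index=True)
        F = all_trips["fleet_factor_true"]
        model = UndisturbedRevenueModel().fit(all_trips, F)
        assert 999 not in model.performance_.index
        assert 999 in model.dropped_vessels_

    def test_beta_recovery_low_bias(self):
        """Across seeds, duration and fleet coefficients are near-unbiased."""
        b1, b2 = [], []
        for seed in range(10):
            cfg, fleet = _bau_fleet(n_vessels=40, seed=seed, undisturbed_days=200)
            trips = synthetic.simulate_trip_table(fleet, cfg, rng=np.random.default_rng(seed))
            model = UndisturbedRevenueModel().fit(trips, trips["fleet_factor_true"])
            b1.append(model.beta_duration_)
            b2.append(model.beta_fleet_)
        cfg0 = FleetConfig()
        assert abs(np.mean(b1) - cfg0.beta_duration) < 0.02 * cfg0.beta_duration
        assert abs(np.mean(b2) - cfg0.beta_fleet) < 0.02 * cfg0.beta_fleet


class TestDeviance:
    @staticmethod
    def _fit_and_deviate(cfg, fleet, seed, deviance_terms=None, disturbed_days=50):
        rng = np.random.default_rng(seed)
        und = synthetic.simulate_trip_table(fleet, cfg, rng=rng)
        model = UndisturbedRevenueModel().fit(und, und["fleet_factor_true"])
        dis = synthetic.simulate_trip_table(
            fleet,
            cfg,
            n_days=disturbed_days,
            rng=rng,
            period="disturbed",
            deviance_terms=deviance_terms,
            start_day=cfg.undisturbed_days,
        )
        dev = compute_deviance(model, dis, dis["fleet_factor_true"])
        return model, dis, dev

    def test_business_as_usual_null_centred(self):
        cfg, fleet = _bau_fleet(n_vessels=40, seed=5)
        _, _, dev = self._fit_and_deviate(cfg, fleet, seed=5)
        mean = dev["deltaP"].mean()
        se = dev["deltaP"].std() / np.sqrt(len(dev))
        assert abs(mean) < 2.0 * se + 1e-12

    def test_null_deviance_approximately_gaussian(self):
        cfg, fleet = _bau_fleet(n_vessels=40, seed=6)
        _, _, dev = self._fit_and_deviate(cfg, fleet, seed=6)
        sample = dev["deltaP"].to_numpy()[:50]
        stat, p = stats.shapiro(sample)
        assert p > 0.01

    def test_doubled_revenue_shifts_deviance_positive(self):
        cfg, fleet = _bau_fleet(n_vessels=20, seed=7)
        model, dis, dev = self._fit_and_deviate(cfg, fleet, seed=7)
        dis2 = dis.copy()
        dis2["revenue"] = dis2["revenue"] * 2.0
        dev2 = compute_deviance(model, dis2, dis2["fleet_factor_true"])
        assert dev2["deltaP"].mean() > dev["deltaP"].mean() + 0.5

    def test_uniform_deviance_recovered(self):
        """A flat -30% shock to vessel performance shows up as mean deltaP ~ -0.3."""
        cfg = FleetConfig(
            n_vessels=40,
            seed=8,
            deviance_entropy_coef=0.3,
            deviance_displacement_coef=0.0,
            deviance_decay_halflife=1e9,
            deviance_noise_sd=0.0,
        )
        fleet = synthetic.generate_fleet(cfg)
        terms = {"S_z": -np.ones(len(fleet)), "d_z": np.zeros(len(fleet))}
        _, _, dev = self._fit_and_deviate(cfg, fleet, seed=8, deviance_terms=terms)
        assert dev["deltaP"].mean() == pytest.approx(-0.3, abs=0.05)

    def test_scale_invariance_of_deviance(self):
        cfg, fleet = _bau_fleet(n_vessels=10, seed=9, noise_sd=0.0)
        rng = np.random.default_rng(9)
        und = synthetic.simulate_trip_table(fleet, cfg, rng=rng)
        dis = synthetic.simulate_trip_table(
            fleet, cfg, n_days=40, rng=rng, period="disturbed", start_day=cfg.undisturbed_days
        )
        model1 = UndisturbedRevenueModel().fit(und, und["fleet_factor_true"])
        dev1 = compute_deviance(model1, dis, dis["fleet_factor_true"])
        c = 3.7
        und2 = und.copy()
        und2["revenue"] *= c
        dis2 = dis.copy()
        dis2["revenue"] *= c
        model2 = UndisturbedRevenueModel().fit(und2, und2["fleet_factor_true"] * c)
        dev2 = compute_deviance(model2, dis2, dis2["fleet_factor_true"] * c)
        assert np.allclose(dev1["deltaP"], dev2["deltaP"], atol=1e-8)

    def test_unknown_vessel_excluded(self):
        cfg, fleet = _bau_fleet(n_vessels=6, seed=10)
        model, dis, _ = self._fit_and_deviate(cfg, fleet, seed=10)
        ghost = dis.iloc[:1].copy()
        ghost["vessel_id"] = 12345
        dev = compute_deviance(model, ghost, ghost["fleet_factor_true"])
        assert len(dev) == 0

    def test_identity_when_measured_equals_expected(self):
        cfg, fleet = _bau_fleet(n_vessels=6, seed=11, noise_sd=0.0, fleet_amplitude=0.0, fleet_shock_sd=0.0)
        _, _, dev = self._fit_and_deviate(cfg, fleet, seed=11)
        # noiseless business as usual: Md equals Ed exactly, deltaP = 0
        assert np.allclose(dev["deltaP"], 0.0, atol=1e-8)

    def test_log_link_mode_runs_end_to_end(self):
        cfg, fleet = _bau_fleet(n_vessels=10, seed=12)
        rng = np.random.default_rng(12)
        und = synthetic.simulate_trip_table(fleet, cfg, rng=rng)
        model = UndisturbedRevenueModel(link="log").fit(und, und["fleet_factor_true"])
        dis = synthetic.simulate_trip_table(
            fleet, cfg, n_days=40, rng=rng, period="disturbed", start_day=cfg.undisturbed_days
        )
        dev = compute_deviance(model, dis, dis["fleet_factor_true"])
        assert np.isfinite(dev["deltaP"]).all()
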