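"""Covariate scaling, strategy regressions, selection and the growing window."""

import numpy as np
import pandas as pd
import pytest

from eetolab.inference import (
    CovariateScaler,
    DevianceMixedModel,
    EQ6_TERMS,
    fit_strategy_performance,
    fleet_shift_test,
    growing_window,
    scale_covariates,
    stepwise_select,
)


def _profiles(n=60, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "vessel_id": np.arange(n),
            "S": rng.normal(4.0, 1.0, n),
            "prt": rng.lognormal(3.0, 0.4, n),
            "activity": rng.uniform(50, 250, n),
            "length_m": rng.uniform(15, 30, n),
            "displacement": rng.uniform(0, 1, n),
        }
    )


class TestScaling:
    def test_three_point_column(self):
        prof = pd.DataFrame({"vessel_id": [1, 2, 3], "S": [1.0, 2.0, 3.0]})
        out = scale_covariates(prof, columns=["S"])
        assert np.allclose(out["S_z"], [-1.0, 0.0, 1.0])

    def test_idempotent_on_standardized_column(self):
        prof = _profiles()
        once = scale_covariates(prof)
        prof2 = prof.copy()
        prof2["S"] = once["S_z"]
        twice = scale_covariates(prof2)
        assert np.allclose(twice["S_z"], once["S_z"])

    def test_affine_invariance(self):
        prof = _profiles()
        a = scale_covariates(prof)["S_z"]
        prof2 = prof.copy()
        prof2["S"] = 3.0 * prof2["S"] - 17.0
        b = scale_covariates(prof2)["S_z"]
        assert np.allclose(a, b)

    def test_zero_variance_named_in_error(self):
        prof = _profiles()
        prof["prt"] = 5.0
        with pytest.raises(ValueError, match="prt"):
            scale_covariates(prof)

    def test_unit_moments_and_quadratics(self):
        out = scale_covariates(_profiles())
        for c in ["S_z", "prt_z", "activity_z", "length_m_z", "displacement_z"]:
            assert out[c].mean() == pytest.approx(0.0, abs=1e-9)
            assert out[c].std(ddof=1) == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(out["S_sq"], out["S_z"] ** 2)

    def test_transformer_applies_fitted_scale(self):
        prof = _profiles()
        sc = CovariateScaler().fit(prof)
        out = sc.transform(prof.iloc[:5])
        ref = scale_covariates(prof)
        assert np.allclose(out["S_z"], ref["S_z"].iloc[:5])


class TestStrategyPerformanceModel:
    def test_recovers_length_effect(self):
        rng = np.random.default_rng(1)
        prof = scale_covariates(_profiles(n=100, seed=1))
        P = 1000.0 + 300.0 * prof["length_m_z"] + rng.normal(0, 50, 100)
        res = fit_strategy_performance(prof, pd.Series(P.to_numpy(), index=prof["vessel_id"]))
        lo, hi = res.conf_int("length_m_z")
        assert lo <= 300.0 <= hi
        assert res.pvalue("length_m_z") < 1e-6

    def test_detects_humped_entropy_effect(self):
        rng = np.random.default_rng(2)
        prof = scale_covariates(_profiles(n=100, seed=2))
        P = 1000.0 - 150.0 * prof["S_sq"] + rng.normal(0, 50, 100)
        res = fit_strategy_performance(prof, pd.Series(P.to_numpy(), index=prof["vessel_id"]))
        assert res.coef("S_sq") < 0
        assert res.pvalue("S_sq") < 1e-4

    def test_too_few_vessels_rejected(self):
        prof = scale_covariates(_profiles(n=8))
        with pytest.raises(ValueError):
            fit_strategy_performance(prof, np.arange(8.0), terms=EQ6_TERMS)


class TestStepwise:
    @staticmethod
    def _fit_fn(prof, y):
        return lambda terms: fit_strategy_performance(prof, y, terms=terms)

    def test_pure_noise_mostly_reduced_to_intercept(self):
        reduced_all = 0
        for seed in range(30):
            rng = np.random.default_rng(10_000 + seed)
            prof = scale_covariates(_profiles(n=80, seed=seed))
            y = pd.Series(rng.normal(0, 1, 80).astype(float), index=prof["vessel_id"])
            terms, _ = stepwise_select(self._fit_fn(prof, y), list(EQ6_TERMS))
            reduced_all += len(terms) <= 2
        assert reduced_all >= 18  # majority of null runs end near intercept-only

    def test_strong_effect_always_retained(self):
        for seed in range(30):
            rng = np.random.default_rng(100 + seed)
            prof = scale_covariates(_profiles(n=80, seed=seed))
            y = pd.Series(
                (5.0 * prof["displacement_z"] + rng.normal(0, 0.5, 80)).to_numpy(),
                index=prof["vessel_id"],
            )
            terms, _ = stepwise_select(self._fit_fn(prof, y), list(EQ6_TERMS))
            assert "displacement_z" in terms

    def test_minimal_model_is_fixed_point(self):
        rng = np.random.default_rng(3)
        prof = scale_covariates(_profiles(n=60, seed=3))
        y = pd.Series(
            (4.0 * prof["S_z"] + rng.normal(0, 0.1, 60)).to_numpy(), index=prof["vessel_id"]
        )
        terms, _ = stepwise_select(self._fit_fn(prof, y), ["S_z"])
        assert terms == ["S_z"]

    def test_linear_never_dropped_before_its_quadratic(self):
        rng = np.random.default_rng(4)
        prof = scale_covariates(_profiles(n=80, seed=4))
        # effect purely quadratic in S: the linear term is noise, but must
        # survive as long as S_sq is in the model
        y = pd.Series(
            (3.0 * prof["S_sq"] + rng.normal(0, 0.3, 80)).to_numpy(), index=prof["vessel_id"]
        )
        terms, _ = stepwise_select(self._fit_fn(prof, y), list(EQ6_TERMS))
        if "S_sq" in terms:
            assert "S_z" in terms


def _deviance_data(n_vessels=40, trips_per_vessel=4, seed=0, effects=None, re_sd=0.05):
    rng = np.random.default_rng(seed)
    prof = scale_covariates(_profiles(n=n_vessels, seed=seed))
    effects = effects or {}
    rows = []
    b0 = rng.normal(0, re_sd, n_vessels)
    for i in range(n_vessels):
        mu = b0[i] + sum(coef * prof.loc[i, term] for term, coef in effects.items())
        for t in range(trips_per_vessel):
            rows.append(
                {
                    "vessel_id": i,
                    "trip_id": i * 100 + t,
                    "deltaP": mu + rng.normal(0, 0.05),
                    "days_since_closure": rng.uniform(0, 50),
                }
            )
    return pd.DataFrame(rows).merge(prof, on="vessel_id"), prof


class TestDevianceMixedModel:
    def test_recovers_effect_signs(self):
        data, _ = _deviance_data(effects={"S_z": 0.1, "displacement_z": -0.15}, seed=5)
        m = DevianceMixedModel().fit(data)
        tab = m.fixef_.set_index("term")
        assert tab.loc["S_z", "estimate"] > 0
        assert tab.loc["displacement_z", "estimate"] < 0

    def test_one_trip_per_vessel_matches_ols(self):
        data, _ = _deviance_data(trips_per_vessel=1, re_sd=0.0, seed=6)
        m = DevianceMixedModel().fit(data)
        from eetolab.inference import _ols_result

        ols = _ols_result(data["deltaP"].to_numpy(), data, m.terms_)
        ours = m.fixef_.set_index("term")["estimate"]
        theirs = ols.table.set_index("term")["estimate"]
        assert np.allclose(ours.to_numpy(), theirs.to_numpy(), atol=1e-5)

    def test_zero_random_variance_reproduces_ols(self):
        data, _ = _deviance_data(re_sd=0.0, seed=7, effects={"S_z": 0.2})
        m = DevianceMixedModel().fit(data)
        from eetolab.inference import _ols_result

        ols = _ols_result(data["deltaP"].to_numpy(), data, m.terms_)
        assert np.allclose(
            m.fixef_.set_index("term")["estimate"].to_numpy(),
            ols.table.set_index("term")["estimate"].to_numpy(),
            atol=2e-3,
        )

    def test_duplicating_balanced_trips_keeps_estimates(self):
        data, _ = _deviance_data(trips_per_vessel=3, seed=8, effects={"S_z": 0.1})
        m1 = DevianceMixedModel().fit(data)
        doubled = pd.concat([data, data], ignore_index=True)
        m2 = DevianceMixedModel().fit(doubled)
        assert np.allclose(
            m1.fixef_["estimate"].to_numpy(), m2.fixef_["estimate"].to_numpy(), atol=1e-3
        )

    def test_random_intercept_variance_nonnegative(self):
        data, _ = _deviance_data(seed=9, re_sd=0.15)
        m = DevianceMixedModel().fit(data)
        assert m.re_var_ >= 0.0


class TestFleetShift:
    def test_identical_groups_null(self):
        out = fleet_shift_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["F"] == 0.0 and out["p"] == 1.0

    def test_hand_computed_f(self):
        out = fleet_shift_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert out["F"] == pytest.approx(1.5)
        assert out["df"] == (1, 4)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            fleet_shift_test([1.0], [1.0, 2.0])

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(10)
        pooled = rng.normal(0, 1, 60)
        hits = 0
        n_perm = 1000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            out = fleet_shift_test(perm[:30], perm[30:])
            hits += out["p"] < 0.05
        assert abs(hits / n_perm - 0.05) <= 0.02


class TestGrowingWindow:
    def test_final_window_matches_direct_fit(self):
        data, prof = _deviance_data(seed=11, effects={"S_z": 0.1})
        dev = data[["vessel_id", "trip_id", "deltaP", "days_since_closure"]]
        table = growing_window(dev, prof)
        final = table.loc[(table["window_end_day"] == 50.0) & (table["term"] == "S_z"), "estimate"].iloc[0]
        direct = (
            DevianceMixedModel()
            .fit(dev.loc[dev["days_since_closure"] <= 50.0].merge(prof, on="vessel_id"))
            .fixef_.set_index("term")
            .loc["S_z", "estimate"]
        )
        assert final == pytest.approx(direct, abs=1e-8)

    def test_constant_effect_has_flat_trajectory(self):
        data, prof = _deviance_data(n_vessels=60, trips_per_vessel=5, seed=12, effects={"S_z": 0.2})
        dev = data[["vessel_id", "trip_id", "deltaP", "days_since_closure"]]
        table = growing_window(dev, prof)
        est = table.loc[table["term"] == "S_z"].sort_values("window_end_day")["estimate"].to_numpy()
        x = np.arange(len(est))
        slope, intercept = np.polyfit(x, est, 1)
        assert abs(slope) < 0.01  # no systematic drift across windows

    def test_sparse_window_flagged(self):
        data, prof = _deviance_data(n_vessels=10, trips_per_vessel=1, seed=13)
        dev = data[["vessel_id", "trip_id", "deltaP", "days_since_closure"]].copy()
        dev["days_since_closure"] = np.linspace(35, 50, len(dev))  # early windows empty
        table = growing_window(dev, prof)
        first = table.loc[table["window_end_day"] == 10.0]
        assert first["singular"].all() and first["estimate"].isna().all()
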