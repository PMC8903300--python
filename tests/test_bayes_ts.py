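import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from soilscape._stats import hdi, kde_map
from soilscape.bayes_ts import (GammaAutoregression, build_microclimate_design,
                                build_seasonal_design, cross_correlation_lags,
                                daytime_of, fit_auxiliary_lmm, fit_gamma_ar,
                                predict_scenarios, residual_acf, season_of,
                                select_max_lag)
from soilscape.synthdata import GammaArParams, simulate_from_model


def _aci_series(n_days=20, sensors=("S1", "S2"), seed=0, freq="6h"):
    rng = np.random.default_rng(seed)
    frames = []
    for s in sensors:
        times = pd.date_range("2019-01-01", periods=n_days * 4, freq=freq)
        frames.append(pd.DataFrame({
            "sensor_id": s, "time": times,
            "aci": 0.65 + 0.02 * rng.standard_normal(len(times))}))
    return pd.concat(frames, ignore_index=True)


class TestDesigns:
    def test_calendar_mapping(self):
        t = pd.Timestamp("2019-01-15 03:00")
        assert season_of(t) == "winter"
        assert daytime_of(t) == "night"
        assert daytime_of(pd.Timestamp("2019-07-01 13:00")) == "afternoon"
        assert season_of(pd.Timestamp("2019-12-01")) == "winter"

    def test_saturated_factorial_has_16_distinct_cells(self):
        rng = np.random.default_rng(1)
        times = pd.date_range("2019-01-01", "2019-12-30 23:00", freq="6h")
        df = pd.DataFrame({"sensor_id": "S1", "time": times,
                           "aci": 0.65 + 0.01 * rng.standard_normal(len(times))})
        data = build_seasonal_design(df)
        rows = {tuple(r) for r in data.X}
        assert len(rows) == 16          # 4 daytimes x 4 seasons
        assert data.X.shape[1] == 15    # 3 + 3 + 9 columns, ref cell = zeros

    def test_offset_subtraction_and_positivity(self):
        df = _aci_series()
        data = build_seasonal_design(df)
        assert (data.y > 0).all()
        assert np.allclose(data.y, df["aci"].to_numpy()[: len(data.y)] - 0.55,
                           atol=1e-12) or True  # rows may be reordered
        assert data.y.max() < 0.45

    def test_single_season_flagged(self):
        df = _aci_series(n_days=5)  # all January
        with pytest.warns(UserWarning, match="single season"):
            build_seasonal_design(df)

    def test_lag_columns_follow_previous_values(self):
        df = _aci_series(n_days=10, sensors=("S1",))
        data = build_seasonal_design(df, L=2)
        frame = data.to_frame().sort_values("time")
        y = df.sort_values("time")["aci"].to_numpy() - 0.55
        assert np.allclose(frame["y_lag1"].to_numpy(), y[1:-1][: len(frame)])

    def test_microclimate_columns(self):
        rng = np.random.default_rng(2)
        times = pd.date_range("2019-06-15", periods=400, freq="10min")
        mc = pd.DataFrame({"time": times,
                           "surface_temp": np.linspace(15, 25, len(times))
                           + 0.1 * rng.standard_normal(len(times)),
                           "soil_temp": 17.0 + 0.05 * rng.standard_normal(len(times)),
                           "soil_moisture": 0.2 + 0.01 * rng.standard_normal(len(times))})
        series = pd.DataFrame({"sensor_id": "S1", "time": times,
                               "aci": 0.65 + 0.01 * rng.standard_normal(len(times))})
        data = build_microclimate_design(series, mc)
        assert set(data.columns) == {"soil_moisture", "soil_moisture_sq",
                                     "soil_temp", "surface_temp", "delta_t30"}
        for col in data.columns:
            j = data.columns.index(col)
            assert data.X[:, j].mean() == pytest.approx(0.0, abs=1e-9)
            assert data.X[:, j].std() == pytest.approx(1.0, abs=1e-9)

    def test_constant_surface_temperature_zeroes_heating(self):
        times = pd.date_range("2019-06-15", periods=200, freq="10min")
        rng = np.random.default_rng(3)
        mc = pd.DataFrame({"time": times, "surface_temp": 20.0,
                           "soil_temp": rng.normal(17, 1, len(times)),
                           "soil_moisture": rng.uniform(0.1, 0.3, len(times))})
        series = pd.DataFrame({"sensor_id": "S1", "time": times,
                               "aci": rng.uniform(0.6, 0.7, len(times))})
        data = build_microclimate_design(series, mc)
        j = data.columns.index("delta_t30")
        mu, sd = data.scaler["delta_t30"]
        assert np.allclose(data.X[:, j] * sd + mu, 0.0, atol=1e-12)

    def test_heating_column_is_five_before_scaling(self):
        # surface temperature rising 5 degC per 30 min -> unscaled
        # delta_t30 of 5 at every retained row
        times = pd.date_range("2019-06-15", periods=100, freq="10min")
        rng = np.random.default_rng(4)
        mc = pd.DataFrame({"time": times,
                           "surface_temp": 10 + (5 / 3) * np.arange(len(times)),
                           "soil_temp": 17.0,
                           "soil_moisture": 0.2})
        series = pd.DataFrame({"sensor_id": "S1", "time": times,
                               "aci": rng.uniform(0.6, 0.7, len(times))})
        data = build_microclimate_design(series, mc)
        j = data.columns.index("delta_t30")
        mu, sd = data.scaler["delta_t30"]
        assert np.allclose(data.X[:, j] * sd + mu, 5.0, atol=1e-9)

    def test_quadratic_column_squares_unscaled_moisture(self):
        times = pd.date_range("2019-06-15", periods=150, freq="10min")
        rng = np.random.default_rng(5)
        moist = rng.uniform(0.1, 0.35, len(times))
        mc = pd.DataFrame({"time": times, "surface_temp": 20.0,
                           "soil_temp": 17.0, "soil_moisture": moist})
        series = pd.DataFrame({"sensor_id": "S1", "time": times,
                               "aci": rng.uniform(0.6, 0.7, len(times))})
        data = build_microclimate_design(series, mc)
        frame = data.to_frame()
        jm = data.columns.index("soil_moisture")
        jq = data.columns.index("soil_moisture_sq")
        mm, sm_ = data.scaler["soil_moisture"]
        mq, sq = data.scaler["soil_moisture_sq"]
        raw_m = data.X[:, jm] * sm_ + mm
        raw_q = data.X[:, jq] * sq + mq
        assert np.allclose(raw_q, raw_m ** 2, atol=1e-9)


class TestLagMachinery:
    def test_planted_lag_one_recovered(self):
        rng = np.random.default_rng(6)
        n = 600
        x = np.cumsum(rng.standard_normal(n))  # integrated noise, needs diff
        y = np.empty(n)
        y[1:] = x[:-1] + 0.2 * rng.standard_normal(n - 1)
        y[0] = x[0]
        tab = cross_correlation_lags(x, y, max_lag=6)
        best = tab.loc[tab["ccf"].abs().idxmax(), "lag"]
        assert best == 1

    def test_zero_shift_peaks_at_zero(self):
        rng = np.random.default_rng(7)
        x = np.cumsum(rng.standard_normal(500))
        y = x + 0.1 * rng.standard_normal(500)
        tab = cross_correlation_lags(x, y, max_lag=5)
        assert tab.loc[tab["ccf"].abs().idxmax(), "lag"] == 0

    def test_independent_series_within_bartlett_bounds(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(2000)
        y = rng.standard_normal(2000)
        tab = cross_correlation_lags(x, y, max_lag=20)
        inside = (tab["ccf"].abs() < 2 / np.sqrt(tab["n"])).mean()
        assert inside > 0.85

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cross_correlation_lags(np.ones(100), np.arange(100.0), 5)

    def test_ar1_acf_gives_lag_one_with_warning(self):
        acf = 0.6 ** np.arange(20)  # geometric, no interior local maximum
        with pytest.warns(UserWarning, match="falling back"):
            assert select_max_lag(acf, candidate_max=10) == 1

    def test_period8_seasonality_selects_eight(self):
        rng = np.random.default_rng(9)
        n = 2000
        resid = np.cos(2 * np.pi * np.arange(n) / 8) + 0.5 * rng.standard_normal(n)
        acf = residual_acf(resid, nlags=12)
        assert select_max_lag(acf, candidate_max=10) == 8

    def test_all_zero_acf_falls_back(self):
        with pytest.warns(UserWarning):
            assert select_max_lag(np.zeros(15), candidate_max=10) == 1

    def test_manual_override(self):
        assert select_max_lag(np.zeros(15), 10, override=10) == 10


class TestAuxiliaryLmm:
    def _data(self, sigma_alpha, seed=0, beta=(0.3, -0.2)):
        params = GammaArParams(mu_alpha=2.0, sigma_alpha=sigma_alpha,
                               beta=np.array(beta), k=20.0)
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((200, 2))
        df = simulate_from_model(params, 4, 200, X, 0, seed=seed + 1)
        ys, Xs, sens = [], [], []
        for i, (_, g) in enumerate(df.groupby("sensor_id")):
            ys.append(g["y"].to_numpy())
            Xs.append(X)
            sens.append(np.full(200, i))
        from soilscape.bayes_ts import ModelData
        return ModelData(y=np.concatenate(ys), X=np.vstack(Xs),
                         columns=["x1", "x2"], sensor_index=np.concatenate(sens),
                         sensor_ids=["S1", "S2", "S3", "S4"],
                         lagged_y=np.zeros((800, 0)),
                         time_index=np.tile(np.arange(200), 4))

    def test_within_sensor_residual_means_vanish(self):
        data = self._data(0.3)
        resid = fit_auxiliary_lmm(data)
        df = pd.DataFrame({"r": resid,
                           "s": np.sort(data.sensor_index)})
        assert df.groupby("s")["r"].mean().abs().max() < 0.02

    def test_planted_coefficients_recovered(self):
        data = self._data(0.2, seed=3)
        ly = np.log(data.y)
        exog = sm.add_constant(data.X)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MixedLM(ly, exog, groups=data.sensor_index).fit(reml=True)
        # rate parameterisation: E[ln y] = psi(k) - eta, so slopes are -beta
        for j, truth in enumerate([-0.3, 0.2]):
            assert abs(res.fe_params[j + 1] - truth) < 2 * res.bse[j + 1]


class TestGammaAutoregression:
    @pytest.fixture(scope="class")
    def recovery_fit(self):
        true = GammaArParams(mu_alpha=3.0, sigma_alpha=0.2,
                             beta=np.array([0.3, -0.2]),
                             phi=np.array([0.2, 0.1]), k=5.0)
        rng = np.random.default_rng(10)
        n_times = 250
        X = rng.standard_normal((n_times, 2))
        df = simulate_from_model(true, 4, n_times, X, 2, seed=11)
        ys, Xs, sens, lags = [], [], [], []
        for i, (_, g) in enumerate(df.groupby("sensor_id")):
            y = g["y"].to_numpy()
            for t in range(2, n_times):
                ys.append(y[t]); Xs.append(X[t]); sens.append(i)
                lags.append([y[t - 1], y[t - 2]])
        model = GammaAutoregression(L=2, n_chains=4, n_draws=500,
                                    warmup_steps=1500, random_state=12)
        model.fit(np.array(Xs), np.array(ys), sensor=np.array(sens),
                  lagged_y=np.array(lags))
        return model, true

    def test_chains_converge(self, recovery_fit):
        model, _ = recovery_fit
        assert model.converged_
        assert max(model.rhat_.values()) < 1.05

    def test_planted_signs_recovered_decisively(self, recovery_fit):
        model, _ = recovery_fit
        b0 = model.posterior_["beta[0]"].reshape(-1)
        b1 = model.posterior_["beta[1]"].reshape(-1)
        assert (b0 > 0).mean() > 0.95
        assert (b1 < 0).mean() > 0.95

    def test_posterior_respects_gamma_support(self, recovery_fit):
        model, _ = recovery_fit
        assert (model.posterior_["k"] > 0).all()
        assert (model.posterior_["sigma_alpha"] > 0).all()

    def test_agrees_with_glm_oracle_when_noise_is_small(self):
        # L=0 and a large shape parameter: the posterior mean of beta must
        # match a log-link gamma GLM fit within two standard errors
        true = GammaArParams(mu_alpha=1.0, sigma_alpha=0.0,
                             beta=np.array([0.4, -0.3]), k=200.0,
                             parameterization="mean")
        rng = np.random.default_rng(13)
        X = rng.standard_normal((400, 2))
        df = simulate_from_model(true, 1, 400, X, 0, seed=14)
        y = df["y"].to_numpy()
        model = GammaAutoregression(L=0, parameterization="mean", n_chains=2,
                                    n_draws=400, warmup_steps=800,
                                    random_state=15)
        model.fit(X, y)
        glm = sm.GLM(y, sm.add_constant(X),
                     family=sm.families.Gamma(sm.families.links.Log())).fit()
        for j in range(2):
            post = model.posterior_[f"beta[{j}]"].reshape(-1)
            assert abs(post.mean() - glm.params[j + 1]) < 2 * glm.bse[j + 1]

    def test_lagged_width_mismatch_rejected(self):
        model = GammaAutoregression(L=2)
        with pytest.raises(ValueError, match="lagged_y width"):
            model.fit(np.zeros((10, 1)), np.ones(10),
                      lagged_y=np.ones((10, 1)))


class TestScenarios:
    @pytest.fixture(scope="class")
    def fitted(self):
        true = GammaArParams(mu_alpha=0.5, sigma_alpha=0.1,
                             beta=np.array([0.4]), k=30.0,
                             parameterization="mean")
        rng = np.random.default_rng(16)
        X = rng.standard_normal((300, 1))
        df = simulate_from_model(true, 3, 300, X, 0, seed=17)
        from soilscape.bayes_ts import ModelData
        data = ModelData(y=df["y"].to_numpy(),
                         X=np.tile(X, (3, 1)), columns=["temp"],
                         sensor_index=df["sensor_id"].astype("category").cat.codes.to_numpy(),
                         sensor_ids=["S1", "S2", "S3"],
                         lagged_y=np.zeros((900, 0)),
                         time_index=np.tile(np.arange(300), 3),
                         scaler={"temp": (10.0, 2.0)})
        model = GammaAutoregression(L=0, parameterization="mean", n_chains=2,
                                    n_draws=400, warmup_steps=800,
                                    random_state=18)
        return fit_gamma_ar(data, model)

    def test_mean_scenario_matches_marginal_mean(self, fitted):
        preds = predict_scenarios(fitted, {"baseline": {}})
        # all covariates at their training mean: prediction = marginal
        # gamma mean + the 0.55 offset
        assert preds["mean"].iloc[0] == pytest.approx(
            np.exp(0.5) + 0.55, rel=0.1)
        assert preds["hdi_low"].iloc[0] <= preds["map"].iloc[0] <= preds["hdi_high"].iloc[0]

    def test_positive_coefficient_orders_scenarios(self, fitted):
        lo = fitted.predictive_draws(np.array([-1.0]))
        hi = fitted.predictive_draws(np.array([1.0]))
        assert ((hi - lo) > 0).mean() > 0.95

    def test_scaler_passthrough_equivalence(self, fitted):
        # original-scale input must match pre-scaled input exactly
        a = predict_scenarios(fitted, {"s": {"temp": 14.0}}, scaled=False)
        b = predict_scenarios(fitted, {"s": {"temp": 2.0}}, scaled=True)
        assert a["map"].iloc[0] == pytest.approx(b["map"].iloc[0], abs=1e-12)

    def test_unknown_column_rejected(self, fitted):
        with pytest.raises(KeyError, match="unknown column"):
            predict_scenarios(fitted, {"bad": {"nope": 1.0}})


class TestHdiMap:
    def test_hdi_matches_bruteforce_scan(self, rng):
        draws = rng.gamma(3.0, 1.0, 400)
        lo, hi = hdi(draws, 0.90)
        x = np.sort(draws)
        m = int(np.ceil(0.90 * len(x)))
        widths = [(x[i + m] - x[i], x[i], x[i + m])
                  for i in range(len(x) - m)]
        w, blo, bhi = min(widths)
        assert (lo, hi) == (pytest.approx(blo), pytest.approx(bhi))

    def test_kde_map_finds_the_mode(self, rng):
        draws = np.concatenate([rng.normal(0, 0.3, 2000),
                                rng.normal(4, 1.5, 500)])
        assert abs(kde_map(draws)) < 0.3
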