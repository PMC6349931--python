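"""Greenness anomaly forecasting, baselines and hindcast evaluation."""

import numpy as np
import pandas as pd
import pytest

from vegwater import (api_index, climatology_forecast, fit_forecast_model,
                      forecast_greenness, hindcast_evaluate,
                      persistence_forecast)
from vegwater.forecasting import (ForecastModel, forecast_anomaly,
                                  forecast_skill, monthly_api)


def _monthly(values, start="2010-01"):
    return pd.Series(values, index=pd.period_range(start, periods=len(values),
                                                   freq="M"))


class TestFitForecastModel:
    def test_exact_linear_recovery(self, rng):
        s = _monthly(rng.normal(0, 50, 48))
        dv = _monthly(np.zeros(48))
        lead = 2
        dv_arr = rng.normal(0, 0.05, 48)
        # construct dV_{t+2} = dV_t + 0.002 S_t + 0.01 exactly
        for t in range(48 - lead):
            dv_arr[t + lead] = dv_arr[t] + 0.002 * s.iloc[t] + 0.01
        dv = _monthly(dv_arr)
        m = fit_forecast_model(dv, s, lead)
        assert m.beta1 == pytest.approx(0.002, abs=1e-9)
        assert m.beta2 == pytest.approx(0.01, abs=1e-9)

    def test_constant_predictor_degenerates_to_persistence(self, rng):
        dv = _monthly(rng.normal(0, 0.05, 36))
        s = _monthly(np.zeros(36))
        with pytest.warns(UserWarning, match="persistence"):
            m = fit_forecast_model(dv, s, 1)
        assert m.degenerate
        assert m.beta1 == 0.0
        diffs = dv.to_numpy()[1:] - dv.to_numpy()[:-1]
        assert m.beta2 == pytest.approx(diffs.mean())

    def test_noisy_fit_matches_normal_equations(self, rng):
        s = _monthly(rng.normal(0, 30, 60))
        dv = _monthly(rng.normal(0, 0.08, 60))
        lead = 3
        m = fit_forecast_model(dv, s, lead)
        # independent closed-form normal-equations solve
        x = s.to_numpy()[:-lead]
        y = dv.to_numpy()[lead:] - dv.to_numpy()[:-lead]
        n = len(x)
        b1 = (n * (x * y).sum() - x.sum() * y.sum()) / \
            (n * (x * x).sum() - x.sum() ** 2)
        b2 = y.mean() - b1 * x.mean()
        assert m.beta1 == pytest.approx(b1, abs=1e-12)
        assert m.beta2 == pytest.approx(b2, abs=1e-12)

    def test_too_few_triplets_rejected(self, rng):
        s = _monthly(rng.normal(size=10))
        dv = _monthly(rng.normal(size=10))
        with pytest.raises(ValueError, match="12"):
            fit_forecast_model(dv, s, 1)


class TestForecastValues:
    def test_zero_coefficients_reduce_to_persistence_plus_climatology(self):
        m = ForecastModel(lead=1, beta1=0.0, beta2=0.0, n_train=24)
        clim = np.linspace(0.2, 0.4, 12)
        assert forecast_greenness(m, 0.05, 123.0, clim, 4) == pytest.approx(
            clim[3] + 0.05)
        assert forecast_greenness(m, 0.0, 0.0, clim, 7) == pytest.approx(clim[6])

    def test_forecast_round_trip_definition(self):
        m = ForecastModel(lead=2, beta1=0.001, beta2=-0.02, n_train=24)
        clim = np.full(12, 0.3)
        anom = forecast_anomaly(m, 0.04, 60.0)
        assert forecast_greenness(m, 0.04, 60.0, clim, 1) == pytest.approx(
            np.clip(anom + 0.3, 0, 1))

    def test_persistence_is_identity(self):
        for v in (0.05, 0.0, -0.12):
            assert persistence_forecast(v) == v


class TestClimatologyForecast:
    def test_single_occurrence_and_periodic(self):
        s = _monthly([0.1, 0.2, 0.3], start="2010-01")
        assert climatology_forecast(s, 2) == pytest.approx(0.2)
        per = _monthly(np.tile(np.linspace(0.1, 0.45, 12), 3))
        for m in range(1, 13):
            assert climatology_forecast(per, m) == pytest.approx(
                np.linspace(0.1, 0.45, 12)[m - 1])

    def test_random_equals_bucket_mean_and_exclusion(self, rng):
        s = _monthly(rng.uniform(0, 1, 50))
        for m in (1, 6, 12):
            bucket = [v for p, v in s.items() if p.month == m]
            assert climatology_forecast(s, m) == pytest.approx(
                np.mean(bucket))
        excl = [p for p in s.index if p.year == 2011]
        kept = [v for p, v in s.items() if p.month == 3 and p.year != 2011]
        assert climatology_forecast(s, 3, exclude=excl) == pytest.approx(
            np.mean(kept))
        with pytest.raises(ValueError, match="no history"):
            climatology_forecast(_monthly([0.1], start="2010-01"), 5)


class TestApiIndex:
    def test_geometric_decay_example(self):
        assert np.allclose(api_index([10.0, 0.0, 0.0], 0.9),
                           [10.0, 9.0, 8.1])
        assert np.allclose(api_index(np.zeros(5)), 0.0)

    def test_matches_brute_force_convolution(self, rng):
        p = rng.gamma(0.5, 8, 200)
        k = 0.9
        got = api_index(p, k)
        brute = np.array([sum(k ** i * p[t - i] for i in range(t + 1))
                          for t in range(len(p))])
        assert np.allclose(got, brute, atol=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="precipitation"):
            api_index([-1.0, 2.0])
        with pytest.raises(ValueError, match="decay"):
            api_index([1.0], decay=1.0)

    def test_monthly_sampling_takes_month_end(self, rng):
        idx = pd.date_range("2012-01-01", periods=90, freq="D")
        p = pd.Series(rng.gamma(0.5, 8, 90), index=idx)
        m = monthly_api(p, 0.9)
        daily = api_index(p.to_numpy(), 0.9)
        assert m[pd.Period("2012-01")] == pytest.approx(daily[30])
        assert m[pd.Period("2012-02")] == pytest.approx(daily[59])


class TestHindcast:
    def test_perfect_forecasts_score_one(self, rng):
        obs = rng.uniform(0.1, 0.6, 100)
        assert forecast_skill(obs, obs) == pytest.approx(1.0)

    def test_shuffled_forecasts_score_near_zero(self, rng):
        """Permutation null: forecasts carrying no information stay inside
        the sampling band around zero."""
        obs = _monthly(np.clip(0.3 + rng.normal(0, 0.05, 72), 0, 1))
        pred = _monthly(rng.permutation(obs.to_numpy()))
        res = hindcast_evaluate(obs, {"noise": pred}, leads=(1,))
        rho = res.skill.set_index("method").loc["noise", "rho"]
        assert abs(rho) < 0.3

    def test_storage_predictor_beats_baselines_when_it_drives_greenness(
            self, rng):
        """dV_{t+3} constructed from storage at t0: the Eq.1 storage
        forecast must outperform persistence and climatology."""
        n = 72
        s = np.zeros(n)
        phi = 0.9
        for t in range(1, n):
            s[t] = phi * s[t - 1] + rng.normal(0, 10)
        dv = np.zeros(n)
        dv[3:] = 0.004 * s[:-3] + rng.normal(0, 0.01, n - 3)
        months = pd.period_range("2010-01", periods=n, freq="M")
        clim = 0.3 + 0.08 * np.sin(2 * np.pi * (months.month - 3) / 12)
        obs = pd.Series(np.clip(clim + dv, 0, 1), index=months)
        res = hindcast_evaluate(obs, {"storage": _monthly(s)}, leads=(3,))
        sk = res.skill.set_index("method")["rho"]
        assert sk["storage"] > sk["persistence"]
        assert sk["storage"] > sk["climatology"]

    def test_unit_persistence_term_with_zero_beta1(self):
        m = ForecastModel(lead=1, beta1=0.0, beta2=0.005, n_train=24)
        dv0 = np.array([0.02, -0.04])
        out = forecast_anomaly(m, dv0, np.array([100.0, 200.0]))
        assert np.allclose(out, dv0 + 0.005)

    def test_held_out_mutation_does_not_change_fitted_models(self, rng):
        """The per-fold coefficients and training climatology must not
        depend on observations inside the held-out segment."""
        n = 72
        obs = _monthly(np.clip(0.3 + rng.normal(0, 0.05, n), 0, 1))
        pred = _monthly(rng.normal(0, 20, n))
        base = hindcast_evaluate(obs, {"s": pred}, leads=(2,),
                                 return_details=True)
        mutated = obs.copy()
        mutated.iloc[:24] = np.clip(mutated.iloc[:24] + 0.1, 0, 1)  # fold 0
        after = hindcast_evaluate(mutated, {"s": pred}, leads=(2,),
                                  return_details=True)
        m0 = base.details[(2, 0, "s")]
        m1 = after.details[(2, 0, "s")]
        assert m0.beta1 == pytest.approx(m1.beta1)
        assert m0.beta2 == pytest.approx(m1.beta2)
        assert np.allclose(base.details[(2, 0, "climatology")],
                           after.details[(2, 0, "climatology")])

    def test_segments_need_twelve_months(self, rng):
        short = _monthly(rng.uniform(0, 1, 30))
        with pytest.raises(ValueError, match="12"):
            hindcast_evaluate(short, {}, leads=(1,))
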