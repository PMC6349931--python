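"""Ensemble Kalman smoother machinery and the assimilation loop."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from vegwater import (AssimilationOptions, ColumnState, ObservationSet,
                      PerturbationParams, SyntheticConfig, assimilate_series,
                      assimilation_closure, enkf_update, generate_truth,
                      nudge_surface_water, observation_operator,
                      perturb_forcings, simulate_observations)
from vegwater.synthetic import surface_fraction_inverse

from conftest import make_forcing_frame


class TestPerturbForcings:
    def test_zero_sds_leave_forcings_unchanged(self):
        f = make_forcing_frame(10, precip=5.0)
        pert = perturb_forcings(f, 4, PerturbationParams(0.0, 0.0, 0.0), 1)
        for col in ("precip", "tair", "rad"):
            assert np.allclose(pert[col],
                               f[col].to_numpy()[:, None])

    def test_same_seed_identical_members(self):
        f = make_forcing_frame(10, precip=5.0)
        a = perturb_forcings(f, 8, PerturbationParams(), 42)
        b = perturb_forcings(f, 8, PerturbationParams(), 42)
        assert all(np.array_equal(a[k], b[k]) for k in a)

    def test_ensemble_mean_precip_unbiased(self):
        f = make_forcing_frame(3, precip=10.0)
        pert = perturb_forcings(f, 10_000, PerturbationParams(), 7)
        mean = pert["precip"].mean(axis=1)
        assert np.allclose(mean, 10.0, rtol=0.02)

    def test_member_count_validated(self):
        with pytest.raises(ValueError, match="2"):
            perturb_forcings(make_forcing_frame(3), 1,
                             PerturbationParams(), 0)


class TestObservationOperator:
    def test_constant_member_column_prediction(self):
        st = np.tile(np.array([10.0, 20.0, 30.0, 40.0, 20.0]), (30, 1))
        out = observation_operator(st, [], include_column=True)
        assert out == pytest.approx([120.0])

    def test_near_surface_is_a_selector(self):
        st = np.zeros((31, 5))
        st[:, 1] = np.arange(31.0)
        out = observation_operator(st, [3, 17], include_column=False)
        assert np.allclose(out, [3.0, 17.0])

    def test_ramp_column_equals_brute_force_mean(self):
        st = np.zeros((31, 5))
        st[:, 1] = np.linspace(0, 30, 31)
        out = observation_operator(st, [], include_column=True)
        brute = np.mean([st[d].sum() for d in range(31)])
        assert out == pytest.approx([brute])

    def test_out_of_window_observation_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            observation_operator(np.zeros((30, 5)), [30])


class TestEnkfUpdate:
    def test_scalar_posterior_mean_converges_to_kalman_value(self):
        rng = np.random.default_rng(0)
        n = 40_000
        prior = rng.normal(0.0, 1.0, size=(1, n))
        post = enkf_update(prior, prior.copy(), np.array([1.0]),
                           np.array([1.0]), rng)
        # x|y ~ N(0.5, 0.5) for unit prior and obs variances, y=1
        assert post.mean() == pytest.approx(0.5, abs=0.02)
        assert post.std() == pytest.approx(np.sqrt(0.5), abs=0.02)

    def test_infinite_obs_variance_recovers_prior(self):
        rng = np.random.default_rng(1)
        prior = rng.normal(size=(3, 500))
        post = enkf_update(prior, prior[:1], np.array([5.0]),
                           np.array([1e12]), rng)
        assert np.allclose(post, prior, atol=1e-3)

    def test_singular_innovation_covariance_raises(self):
        rng = np.random.default_rng(2)
        prior = rng.normal(size=(1, 50))
        dup = np.vstack([prior, prior])  # identical rows, negligible noise
        with pytest.raises(np.linalg.LinAlgError, match="ensemble size"):
            enkf_update(prior, dup, np.array([1.0, 1.0]),
                        np.array([1e-14, 1e-14]), rng)


class TestNudging:
    def test_gain_limits_and_convex_combination(self):
        state = ColumnState(surface_water=10.0)
        same = nudge_surface_water(state, 0.5, 0.0)
        assert same.surface_water == 10.0
        full = nudge_surface_water(state, 0.5, 1.0)
        assert full.surface_water == pytest.approx(
            float(surface_fraction_inverse(0.5, 20.0)))
        # inverse-mapped observation of 20 mm with gain 0.9
        frac = 1 - np.exp(-1.0)  # maps back to exactly 20 mm
        mixed = nudge_surface_water(state, frac, 0.9)
        assert mixed.surface_water == pytest.approx(19.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="fraction"):
            nudge_surface_water(ColumnState(), 1.5, 0.5)
        with pytest.raises(ValueError, match="gain"):
            nudge_surface_water(ColumnState(), 0.5, 1.5)


@pytest.fixture(scope="module")
def twin():
    cfg = SyntheticConfig(n_pixels=1, n_years=3, seed=21,
                          nearsurface_sd_range=(0.1, 0.1),
                          column_sd_range=(1.0, 1.0), fraction_sd=1e-6)
    truth = generate_truth(cfg, 0)
    obs = simulate_observations(truth.states, cfg, 0)
    return cfg, truth, obs


class TestAssimilateSeries:
    def test_empty_observations_equal_open_loop(self, twin):
        cfg, truth, _ = twin
        opts = AssimilationOptions(n_members=20)
        a = assimilate_series(truth.forcings, ObservationSet.empty(),
                              options=opts, seed=3)
        b = assimilate_series(truth.forcings, ObservationSet.empty(),
                              options=dataclasses.replace(opts, update=False),
                              seed=3)
        pd.testing.assert_frame_equal(a.analysis, b.analysis)
        assert len(a.increments) == 0

    def test_same_seed_identical_output(self, twin):
        cfg, truth, obs = twin
        opts = AssimilationOptions(n_members=15)
        a = assimilate_series(truth.forcings, obs, options=opts, seed=5)
        b = assimilate_series(truth.forcings, obs, options=opts, seed=5)
        pd.testing.assert_frame_equal(a.analysis, b.analysis)
        pd.testing.assert_frame_equal(a.increments, b.increments)

    def test_huge_obs_variance_approaches_open_loop(self, twin):
        cfg, truth, obs = twin
        inflated = ObservationSet(
            obs.near_surface.assign(error_sd=1e6),
            obs.column_total.assign(error_sd=1e6),
            obs.surface_fraction.assign(error_sd=1e6))
        opts = AssimilationOptions(n_members=20, nudge_gain=0.0)
        a = assimilate_series(truth.forcings, inflated, options=opts, seed=9)
        b = assimilate_series(truth.forcings, ObservationSet.empty(),
                              options=dataclasses.replace(opts, update=False),
                              seed=9)
        diff = (a.analysis - b.analysis).abs().max().max()
        assert diff < 1e-3

    def test_twin_experiment_posterior_beats_open_loop(self, twin):
        """When the assimilating model runs on a degraded forcing product,
        accurate observations of the truth pull every store closer to truth
        than the unconstrained ensemble does."""
        from vegwater.synthetic import model_forcings
        cfg, truth, obs = twin
        forc = model_forcings(truth.forcings, cfg, 0)
        opts = AssimilationOptions(n_members=40)
        da = assimilate_series(forc, obs, options=opts, seed=13)
        ol = assimilate_series(forc, ObservationSet.empty(),
                               options=dataclasses.replace(opts, update=False),
                               seed=13)
        for store in ("surface_water", "s_top", "s_shallow", "s_deep",
                      "groundwater"):
            e_da = ((da.analysis[store].iloc[1:] - truth.states[store]) ** 2
                    ).mean() ** 0.5
            e_ol = ((ol.analysis[store].iloc[1:] - truth.states[store]) ** 2
                    ).mean() ** 0.5
            assert e_da <= e_ol

    def test_closure_with_ledgered_increments(self, twin):
        cfg, truth, obs = twin
        da = assimilate_series(truth.forcings, obs,
                               options=AssimilationOptions(n_members=15),
                               seed=17)
        assert assimilation_closure(da) < 1e-6
        assert len(da.increments) > 0

    def test_posterior_respects_bounds(self, twin):
        cfg, truth, obs = twin
        from vegwater import ColumnParams
        p = ColumnParams()
        da = assimilate_series(truth.forcings, obs,
                               options=AssimilationOptions(n_members=15),
                               seed=19)
        arr = da.analysis.to_numpy()
        assert (arr >= -1e-9).all()
        caps = p.soil_caps
        assert (da.analysis[["s_top", "s_shallow", "s_deep"]].to_numpy()
                <= caps * (1 + 1e-9)).all()
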