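"""Residual extraction, likelihood, and latent-input estimation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize_scalar

from latentode import (
    ConfigurationError,
    HiddenSignal,
    InvalidWeightsError,
    NoiseModel,
    ObservationMap,
    TimeSeriesData,
    UndefinedError,
    aggregate_hidden,
    build_linear_network,
    estimate_latent,
    estimate_latent_partial,
    fit_penalized_spline,
    log_likelihood,
    prepare_context,
    residual_signal,
    score_s,
    sigma2_mle,
    simulate_linear_dataset,
    solve_ode,
)


class _FnFit:
    """Adapter making an analytic (f, f') pair look like a spline fit."""

    def __init__(self, f, df):
        self.f, self.df = f, df

    def __call__(self, t, order=0):
        return self.f(np.asarray(t, float)) if order == 0 \
            else self.df(np.asarray(t, float))


class TestResidualSignal:
    def test_pure_derivative_when_psi_vanishes(self):
        model = build_linear_network(np.zeros((1, 1)), [0.0])
        t = np.linspace(0, 1, 30)
        fit = fit_penalized_spline(t, t ** 2, k_dim=15, lam=0.0)
        resid = residual_signal(model, [fit], 0, t)
        interior = slice(3, -3)
        assert np.max(np.abs(resid[interior] - 2 * t[interior])) < 1e-2

    def test_exact_inputs_return_exact_signal(self, linear3_noisefree):
        # feed the true trajectories and derivatives: the extraction
        # identity returns a_i * h exactly
        fx = linear3_noisefree
        model, times = fx["model"], fx["times"]
        a, h = fx["a_true"], fx["h_true"]
        from scipy.interpolate import CubicSpline
        dense_t = np.linspace(times[0], times[-1], 600)
        dense = solve_ode(model, dense_t, a=a, h=h)
        fits = [_FnFit(CubicSpline(dense_t, dense[i]),
                       CubicSpline(dense_t, dense[i]).derivative())
                for i in range(3)]
        resid = residual_signal(model, fits, 0, times)
        assert np.max(np.abs(resid - a[0] * h.values)) < 5e-3

    def test_constant_data_zero_rates_zero_residual(self):
        model = build_linear_network(np.zeros((2, 2)), [3.0, 1.0])
        t = np.linspace(0, 1, 20)
        fits = [fit_penalized_spline(t, np.full(20, c), lam=1.0)
                for c in (3.0, 1.0)]
        resid = residual_signal(model, fits, 1, t)
        assert np.max(np.abs(resid)) < 1e-6

    def test_index_out_of_range(self):
        model = build_linear_network(np.zeros((2, 2)), [1.0, 1.0])
        with pytest.raises(IndexError):
            residual_signal(model, [None, None], 5, np.linspace(0, 1, 5))


class TestAggregateHidden:
    def test_single_support_passes_through(self):
        table = np.array([[1.0, 2.0, 3.0], [9.0, 9.0, 9.0], [0.0, 0.0, 0.0]])
        out = aggregate_hidden(table, np.array([1.0, 0.0, 0.0]),
                               times=[0, 1, 2])
        assert np.array_equal(out.values, table[0])

    def test_weighted_average_arithmetic(self):
        table = np.array([[2.0, 4.0], [-1.0, -2.0]])
        out = aggregate_hidden(table, np.array([0.5, -0.5]), times=[0.0, 1.0])
        assert np.allclose(out.values, [3.0, 6.0])

    def test_consistent_inputs_recover_common_signal(self):
        rng = np.random.default_rng(3)
        h = rng.normal(size=10)
        a = np.array([0.3, -0.5, 0.2])
        table = np.outer(a, h)
        out = aggregate_hidden(table, a, times=np.arange(10.0))
        assert np.allclose(out.values, h, atol=1e-12)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(InvalidWeightsError):
            aggregate_hidden(np.ones((2, 3)), np.zeros(2))


class TestLogLikelihood:
    def test_perfect_fit_closed_form(self):
        # 30 observations, sigma^2 = 1: logL = -15 log(2 pi)
        model = build_linear_network(np.zeros((3, 3)), [1.0, 2.0, 3.0])
        times = np.linspace(0, 5, 10)
        traj = solve_ode(model, times)
        data = TimeSeriesData(times=times, values=traj)
        noise = NoiseModel("normal", 1.0)
        ll = log_likelihood(model, data, None, noise, None)
        assert ll == pytest.approx(-15 * math.log(2 * math.pi), abs=1e-8)

    def test_matches_pointwise_gaussian_density_sum(self):
        rng = np.random.default_rng(8)
        model = build_linear_network(rng.uniform(0, 1, (2, 2)) *
                                     (1 - np.eye(2)), [1.0, 0.5])
        times = np.linspace(0, 3, 8)
        traj = solve_ode(model, times)
        data = TimeSeriesData(times=times,
                              values=traj + 0.3 * rng.standard_normal(traj.shape))
        sigma2 = 0.7
        ll = log_likelihood(model, data, None, NoiseModel("normal", sigma2),
                            None)
        from scipy.stats import norm
        brute = norm.logpdf(data.values, loc=traj,
                            scale=math.sqrt(sigma2)).sum()
        assert ll == pytest.approx(brute, abs=1e-10)

    def test_lognormal_nonpositive_fit_gives_minus_inf(self):
        model = build_linear_network(np.zeros((1, 1)), [1.0])
        times = np.linspace(0, 2, 5)
        h = HiddenSignal(times, np.full_like(times, -3.0))
        data = TimeSeriesData(times=times, values=np.full((1, 5), 0.5),
                              noise_kind=None)
        ll = log_likelihood(model, data, np.array([1.0]),
                            NoiseModel("lognormal", 0.01), h)
        assert ll == -np.inf

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000),
           st.floats(-4.0, 4.0).filter(lambda x: abs(x) > 0.05))
    def test_scale_invariance_of_weights_and_signal(self, seed, xi):
        """a_i h = (xi a_i)(h / xi): the likelihood cannot tell them apart."""
        rng = np.random.default_rng(seed)
        k = rng.uniform(0, 1, (3, 3))
        np.fill_diagonal(k, 0)
        model = build_linear_network(k, rng.uniform(0.5, 1.5, 3))
        times = np.linspace(0, 5, 12)
        a = rng.uniform(-1, 1, 3)
        h_grid = rng.normal(size=12)
        truth = solve_ode(model, times)
        data = TimeSeriesData(times=times,
                              values=truth + 0.2 * rng.standard_normal(truth.shape))
        noise = NoiseModel("normal", 0.5)
        ll1 = log_likelihood(model, data, a, noise, HiddenSignal(times, h_grid))
        ll2 = log_likelihood(model, data, xi * a, noise,
                             HiddenSignal(times, h_grid / xi))
        assert abs(ll1 - ll2) < 1e-8


class TestSigma2Mle:
    def test_perfect_fit_zero(self):
        y = np.ones((2, 5))
        assert sigma2_mle(y, y) == 0.0

    def test_direct_arithmetic(self):
        y = np.array([[1.0, -1.0, 2.0]])
        assert sigma2_mle(y, np.zeros((1, 3))) == pytest.approx(2.0)

    def test_matches_numeric_profile_maximum(self):
        """The analytic variance equals the 1-d likelihood maximiser."""
        rng = np.random.default_rng(21)
        for _ in range(20):
            obs = rng.uniform(0.5, 2.0, (3, 10))
            fit = obs * np.exp(0.3 * rng.standard_normal(obs.shape))
            s2_hat = sigma2_mle(obs, fit)
            res = minimize_scalar(
                lambda s2: -NoiseModel("normal", s2).log_density_sum(obs, fit),
                bounds=(1e-6, 10.0), method="bounded",
                options={"xatol": 1e-12})
            assert abs(s2_hat - res.x) < 1e-6

    def test_empty_observations_undefined(self):
        with pytest.raises(UndefinedError):
            sigma2_mle(np.empty((0, 3)), np.empty((0, 3)))


class TestEstimateLatent:
    def test_noise_free_recovery(self, linear3_noisefree):
        fx = linear3_noisefree
        est = estimate_latent(fx["model"], fx["data"], support=(0, 1),
                              noise_kind="normal", seed=0)
        assert np.max(np.abs(est.a - fx["a_true"])) < 0.05
        assert score_s(est.hidden, fx["h_true"]) < 0.05
        assert abs(np.sum(np.abs(est.a)) - 1.0) < 1e-10

    def test_null_model_fits_worse_than_true_support(self, linear3_noisefree):
        fx = linear3_noisefree
        ctx = prepare_context(fx["model"], fx["data"], "normal")
        null = estimate_latent(fx["model"], fx["data"], (), "normal",
                               context=ctx)
        supported = estimate_latent(fx["model"], fx["data"], (0, 1), "normal",
                                    context=ctx)
        assert null.loglik < supported.loglik
        assert null.n_a == 0 and np.all(null.a == 0)

    def test_estimate_is_l1_normalised_and_sign_oriented(self):
        data = simulate_linear_dataset(3, 1.0, 0.1, "lognormal", seed=12)
        model = build_linear_network(data.truth["k_matrix"],
                                     data.truth["x0"])
        est = estimate_latent(model, data, (0, 1, 2), "lognormal", seed=12)
        assert abs(np.sum(np.abs(est.a)) - 1.0) < 1e-10
        assert float(np.mean(est.hidden.values)) >= 0.0
        assert est.sigma2 > 0

    def test_lognormal_sigma_recovered(self):
        sig_hats = []
        for seed in range(10):
            data = simulate_linear_dataset(3, 1.0, 0.1, "lognormal",
                                           seed=seed)
            model = build_linear_network(data.truth["k_matrix"],
                                         data.truth["x0"])
            supp = tuple(np.flatnonzero(np.abs(data.truth["a_true"]) > 0.05))
            est = estimate_latent(model, data, supp, "lognormal", seed=seed)
            sig_hats.append(math.sqrt(est.sigma2))
        assert 0.07 <= np.mean(sig_hats) <= 0.13


class TestEstimateLatentPartial:
    def test_degenerate_full_observation_matches_plain_estimate(
            self, linear3_noisefree):
        fx = linear3_noisefree
        obs_map = ObservationMap(index=[0, 1, 2])
        full = estimate_latent(fx["model"], fx["data"], (0, 1), "normal",
                               seed=0)
        part = estimate_latent_partial(fx["model"], obs_map, fx["data"],
                                       (0, 1), "normal", seed=0)
        assert abs(full.loglik - part.loglik) < 1e-6
        assert np.allclose(full.a, part.a, atol=1e-4)

    def test_support_must_be_observed(self):
        data = simulate_linear_dataset(3, 2 / 3, 0.1, "lognormal", seed=1)
        model = build_linear_network(data.truth["k_matrix"],
                                     data.truth["x0"])
        obs_map = ObservationMap(index=data.observed_indices)
        from latentode import InvalidSupportError
        with pytest.raises(InvalidSupportError):
            estimate_latent_partial(model, obs_map, data, (2,), "lognormal")

    def test_no_hidden_influence_yields_null_and_calibrated_sigma(self):
        """2-component system, only the first observed, no latent input:
        selection keeps the null model and sigma is recovered."""
        from latentode import select_support
        sigma = 0.1
        rel_errs = []
        nulls = 0
        n_rep = 8
        for seed in range(n_rep):
            rng = np.random.default_rng(100 + seed)
            k = rng.uniform(0, 1, (2, 2))
            np.fill_diagonal(k, 0)
            model = build_linear_network(k, rng.uniform(0.5, 1.5, 2))
            times = np.linspace(0, 10, 30)
            truth = solve_ode(model, times)
            vals = truth * np.exp(sigma * rng.standard_normal(truth.shape))
            vals[1] = np.nan
            data = TimeSeriesData(times=times, values=vals,
                                  observed_mask=[True, False],
                                  noise_kind="lognormal")
            sel = select_support(model, data, strategy="forward",
                                 criterion="bic", noise_kind="lognormal",
                                 obs_map=ObservationMap(index=[0]), seed=seed)
            nulls += sel.chosen.n_a == 0
            rel_errs.append(math.sqrt(sel.chosen.sigma2) / sigma)
        assert nulls >= 0.75 * n_rep
        assert abs(np.mean(rel_errs) - 1.0) < 0.2

    def test_alternation_converges_on_partial_linear_network(self):
        data = simulate_linear_dataset(3, 2 / 3, 0.1, "lognormal", seed=7)
        model = build_linear_network(data.truth["k_matrix"],
                                     data.truth["x0"])
        obs_map = ObservationMap(index=data.observed_indices)
        est = estimate_latent_partial(model, obs_map, data, (0, 1),
                                      "lognormal", seed=7)
        assert est.converged
        assert np.all(est.a[~data.observed_mask] == 0)


class TestNoiseModel:
    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigurationError):
            NoiseModel("laplace", 1.0)

    def test_lognormal_density_includes_jacobian(self):
        obs = np.array([0.5, 2.0])
        fit = np.array([0.6, 1.8])
        s2 = 0.04
        got = NoiseModel("lognormal", s2).log_density_sum(obs, fit)
        from scipy.stats import norm
        want = (norm.logpdf(np.log(obs), np.log(fit), math.sqrt(s2)).sum()
                - np.log(obs).sum())
        assert got == pytest.approx(want, abs=1e-12)
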