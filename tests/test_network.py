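"""Network builders, latent forcing, and the ODE solvers."""

import numpy as np
import pytest

from latentode import (
    ConfigurationError,
    DomainError,
    HiddenSignal,
    InvalidModelError,
    ObservationMap,
    add_flow,
    build_cascade_model,
    build_jakstat_model,
    build_linear_network,
    solve_ode,
    transform_linear_network,
)
from latentode.network import LinearPropagator


def _epo(t):
    t = np.asarray(t, dtype=float)
    return (t / 5.0) * np.exp(1.0 - t / 5.0)


class TestHiddenSignal:
    def test_grid_points_return_stored_values(self):
        times = np.array([0.0, 1.0, 2.5, 4.0])
        vals = np.array([1.0, -2.0, 0.5, 3.0])
        for interp in ("linear", "cubic"):
            h = HiddenSignal(times, vals, interpolation=interp)
            assert np.array_equal(h(times), vals)

    def test_linear_interpolation_between_grid_points(self):
        h = HiddenSignal([0.0, 1.0], [0.0, 2.0])
        assert h(0.25) == pytest.approx(0.5)

    def test_outside_domain_raises(self):
        h = HiddenSignal([0.0, 1.0], [0.0, 2.0])
        with pytest.raises(DomainError):
            h(1.5)

    @pytest.mark.parametrize("times,values", [
        ([0.0, 0.0, 1.0], [1, 2, 3]),        # non-increasing
        ([0.0, 1.0], [1.0, np.inf]),          # non-finite
    ])
    def test_invalid_construction(self, times, values):
        with pytest.raises(InvalidModelError):
            HiddenSignal(times, values)


class TestLinearNetwork:
    def test_zero_rates_give_constant_solution(self):
        model = build_linear_network(np.zeros((3, 3)), [1.0, 2.0, 3.0])
        traj = solve_ode(model, np.linspace(0, 5, 11))
        assert np.allclose(traj, [[1.0], [2.0], [3.0]], atol=1e-9)

    def test_two_component_closed_form(self):
        # x2' = -x2, x1' = x2: x2 = e^-t, x1 = 1 - e^-t
        model = build_linear_network([[0.0, 1.0], [0.0, 0.0]], [0.0, 1.0])
        traj = solve_ode(model, np.array([0.0, 1.0]))
        assert traj[0, -1] == pytest.approx(1 - np.exp(-1), abs=1e-7)
        assert traj[1, -1] == pytest.approx(np.exp(-1), abs=1e-7)

    def test_mass_conserved_when_weights_sum_to_zero(self):
        rng = np.random.default_rng(0)
        k = rng.uniform(0, 1, (4, 4))
        np.fill_diagonal(k, 0)
        model = build_linear_network(k, rng.uniform(0.5, 1.5, 4))
        times = np.linspace(0, 10, 40)
        a = np.array([0.5, -0.2, -0.4, 0.1])  # sums to zero
        h = HiddenSignal(times, np.sin(times))
        traj = solve_ode(model, times, a=a, h=h)
        total = traj.sum(axis=0)
        assert np.max(np.abs(total - total[0])) < 1e-6

    @pytest.mark.parametrize("bad", [np.zeros((2, 3)),
                                     -np.ones((2, 2))])
    def test_invalid_matrix_rejected(self, bad):
        with pytest.raises(InvalidModelError):
            build_linear_network(bad, np.ones(bad.shape[0]))


class TestCascade:
    def test_zero_rates_constant(self):
        model = build_cascade_model([0.0, 0.0, 0.0],
                                    initial_values=[1.0, 0.0, 0.0, 0.0])
        traj = solve_ode(model, np.linspace(0, 5, 6))
        assert np.allclose(traj[0], 1.0) and np.allclose(traj[1:], 0.0)

    @pytest.mark.parametrize("feedback", [None, 0.3])
    def test_transport_chain_conserves_mass(self, feedback):
        model = build_cascade_model([0.4, 0.2, 0.5], feedback_rate=feedback,
                                    initial_values=[1.0, 0.5, 0.2, 0.1])
        traj = solve_ode(model, np.linspace(0, 10, 30))
        total = traj.sum(axis=0)
        assert np.max(np.abs(total - total[0])) < 1e-6

    def test_negative_rates_rejected(self):
        with pytest.raises(InvalidModelError):
            build_cascade_model([-0.1, 0.2, 0.3])

    def test_add_flow_matches_built_in_feedback(self):
        x0 = [1.0, 0.5, 0.2, 0.1]
        edited = add_flow(build_cascade_model([0.4, 0.2, 0.5],
                                              initial_values=x0),
                          source=3, target=0, value=0.3)
        direct = build_cascade_model([0.4, 0.2, 0.5], feedback_rate=0.3,
                                     initial_values=x0)
        times = np.linspace(0, 8, 20)
        assert np.allclose(solve_ode(edited, times), solve_ode(direct, times),
                           atol=1e-9)


class TestJakStat:
    RATES = {"k1": 0.05, "k2": 0.04, "k3": 0.03, "k4": 0.02,
             "k5": 1.2, "k6": 0.8, "k7": 1.0}

    def test_unknown_variant_rejected(self):
        with pytest.raises(ConfigurationError):
            build_jakstat_model("bogus", self.RATES, epor_a=_epo)

    def test_zero_input_freezes_the_system(self):
        model = build_jakstat_model("base", self.RATES, epor_a=lambda t: 0.0,
                                    initial_x1=1.5)
        traj = solve_ode(model, np.linspace(0, 30, 16))
        assert np.allclose(traj, traj[:, :1], atol=1e-10)

    @pytest.mark.parametrize("variant", ["base", "delay"])
    def test_weighted_stat5_total_conserved(self, variant):
        model = build_jakstat_model(variant, self.RATES, tau=6.0,
                                    epor_a=_epo, initial_x1=1.5)
        traj = solve_ode(model, np.linspace(0, 60, 40))
        weighted = traj[0] + traj[1] + 2 * traj[2] + 2 * traj[3]
        assert np.max(np.abs(weighted - weighted[0])) < 1e-6

    def test_observed_coordinates_match_transformed_delay_model(self):
        times = np.linspace(0, 60, 40)
        delay = build_jakstat_model("delay", self.RATES, tau=6.0,
                                    epor_a=_epo, initial_x1=1.5)
        obs_model, obs_map = build_jakstat_model(
            "delay_observed", self.RATES, tau=6.0, epor_a=_epo,
            initial_x1=1.5)
        tr_d = solve_ode(delay, times)
        tr_o = solve_ode(obs_model, times)
        k5, k6 = self.RATES["k5"], self.RATES["k6"]
        assert np.allclose(tr_o[0], k5 * (tr_d[1] + 2 * tr_d[2]), atol=1e-6)
        assert np.allclose(tr_o[1],
                           k6 * (tr_d[0] + tr_d[1] + 2 * tr_d[2]), atol=1e-6)
        assert obs_map.n_observed == 2

    def test_unknown_initial_value_flagged(self):
        model = build_jakstat_model("base", self.RATES, epor_a=_epo)
        assert model.unknown_x0_mask[0]
        with pytest.raises(ConfigurationError):
            solve_ode(model, np.linspace(0, 10, 5))


class TestSolveOde:
    def test_zero_signal_equals_no_signal(self):
        model = build_cascade_model([0.4, 0.2, 0.5],
                                    initial_values=[1.0, 0.5, 0.2, 0.1])
        times = np.linspace(0, 5, 12)
        h0 = HiddenSignal(times, np.zeros_like(times))
        plain = solve_ode(model, times)
        forced = solve_ode(model, times, a=np.ones(4), h=h0)
        assert np.allclose(plain, forced, atol=1e-10)

    def test_constant_input_integrates_linearly(self):
        model = build_linear_network(np.zeros((1, 1)), [2.0])
        times = np.linspace(0, 3, 7)
        h = HiddenSignal(times, np.full_like(times, 0.7))
        traj = solve_ode(model, times, a=np.array([1.0]), h=h)
        assert np.allclose(traj[0], 2.0 + 0.7 * times, atol=1e-8)

    def test_relaxation_toward_forced_equilibrium(self):
        # x' = -x + 1, x(0)=0 -> x(t) = 1 - e^-t
        model = build_linear_network([[0.0, 1.0], [0.0, 0.0]], [0.0, 0.0])
        times = np.linspace(0, 1, 5)
        h = HiddenSignal(times, np.ones_like(times))
        traj = solve_ode(model, times, a=np.array([0.0, 1.0]), h=h)
        assert traj[1, -1] == pytest.approx(1 - np.exp(-1), abs=1e-7)

    def test_rk4_is_fourth_order(self):
        model = build_linear_network([[0.0, 1.0], [0.0, 0.0]], [0.0, 1.0])
        times = np.array([0.0, 1.0])
        errs = {}
        for sub in (4, 8):
            traj = solve_ode(model, times, method="rk4", rk4_substeps=sub)
            errs[sub] = abs(traj[1, -1] - np.exp(-1))
        assert errs[4] / errs[8] >= 8.0

    def test_times_outside_signal_domain_rejected(self):
        model = build_linear_network(np.zeros((1, 1)), [1.0])
        h = HiddenSignal([0.0, 1.0], [0.0, 1.0])
        with pytest.raises(DomainError):
            solve_ode(model, np.linspace(0, 2, 5), a=np.array([1.0]), h=h)


class TestLinearPropagator:
    def test_matches_adaptive_solver_on_forced_system(self):
        rng = np.random.default_rng(1)
        n = 4
        a_mat = 0.3 * rng.normal(size=(n, n))
        times = np.linspace(0, 5, 31)
        h_grid = rng.normal(size=31)
        a = rng.normal(size=n)
        x0 = rng.uniform(0.5, 1.5, n)
        drift = rng.normal(size=n)
        prop = LinearPropagator(a_mat, times[1] - times[0], drift=drift)
        fast = prop.propagate(x0, a, h_grid)

        from scipy.integrate import solve_ivp
        h = HiddenSignal(times, h_grid)
        ref = solve_ivp(lambda t, x: a_mat @ x + a * h(t) + drift,
                        (0, 5), x0, t_eval=times, rtol=1e-11, atol=1e-13)
        assert np.max(np.abs(fast - ref.y)) < 1e-7


class TestTransformLinearNetwork:
    def test_affine_transformed_dynamics(self):
        rng = np.random.default_rng(3)
        k = rng.uniform(0, 1, (3, 3))
        np.fill_diagonal(k, 0)
        model = build_linear_network(k, [1.0, 0.8, 1.2])
        obs = ObservationMap(index=[0, 1], scale=[2.0, 0.5],
                             offset=[0.3, -0.1])
        transformed = transform_linear_network(model, obs)
        times = np.linspace(0, 5, 20)
        tr = solve_ode(model, times)
        ref = np.vstack([2.0 * tr[0] + 0.3, 0.5 * tr[1] - 0.1, tr[2]])
        assert np.max(np.abs(solve_ode(transformed, times) - ref)) < 1e-6

    def test_zero_scale_rejected(self):
        with pytest.raises(InvalidModelError):
            ObservationMap(index=[0], scale=[0.0])
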