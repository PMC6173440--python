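"""Delayed Kuramoto integration and order-parameter diagnostics."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from netfluct.connectome import StructuralConnectome
from netfluct.errors import InvalidInputError
from netfluct.oscillator import (KuramotoConfig, OrderParameterSeries,
                                 PhaseTrajectory, build_delays,
                                 integrate_kuramoto, order_parameter)

TWO_PI = 2 * np.pi


def _two_node_sc(weight=1.0, length=10.0):
    w = np.array([[0.0, weight], [weight, 0.0]])
    l = np.where(w > 0, length, 0.0)
    return StructuralConnectome(weights=w, lengths=l)


class TestBuildDelays:
    def test_mean_length_edge_gets_mean_delay(self, modular_connectome):
        cfg = KuramotoConfig(coupling=1.0, duration_s=25.0, mean_delay_ms=12.0)
        dm = build_delays(modular_connectome, cfg)
        lbar = modular_connectome.mean_fiber_length
        edge = modular_connectome.weights > 0
        # delays proportional to lengths; an edge of exactly mean length
        # would get exactly the mean delay
        np.testing.assert_allclose(
            dm.delays_ms[edge],
            12.0 * modular_connectome.lengths[edge] / lbar)

    def test_conduction_velocity_from_mean_delay(self):
        # a connectome whose mean fiber length matches the group value
        sc = _two_node_sc(length=84.5)
        cfg = KuramotoConfig(coupling=1.0, duration_s=25.0, mean_delay_ms=12.0)
        dm = build_delays(sc, cfg)
        assert dm.conduction_velocity_m_s == pytest.approx(84.5 / 12.0)
        assert round(dm.conduction_velocity_m_s, 1) == 7.0

    def test_doubling_lengths_doubles_delays_at_fixed_velocity(self):
        sc1 = _two_node_sc(length=40.0)
        sc2 = _two_node_sc(length=80.0)
        cfg = KuramotoConfig(coupling=1.0, duration_s=25.0,
                             conduction_velocity_m_s=5.0)
        d1 = build_delays(sc1, cfg).delays_ms[0, 1]
        d2 = build_delays(sc2, cfg).delays_ms[0, 1]
        assert d2 == pytest.approx(2 * d1)

    def test_delay_steps_floor_one(self):
        sc = _two_node_sc(length=0.01)
        cfg = KuramotoConfig(coupling=1.0, duration_s=25.0,
                             conduction_velocity_m_s=100.0, dt_ms=1.0)
        dm = build_delays(sc, cfg)
        assert dm.delay_steps[0, 1] == 1

    def test_exactly_one_delay_spec_required(self):
        with pytest.raises(InvalidInputError):
            KuramotoConfig(coupling=1.0, duration_s=25.0).validate()
        with pytest.raises(InvalidInputError):
            KuramotoConfig(coupling=1.0, duration_s=25.0, mean_delay_ms=5.0,
                           conduction_velocity_m_s=5.0).validate()


class TestIntegration:
    def test_uncoupled_closed_form(self):
        # k = 0: theta(t) = theta0 + 2*pi*f*t exactly (constant derivative
        # is integrated exactly by Heun)
        sc = _two_node_sc()
        cfg = KuramotoConfig(coupling=0.0, duration_s=20.5, mean_delay_ms=5.0,
                             transient_discard_s=20.0, dt_ms=0.5, seed=3)
        traj = integrate_kuramoto(sc, cfg)
        rng = np.random.default_rng(3)
        theta0 = rng.uniform(0, TWO_PI, 2)
        # the uncoupled history run advances the ramp by max-delay steps
        # (5 ms delay at dt = 0.5 ms -> 10 steps) before coupled time 0
        t = 0.005 + 20.0 + np.arange(traj.phases.shape[1]) * 0.5e-3
        expected = np.mod(theta0[:, None] + TWO_PI * 60.0 * t[None, :], TWO_PI)
        diff = np.mod(traj.phases - expected + np.pi, TWO_PI) - np.pi
        assert np.max(np.abs(diff)) < 1e-7

    def test_two_node_zero_delay_phase_locking_matches_reference_ode(self):
        # two nodes, negligible delay, no noise: the phase difference
        # Delta obeys dDelta/dt = -2 k C sin(Delta); compare against a
        # dense independent integration of that 1-D ODE
        k, c = 2.0, 1.0
        sc = _two_node_sc(weight=c, length=1e-4)
        cfg = KuramotoConfig(coupling=k, duration_s=22.0,
                             conduction_velocity_m_s=100.0,
                             transient_discard_s=20.0, dt_ms=0.1, seed=5)
        traj = integrate_kuramoto(sc, cfg)
        delta = np.mod(traj.phases[0] - traj.phases[1] + np.pi, TWO_PI) - np.pi

        rng = np.random.default_rng(5)
        theta0 = rng.uniform(0, TWO_PI, 2)
        d0 = np.mod(theta0[0] - theta0[1] + np.pi, TWO_PI) - np.pi
        sol = solve_ivp(lambda t, y: -2 * k * c * np.sin(y), (0, 22.0), [d0],
                        t_eval=20.0 + np.arange(len(delta)) * 1e-4,
                        rtol=1e-10, atol=1e-12)
        assert np.max(np.abs(delta - sol.y[0])) < 1e-3
        # and the difference has essentially locked by then
        assert np.abs(delta[-1]) < 1e-2

    def test_deterministic_with_noise_seed(self, modular_connectome):
        cfg = KuramotoConfig(coupling=10.0, duration_s=21.0, mean_delay_ms=8.0,
                             noise_sd_rad_s=1.25, dt_ms=1.0, seed=42)
        a = integrate_kuramoto(modular_connectome, cfg)
        b = integrate_kuramoto(modular_connectome, cfg)
        assert np.array_equal(a.phases, b.phases)

    def test_phases_wrapped_and_finite(self, modular_connectome):
        cfg = KuramotoConfig(coupling=30.0, duration_s=21.0, mean_delay_ms=5.0,
                             noise_sd_rad_s=1.25, dt_ms=1.0, seed=1)
        traj = integrate_kuramoto(modular_connectome, cfg)
        assert np.isfinite(traj.phases).all()
        assert (traj.phases >= 0).all() and (traj.phases < TWO_PI).all()

    def test_expected_sample_count(self, modular_connectome):
        cfg = KuramotoConfig(coupling=5.0, duration_s=22.0, mean_delay_ms=5.0,
                             dt_ms=1.0, seed=0)
        traj = integrate_kuramoto(modular_connectome, cfg)
        assert traj.phases.shape == (40, 2000)     # (22 - 20) s / 1 ms

    def test_coupling_raises_synchrony_on_complete_graph(self):
        # classical (near-zero-delay) Kuramoto sanity check
        n = 10
        w = np.ones((n, n)) - np.eye(n)
        sc = StructuralConnectome(weights=w, lengths=np.where(w > 0, 1e-3, 0))
        syncs = []
        for k in (0.0, 5.0):
            cfg = KuramotoConfig(coupling=k, duration_s=22.0,
                                 conduction_velocity_m_s=100.0,
                                 dt_ms=0.5, seed=9)
            traj = integrate_kuramoto(sc, cfg)
            syncs.append(order_parameter(traj).synchrony)
        assert syncs[1] >= syncs[0]


class TestOrderParameter:
    def test_identical_phases_give_unity(self):
        traj = PhaseTrajectory(phases=np.full((7, 50), 1.3),
                               sample_rate_hz=1000.0, start_time_s=0.0)
        res = order_parameter(traj)
        assert np.allclose(res.magnitude, 1.0)
        assert res.metastability == pytest.approx(0.0)

    def test_equally_spaced_phases_cancel(self):
        n = 8
        phases = np.tile((TWO_PI * np.arange(n) / n)[:, None], (1, 10))
        res = order_parameter(PhaseTrajectory(phases=phases,
                                              sample_rate_hz=1000.0,
                                              start_time_s=0.0))
        assert np.all(res.magnitude < 1e-12)

    def test_uniform_random_phases_scale(self, rng):
        # i.i.d. uniform phases: R ~ N^{-1/2}; at N = 1000, R < 0.1
        # in the overwhelming majority of draws
        hits = 0
        for _ in range(200):
            phases = rng.uniform(0, TWO_PI, (1000, 1))
            r = order_parameter(PhaseTrajectory(
                phases=phases, sample_rate_hz=1.0, start_time_s=0.0))
            hits += r.synchrony < 0.1
        assert hits >= 198

    def test_summary_statistics(self):
        phases = np.zeros((2, 4))
        phases[1] = [0.0, np.pi, 0.0, np.pi]
        res = order_parameter(PhaseTrajectory(phases=phases,
                                              sample_rate_hz=1.0,
                                              start_time_s=0.0))
        assert np.allclose(res.magnitude, [1, 0, 1, 0], atol=1e-12)
        assert res.synchrony == pytest.approx(0.5)
        assert res.metastability == pytest.approx(0.5)
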