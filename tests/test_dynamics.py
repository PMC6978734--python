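import numpy as np
import pytest

from hebbseq.dynamics import (
    NetworkConfig,
    NetworkState,
    RunawayError,
    build_rf_matrix,
    simulate,
    step_excitatory,
    step_full_inhibition,
    step_reduced_inhibition,
)
from hebbseq.transfer import PiecewiseLinearTF


class TestBuildRfMatrix:
    def test_explicit_small_cases(self):
        np.testing.assert_array_equal(
            build_rf_matrix(3, 2.0, 1.0), [[2, 0, 0], [1, 2, 0], [0, 1, 2]]
        )
        np.testing.assert_array_equal(build_rf_matrix(2, 0.0, 1.0), [[0, 0], [1, 0]])

    def test_no_feedforward_is_scaled_identity(self):
        np.testing.assert_array_equal(build_rf_matrix(4, 0.7, 0.0), 0.7 * np.eye(4))

    def test_rejects_single_population(self):
        with pytest.raises(ValueError):
            build_rf_matrix(1, 1.0, 1.0)


class TestConfigValidation:
    def test_lumped_inhibition_from_split(self):
        cfg = NetworkConfig(n=10, w_EI=0.5, w_IE=0.4)
        assert cfg.w_I == pytest.approx(10 * 0.5 * 0.4)

    def test_inconsistent_inhibition_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            NetworkConfig(n=10, w_I=1.0, w_EI=0.5, w_IE=0.4)

    def test_basic_invariants(self):
        with pytest.raises(ValueError):
            NetworkConfig(n=1)
        with pytest.raises(ValueError):
            NetworkConfig(n=5, tau=0.0)
        with pytest.raises(ValueError):
            NetworkConfig(n=5, w=-1.0)


class TestEulerSteps:
    def test_exponential_decay_without_input(self, pl_tf):
        # I = 0, W = 0: u(t) = exp(-t/tau)
        tau, dt = 10.0, 0.1
        state = NetworkState(u=np.array([1.0, 0.0]))
        W = np.zeros((2, 2))
        for _ in range(1000):
            state = step_excitatory(state, np.zeros(2), dt, pl_tf, W, tau=tau)
        assert state.u[0] == pytest.approx(np.exp(-10.0), rel=0.1)  # forward-Euler bias ~ dt/(2 tau) per tau

    def test_relaxation_to_constant_input(self, pl_tf):
        state = NetworkState(u=np.zeros(2))
        I = np.array([0.0, 2.5])
        W = np.zeros((2, 2))
        for _ in range(2000):
            state = step_excitatory(state, I, 0.1, pl_tf, W, tau=10.0)
        np.testing.assert_allclose(state.u, I, atol=1e-6)

    def test_single_population_supersaturated_fixed_point(self, pl_tf):
        # w = 1.5 with saturated rate 1: u* = w * phi(u*) = 1.5
        state = NetworkState(u=np.array([1.0, 0.0]))
        W = build_rf_matrix(2, 1.5, 0.0)
        for _ in range(5000):
            state = step_excitatory(state, np.zeros(2), 0.1, pl_tf, W, tau=10.0)
        assert state.u[0] == pytest.approx(1.5, abs=1e-6)

    def test_full_inhibition_decouples_at_zero_wIE(self, pl_tf):
        cfg = NetworkConfig(
            n=3, w=0.5, s=0.6, w_EI=1.0, w_IE=0.0, variant="full_inhibition"
        )
        s_exc = NetworkState(u=np.array([1.0, 0.2, 0.0]))
        s_full = NetworkState(u=np.array([1.0, 0.2, 0.0]), u_I=0.0)
        W = build_rf_matrix(3, cfg.w, cfg.s)
        for _ in range(300):
            s_exc = step_excitatory(s_exc, np.zeros(3), 0.1, pl_tf, W, tau=cfg.tau)
            s_full = step_full_inhibition(s_full, np.zeros(3), 0.1, pl_tf, cfg)
        np.testing.assert_allclose(s_full.u, s_exc.u, atol=1e-12)

    def test_inhibitory_current_decays_when_rates_zero(self, pl_tf):
        cfg = NetworkConfig(n=2, tau_I=2.0, variant="full_inhibition", w_I=1.0)
        state = NetworkState(u=np.array([-1.0, -1.0]), u_I=1.0)
        dt, steps = 0.1, 40
        for _ in range(steps):
            state = step_full_inhibition(state, np.full(2, -1.0), dt, pl_tf, cfg)
        assert state.u_I == pytest.approx(np.exp(-steps * dt / cfg.tau_I), rel=1e-1)

    def test_reduced_inhibition_zero_is_fixed_point(self, pl_tf):
        cfg = NetworkConfig(n=4, w=0.8, s=0.5, w_I=2.0)
        state = NetworkState(u=np.zeros(4))
        for _ in range(100):
            state = step_reduced_inhibition(state, np.zeros(4), 0.1, pl_tf, cfg)
        np.testing.assert_array_equal(state.u, 0.0)

    def test_reduced_symmetric_initial_state_stays_symmetric(self, pl_tf):
        # with s=0 the reduced model is permutation symmetric
        cfg = NetworkConfig(n=5, w=0.9, s=0.0, w_I=1.5)
        state = NetworkState(u=np.full(5, 0.6))
        for _ in range(500):
            state = step_reduced_inhibition(state, np.zeros(5), 0.1, pl_tf, cfg)
        assert np.ptp(state.u) == 0.0

    def test_dt_must_resolve_tau(self, pl_tf):
        state = NetworkState(u=np.zeros(2))
        with pytest.raises(ValueError, match="dt"):
            step_excitatory(state, np.zeros(2), 5.0, pl_tf, np.zeros((2, 2)), tau=10.0)


class TestSimulate:
    def test_zero_input_zero_state(self, pl_tf):
        cfg = NetworkConfig(n=3, w=0.5, s=0.5)
        traj = simulate(cfg, pl_tf, None, None, np.zeros(3), 50.0, dt=0.1)
        assert np.all(traj.currents == 0.0)
        assert np.all(traj.rates == 0.0)
        assert np.all(np.diff(traj.times) > 0)

    def test_rates_are_phi_of_currents(self, pl_tf):
        cfg = NetworkConfig(n=3, w=0.6, s=0.8, variant="excitatory")
        u0 = np.array([1.0, 0.0, 0.0])
        traj = simulate(cfg, pl_tf, None, None, u0, 100.0, dt=0.1)
        np.testing.assert_allclose(traj.rates, pl_tf(traj.currents))

    def test_sequential_transient_activation(self, pl_tf):
        # w < 1/nu < w+s: successive populations transiently activated
        cfg = NetworkConfig(n=6, w=0.5, s=1.0, variant="excitatory")
        u0 = np.zeros(6)
        u0[0] = 1.0
        traj = simulate(cfg, pl_tf, None, None, u0, 600.0, dt=0.1, stride=5)
        above = traj.rates > 0.5
        first_cross = traj.times[above.argmax(axis=0)]
        assert np.all(np.diff(first_cross) > 0)
        assert traj.rates[:, -1].max() > 0.5
        assert np.all(traj.rates[-1] < 0.5)  # transient: activity has passed

    def test_linear_network_amplitude_grows_along_sequence(self):
        # without saturation the sequence amplitude increases with position
        tf_lin = PiecewiseLinearTF(nu=1.0, theta=0.0, u_c=1e9)
        cfg = NetworkConfig(n=8, w=0.5, s=1.0, variant="excitatory")
        u0 = np.zeros(8)
        u0[0] = 1.0
        traj = simulate(cfg, tf_lin, None, None, u0, 800.0, dt=0.1, stride=5)
        peaks = traj.rates.max(axis=0)
        assert np.all(np.diff(peaks[1:]) > 0)

    def test_first_order_dt_convergence(self, pl_tf):
        cfg = NetworkConfig(n=4, w=0.6, s=0.9, w_I=1.0)
        u0 = np.zeros(4)
        u0[0] = 1.0

        def run(dt):
            return simulate(cfg, pl_tf, None, None, u0, 100.0, dt=dt, stride=int(1 / dt))

        e1 = np.abs(run(0.2).currents - run(0.05).currents).max()
        e2 = np.abs(run(0.1).currents - run(0.05).currents).max()
        assert e2 < e1  # error shrinks with dt
        assert e1 / e2 == pytest.approx(3.0, abs=1.2)  # ~first order: (0.2-0.05)/(0.1-0.05)

    def test_permutation_symmetry(self, pl_tf):
        # consistent relabeling of W, u0 relabels the trajectory
        rng = np.random.default_rng(0)
        n = 5
        W = rng.uniform(0, 0.8, (n, n))
        u0 = rng.uniform(0, 1, n)
        perm = rng.permutation(n)
        cfg = NetworkConfig(n=n, w_I=1.0)
        t1 = simulate(cfg, pl_tf, W, None, u0, 50.0, dt=0.1)
        t2 = simulate(cfg, pl_tf, W[np.ix_(perm, perm)], None, u0[perm], 50.0, dt=0.1)
        np.testing.assert_allclose(t2.currents, t1.currents[:, perm], atol=1e-12)

    def test_bounded_trajectories_with_saturating_tf(self, pl_tf):
        cfg = NetworkConfig(n=5, w=2.5, s=2.0, variant="excitatory")
        u0 = np.full(5, 1.0)
        traj = simulate(cfg, pl_tf, None, None, u0, 500.0, dt=0.1)
        bound = 0.0 + (cfg.w + cfg.s) * pl_tf.max_rate + 1e-9
        assert np.abs(traj.currents).max() <= bound

    def test_runaway_reports_blowup_time(self):
        tf_lin = PiecewiseLinearTF(nu=1.0, theta=0.0, u_c=1e12)
        cfg = NetworkConfig(n=2, w=3.0, s=0.0, variant="excitatory")
        with pytest.raises(RunawayError) as exc:
            simulate(cfg, tf_lin, None, None, np.array([1.0, 0.0]), 2000.0, dt=0.1)
        assert exc.value.t > 0
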