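import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hebbseq.dynamics import NetworkConfig, NetworkState, step_reduced_inhibition
from hebbseq.plasticity import (
    HebbianParams,
    HomeostaticParams,
    NoiseConfig,
    PlasticState,
    coupled_step,
    effective_weights,
    f_post,
    g_pre,
    hebbian_step,
    homeostatic_step,
    normalize_step,
    tau_w,
)
from hebbseq.transfer import PiecewiseLinearTF

P = HebbianParams(T_w=100.0)


class TestSigmoidDrives:
    def test_midpoint_and_limits(self):
        assert f_post(P.b_post, P) == pytest.approx(0.5)
        assert g_pre(P.b_pre, P) == pytest.approx(0.5)
        assert f_post(100.0, P) == pytest.approx(1.0)
        assert f_post(-100.0, P) == pytest.approx(0.0, abs=1e-12)

    @given(x=st.floats(-2, 2))
    def test_antisymmetry_about_midpoint(self, x):
        assert f_post(P.b_post + x, P) + f_post(P.b_post - x, P) == pytest.approx(1.0)
        assert g_pre(P.b_pre + x, P) + g_pre(P.b_pre - x, P) == pytest.approx(1.0)


class TestActivityDependentTimescale:
    def test_frozen_only_when_both_below_threshold(self):
        assert np.isinf(tau_w(0.0, 0.0, P))
        assert tau_w(P.r_w, 0.0, P) == P.T_w
        assert tau_w(0.0, P.r_w, P) == P.T_w
        assert tau_w(2 * P.r_w, 2 * P.r_w, P) == P.T_w


class TestHebbianStep:
    def run_constant(self, rates, steps, dt=0.5, params=P, normalize=False, W0=None):
        n = len(rates)
        st_ = PlasticState(n, dt, params.D, W0=W0, r0=np.asarray(rates, float))
        for _ in range(steps):
            hebbian_step(st_, np.asarray(rates, float), dt, params, normalize=normalize)
        return st_

    def test_converges_to_separable_target(self):
        # constant suprathreshold rates: W -> w_max f(r_i) g(r_j), rank 1
        rates = np.array([0.9, 0.7, 0.8])
        st_ = self.run_constant(rates, steps=5000)
        target = P.w_max * np.outer(f_post(rates, P), g_pre(rates, P))
        np.testing.assert_allclose(st_.W, target, atol=1e-3)
        sv = np.linalg.svd(st_.W, compute_uv=False)
        assert sv[1] / sv[0] < 1e-3  # separable (rank-1) structure

    def test_frozen_below_threshold(self):
        rates = np.array([0.3, 0.2])  # both below r_w = 0.4
        W0 = np.array([[0.5, 0.2], [0.1, 0.7]])
        st_ = self.run_constant(rates, steps=200, W0=W0.copy())
        np.testing.assert_array_equal(st_.W, W0)

    def test_ltp_and_ltd_directions(self):
        # relative to W = 0.5 w_max: target below => depression, above => potentiation
        W0 = np.full((2, 2), 0.5 * P.w_max)
        low = np.array([0.5, 0.5])      # f*g = 0.25 < 0.5 -> LTD
        high = np.array([0.8, 0.8])     # f*g ~ 0.99 > 0.5 -> LTP
        assert self.run_constant(low, 50, W0=W0.copy()).W[0, 0] < 0.5 * P.w_max
        assert self.run_constant(high, 50, W0=W0.copy()).W[0, 0] > 0.5 * P.w_max

    @given(
        w0=st.floats(0.0, 3.0),
        r1=st.floats(0.0, 1.0),
        r2=st.floats(0.0, 1.0),
    )
    def test_weights_stay_in_bounds(self, w0, r1, r2):
        # relaxation toward a target in [0, w_max] keeps W in [0, w_max]
        st_ = self.run_constant(np.array([r1, r2]), steps=300, W0=np.full((2, 2), w0))
        assert np.all(st_.W >= -1e-12)
        assert np.all(st_.W <= P.w_max + 1e-12)


class TestDelayBuffer:
    def test_delayed_reads_past_rates(self):
        st_ = PlasticState(2, dt=0.5, D=2.0)
        for k in range(10):
            st_.push(np.array([float(k), 0.0]))
        assert st_.delayed(2.0)[0] == pytest.approx(9 - 4)
        assert st_.delayed(0.0)[0] == pytest.approx(9)

    def test_linear_interpolation_for_fractional_delay(self):
        st_ = PlasticState(1, dt=1.0, D=3.0)
        for k in range(5):
            st_.push(np.array([float(k)]))
        assert st_.delayed(1.5)[0] == pytest.approx(2.5)

    def test_prestimulus_history_filled_with_initial_rates(self):
        st_ = PlasticState(2, dt=0.5, D=5.0, r0=np.array([0.7, 0.1]))
        np.testing.assert_allclose(st_.delayed(5.0), [0.7, 0.1])


class TestNormalization:
    def test_mean_subtraction_examples(self):
        upd = np.array([[0.2, 0.0], [0.0, 0.0]])
        out = normalize_step(upd)
        np.testing.assert_allclose(out[0], [0.1, -0.1])
        np.testing.assert_allclose(normalize_step(np.full((3, 3), 0.7)), 0.0, atol=1e-15)

    @given(
        seed=st.integers(0, 100),
    )
    def test_row_sums_conserved(self, seed):
        rng = np.random.default_rng(seed)
        W = rng.uniform(0, 1, (5, 5))
        upd = rng.normal(0, 0.1, (5, 5))
        before = W.sum(axis=1)
        after = (W + normalize_step(upd)).sum(axis=1)
        np.testing.assert_allclose(after, before, atol=1e-12)

    def test_rejects_non_square(self):
        with pytest.raises(ValueError):
            normalize_step(np.zeros((2, 3)))


class TestHomeostaticStep:
    def iterate(self, r, H0, steps=60000, dt=0.5, params=HomeostaticParams(tau_H=1000.0, r_0=0.2)):
        H = np.array([H0])
        rr = np.array([r])
        for _ in range(steps):
            H = homeostatic_step(H, rr, dt, params)
        return H[0]

    def test_fixed_points(self):
        # H* = 1 - r/r_0 (clipped at 0): roots of (1 - r/r0) H - H^2
        assert self.iterate(0.0, 0.5) == pytest.approx(1.0, abs=1e-3)
        assert self.iterate(0.1, 0.5) == pytest.approx(0.5, abs=1e-3)
        assert self.iterate(0.4, 0.5) == pytest.approx(0.0, abs=1e-2)

    @given(H0=st.floats(0.0, 1.0), r=st.floats(0.0, 2.0))
    def test_H_stays_in_unit_interval(self, H0, r):
        params = HomeostaticParams(tau_H=500.0, r_0=0.2)
        H = np.array([H0])
        for _ in range(200):
            H = homeostatic_step(H, np.array([r]), 0.5, params)
            assert 0.0 <= H[0] <= 1.0 + 1e-9


class TestEffectiveWeights:
    def test_row_scaling(self):
        st_ = PlasticState(2, 0.5, 0.0, W0=np.full((2, 2), 2.0))
        st_.H = np.array([0.5, 1.0])
        W = effective_weights(st_)
        np.testing.assert_allclose(W, [[1.0, 1.0], [2.0, 2.0]])

    def test_unmasked_and_fully_masked(self):
        W0 = np.array([[1.0, 2.0], [3.0, 4.0]])
        st_ = PlasticState(2, 0.5, 0.0, W0=W0)
        np.testing.assert_array_equal(effective_weights(st_), W0)
        st_.H = np.zeros(2)
        np.testing.assert_array_equal(effective_weights(st_), 0.0)


class TestCoupledStep:
    def test_degenerates_to_reduced_inhibition(self, pl_tf):
        # sigma=0, H=1, plasticity off: identical to the fixed-connectivity model
        n = 4
        cfg = NetworkConfig(n=n, w_I=1.0)
        W = np.array([[0.5, 0.1, 0.0, 0.0]] * n)
        net = NetworkState(u=np.array([1.0, 0.3, 0.0, 0.1]))
        ref = NetworkState(u=net.u.copy())
        plastic = PlasticState(n, 0.5, 0.0, W0=W.copy())
        I = np.zeros(n)
        for _ in range(200):
            net, plastic = coupled_step(net, plastic, I, 0.5, cfg, pl_tf, hebbian=None)
            ref = step_reduced_inhibition(ref, I, 0.5, pl_tf, cfg, W=W)
        np.testing.assert_allclose(net.u, ref.u, atol=1e-12)
        np.testing.assert_array_equal(plastic.W, W)

    def test_zero_delay_uses_simultaneous_rates(self, pl_tf):
        n = 2
        params = HebbianParams(D=0.0, T_w=100.0)
        cfg = NetworkConfig(n=n, w_I=0.0)
        net = NetworkState(u=np.array([2.0, 2.0]))
        plastic = PlasticState(n, 0.5, 0.0)
        I = np.full(n, 2.0)
        for _ in range(2000):
            net, plastic = coupled_step(net, plastic, I, 0.5, cfg, pl_tf, params)
        # rates pinned at 1 => instantaneous Hebb target w_max f(1) g(1)
        target = params.w_max * f_post(1.0, params) * g_pre(1.0, params)
        np.testing.assert_allclose(plastic.W, target, atol=1e-2)

    def test_same_seed_bitwise_identical(self, pl_tf):
        n = 3
        cfg = NetworkConfig(n=n, w_I=1.0)
        params = HebbianParams(T_w=200.0)
        homeo = HomeostaticParams(tau_H=1000.0, r_0=0.1)

        def run(seed):
            rng = np.random.default_rng(seed)
            net = NetworkState(u=np.zeros(n))
            plastic = PlasticState(n, 0.5, params.D)
            for k in range(500):
                I = np.array([2.0 if (k // 100) % 2 == 0 else 0.0, 0.0, 0.0])
                net, plastic = coupled_step(
                    net, plastic, I, 0.5, cfg, pl_tf, params,
                    homeostatic=homeo, sigma=0.3, rng=rng,
                )
            return net.u.copy(), plastic.W.copy(), plastic.H.copy()

        u1, W1, H1 = run(7)
        u2, W2, H2 = run(7)
        assert np.array_equal(u1, u2) and np.array_equal(W1, W2) and np.array_equal(H1, H2)

    def test_noise_requires_rng(self, pl_tf):
        cfg = NetworkConfig(n=2)
        with pytest.raises(ValueError, match="rng"):
            coupled_step(
                NetworkState(u=np.zeros(2)), PlasticState(2, 0.5, 0.0),
                np.zeros(2), 0.5, cfg, pl_tf, None, sigma=0.1,
            )


def test_noise_config_validation():
    with pytest.raises(ValueError):
        NoiseConfig(sigma=-0.1)
    assert NoiseConfig(sigma=0.3, seed=1).sigma == 0.3


def test_homeostatic_separation_warning():
    with pytest.warns(UserWarning, match="scale separation"):
        HomeostaticParams(tau_H=100.0, r_0=0.1).check_separation(T_w=500.0)
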