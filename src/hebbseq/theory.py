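"""Reduced one-presentation learning map and its fixed points.

During training with homeostasis the learned excitatory weights are
masked (H small), so the net recurrent current is weak and each
population's response to its stimulus is well approximated by the
*decoupled* dynamics: an exponential rise of the current toward the
stimulus amplitude during stimulation and an exponential decay back to
baseline afterwards.  Integrating the Hebbian rule along these decoupled
rate trajectories for a single presentation of the sequence yields a map

    (w_k, s_k)  ->  (w_{k+1}, s_{k+1})

on the mean recurrent and feedforward weights as a function of the
stimulus parameters (T, Delta, I_amp) and the plasticity parameters.
The fixed point of the map is the learned connectivity, and its position
in the (s, w) bifurcation diagram predicts the retrieved regime.

The map assumes total masking during stimulation (no recurrent
feedback), which is its stated regime of validity; it is evaluated by
trapezoid-free explicit quadrature at a fine step along the closed-form
rate trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dynamics import NetworkConfig
from .phases import Regime, analytic_label
from .plasticity import HebbianParams, f_post, g_pre
from .transfer import PiecewiseLinearTF, TransferFunction

__all__ = [
    "MapConfig",
    "decoupled_rate",
    "presentation_map",
    "map_fixed_point",
    "predict_regime",
]


@dataclass(frozen=True)
class MapConfig:
    """Stimulus timing, plasticity parameters and quadrature settings of
    the reduced learning map."""

    T: float
    Delta: float
    I_amp: float
    hebbian: HebbianParams
    tau: float = 10.0
    quad_step: float = 0.05
    tf: TransferFunction = PiecewiseLinearTF()
    u_bg: float = 0.0
    w_I: float = 0.0
    n: int = 10

    def __post_init__(self) -> None:
        if self.T <= 0 or self.Delta < 0 or self.I_amp <= 0:
            raise ValueError("timings and amplitude must be positive")
        if self.quad_step <= 0 or self.quad_step > 0.1:
            raise ValueError("quadrature step must be in (0, 0.1] ms")


def decoupled_rate(t, phase: str, I_amp: float, tau: float = 10.0,
                   tf: TransferFunction = PiecewiseLinearTF(),
                   u_end: float | None = None):
    """Closed-form decoupled response of a stimulated population.

    ``phase='stimulated'``: ``u(t) = I_amp (1 - exp(-t/tau))`` with ``t``
    measured from stimulus onset.  ``phase='relaxing'``:
    ``u(t) = u_end exp(-t/tau)`` with ``t`` from stimulus offset and
    ``u_end`` the current at offset.  Returns the rate ``phi(u)``.
    """
    t = np.asarray(t, dtype=float)
    if phase == "stimulated":
        u = I_amp * (1.0 - np.exp(-t / tau))
    elif phase == "relaxing":
        if u_end is None:
            raise ValueError("relaxing phase needs the current at offset")
        u = u_end * np.exp(-t / tau)
    else:
        raise ValueError(f"unknown phase {phase!r}")
    return tf(u)


def _pulse_rate(t: np.ndarray, onset: float, cfg: MapConfig) -> np.ndarray:
    """Rate of a population stimulated during [onset, onset + T),
    resting at the background current before onset.

    Without inhibition this is the closed-form exponential rise/decay;
    with the (unmasked) global inhibition ``w_I`` the population's own
    rate feeds back subtractively with weight ``w_I / n``, and the
    trajectory is integrated with RK4 at the quadrature step.
    """
    t = np.asarray(t, dtype=float)
    tl = t - onset
    if cfg.w_I == 0.0:
        rise = cfg.I_amp * (1.0 - np.exp(-np.clip(tl, 0.0, None) / cfg.tau))
        u_end = cfg.I_amp * (1.0 - math.exp(-cfg.T / cfg.tau))
        decay = u_end * np.exp(-np.clip(tl - cfg.T, 0.0, None) / cfg.tau)
        u = cfg.u_bg + np.where(tl < 0.0, 0.0, np.where(tl < cfg.T, rise, decay))
        return cfg.tf(u)
    g = cfg.w_I / cfg.n
    h = cfg.quad_step
    m = int(math.ceil((float(tl.max()) if tl.size else 0.0) / h)) + 1
    grid_u = np.empty(max(m, 1))
    u = cfg.u_bg
    tf = cfg.tf
    if isinstance(tf, PiecewiseLinearTF):
        nu, th, hi = tf.nu, tf.theta, tf.max_rate

        def phi(x: float) -> float:
            return min(max(nu * (x - th), 0.0), hi)

    else:

        def phi(x: float) -> float:
            return float(tf(x))

    tau = cfg.tau
    tt = 0.0
    for i in range(m):
        grid_u[i] = u
        drive0 = cfg.u_bg + (cfg.I_amp if 0.0 <= tt < cfg.T else 0.0)
        drive1 = cfg.u_bg + (cfg.I_amp if 0.0 <= tt + h < cfg.T else 0.0)
        k1 = (drive0 - u - g * phi(u)) / tau
        x = u + 0.5 * h * k1
        k2 = (drive0 - x - g * phi(x)) / tau
        x = u + 0.5 * h * k2
        k3 = (drive0 - x - g * phi(x)) / tau
        x = u + h * k3
        k4 = (drive1 - x - g * phi(x)) / tau
        u += (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        tt += h
    idx = np.clip((tl / h).astype(int), 0, m - 1)
    uu = np.where(tl < 0.0, cfg.u_bg, grid_u[idx])
    return cfg.tf(uu)


def _integrate_pair(
    W0: float, post_onset: float, pre_onset: float, cfg: MapConfig
) -> float:
    """Integrate the Hebbian ODE for one (post, pre) population pair over
    one presentation, along the decoupled rate trajectories.

    The pre-synaptic rate enters delayed by D.  Outside the window where
    either rate exceeds r_w the weight is frozen, so the integration
    range [0, end] with end covering both pulses plus their decay tails
    is exhaustive.
    """
    A, B = _pair_affine(post_onset, pre_onset, cfg)
    return A * W0 + B


def _pair_affine(
    post_onset: float, pre_onset: float, cfg: MapConfig
) -> tuple[float, float]:
    """Affine coefficients of one presentation for a (post, pre) pair:
    ``W_{k+1} = A W_k + B``.

    The Hebbian ODE relaxes W toward a time-dependent target at rate
    1/T_w whenever plasticity is on, so a presentation acts affinely:
    ``A`` is the accumulated decay factor over the plastic time and
    ``B`` the decay-weighted quadrature of the target.
    """
    p = cfg.hebbian
    end = max(post_onset, pre_onset + p.D) + cfg.T + 10.0 * cfg.tau
    t = np.arange(0.0, end, cfg.quad_step)
    r_post = _pulse_rate(t, post_onset, cfg)
    r_pre_delayed = _pulse_rate(t - p.D, pre_onset, cfg)
    plastic = (r_post >= p.r_w) | (r_pre_delayed >= p.r_w)
    target = p.w_max * f_post(r_post, p) * g_pre(r_pre_delayed, p)
    lam = cfg.quad_step / p.T_w
    factors = np.where(plastic, 1.0 - lam, 1.0)
    # suffix products: weight of each step's contribution at presentation end
    suffix = np.ones_like(factors)
    suffix[:-1] = np.cumprod(factors[::-1])[-2::-1]
    A = float(np.prod(factors))
    B = float(np.sum(np.where(plastic, lam * target, 0.0) * suffix))
    return A, B


def presentation_map(
    w_k: float, s_k: float, map_cfg: MapConfig
) -> tuple[float, float]:
    """One-presentation update of the mean recurrent and feedforward
    weights.

    The recurrent weight of population ``i`` pairs its own rate with its
    own delayed rate (onsets coincide); the feedforward weight from
    ``i`` to ``i+1`` pairs the successor's rate (onset ``T + Delta``
    later) with population ``i``'s delayed rate.
    """
    if not (0.0 <= w_k <= map_cfg.hebbian.w_max and 0.0 <= s_k <= map_cfg.hebbian.w_max):
        raise ValueError("weights must lie in [0, w_max]")
    w_next = _integrate_pair(w_k, 0.0, 0.0, map_cfg)
    s_next = _integrate_pair(s_k, map_cfg.T + map_cfg.Delta, 0.0, map_cfg)
    return w_next, s_next


def map_fixed_point(
    map_cfg: MapConfig,
    tol: float = 1.0e-6,
    max_iter: int = 5000,
) -> tuple[float, float, int]:
    """Iterate the presentation map from (0, 0) to its fixed point.

    Returns ``(w_inf, s_inf, iterations)``.  The map is affine in each
    weight (exponential relaxation toward a stimulus-determined target),
    so iteration converges geometrically; exceeding ``max_iter`` raises.
    """
    w, s = 0.0, 0.0
    for it in range(1, max_iter + 1):
        w_next, s_next = presentation_map(w, s, map_cfg)
        if abs(w_next - w) < tol and abs(s_next - s) < tol:
            return w_next, s_next, it
        w, s = w_next, s_next
    raise RuntimeError(f"fixed-point iteration did not converge in {max_iter} steps")


def predict_regime(
    map_cfg: MapConfig,
    net_cfg: NetworkConfig,
    alpha: float = 0.5,
) -> tuple[Regime, float, float]:
    """Learned regime predicted by the reduced map.

    Locates the map's fixed point in the analytic (s, w) bifurcation
    diagram of the piecewise linear network and returns
    ``(label, w_inf, s_inf)``.
    """
    w_inf, s_inf, _ = map_fixed_point(map_cfg)
    label = analytic_label(
        s_inf, w_inf, net_cfg.w_I, net_cfg.n, alpha=alpha
    )
    return label, w_inf, s_inf
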