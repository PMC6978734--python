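"""Temporally asymmetric Hebbian plasticity and its stabilization rules.

The excitatory-to-excitatory weight matrix (the *fast* Hebbian variable
``W_fast``) relaxes toward a separable target set by the post-synaptic
rate and the *delayed* pre-synaptic rate:

    dW_ij/dt = (w_max f[r_i(t)] g[r_j(t - D)] - W_ij) / tau_w

with sigmoidal drives ``f`` (post) and ``g`` (pre) and an
activity-dependent time constant: ``tau_w`` is infinite (weights frozen)
when both rates are below the plasticity threshold ``r_w``, and equals
``T_w`` otherwise.  The delay ``D`` makes the rule order-selective:
stimulus timing relative to ``D`` decides whether recurrent weights,
feedforward weights, both, or neither grow.

Two stabilization mechanisms are provided:

* synaptic normalization — after each Hebbian update the row mean of the
  update is subtracted, conserving each population's total incoming
  weight exactly;
* generalized homeostatic plasticity — a slow multiplicative scaling
  ``H_i`` of all incoming excitatory weights, with dynamics
  ``tau_H dH_i/dt = (1 - r_i/r_0) H_i - H_i^2``.  The quadratic term
  makes the post-stimulation steady state O(1) (*unmasking* the learned
  weights) instead of pinning the rate at the set point.

``coupled_step`` advances the noisy current dynamics (Euler–Maruyama)
together with all enabled plasticity rules; inhibition is fixed and is
not scaled by ``H``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .dynamics import OVERFLOW_GUARD, NetworkConfig, NetworkState, RunawayError
from .transfer import TransferFunction

__all__ = [
    "HebbianParams",
    "HomeostaticParams",
    "NoiseConfig",
    "PlasticState",
    "f_post",
    "g_pre",
    "tau_w",
    "hebbian_step",
    "normalize_step",
    "homeostatic_step",
    "effective_weights",
    "coupled_step",
]


@dataclass(frozen=True)
class HebbianParams:
    """Parameters of the temporally asymmetric Hebbian rule.

    Rates are in units of the maximum firing rate (1 with the default
    normalized transfer functions); times in ms.  ``T_w`` should be much
    slower than the population time constant tau.
    """

    w_max: float = 3.0
    D: float = 12.0
    T_w: float = 2000.0
    r_w: float = 0.4
    a_pre: float = 10.0
    b_pre: float = 0.5
    a_post: float = 10.0
    b_post: float = 0.5

    def __post_init__(self) -> None:
        if self.w_max <= 0:
            raise ValueError("w_max must be positive")
        if self.D < 0:
            raise ValueError("plasticity delay D must be non-negative")
        if self.T_w <= 0:
            raise ValueError("plasticity time constant T_w must be positive")
        if self.r_w < 0:
            raise ValueError("plasticity threshold r_w must be non-negative")


@dataclass(frozen=True)
class HomeostaticParams:
    """Parameters of the generalized homeostatic rule: time constant
    ``tau_H`` (ms) and target-like background rate ``r_0 = phi(u_0)``."""

    tau_H: float = 20000.0
    r_0: float = 0.08

    def __post_init__(self) -> None:
        if self.tau_H <= 0:
            raise ValueError("tau_H must be positive")
        if self.r_0 <= 0:
            raise ValueError("background rate r_0 must be positive")

    def check_separation(self, T_w: float) -> None:
        if self.tau_H < 2.0 * T_w:
            warnings.warn(
                f"homeostatic time constant tau_H={self.tau_H} is not much "
                f"slower than the Hebbian T_w={T_w}; scale separation is "
                "assumed by the masking mechanism",
                stacklevel=2,
            )


@dataclass(frozen=True)
class NoiseConfig:
    """Current-noise amplitude and seed for the stochastic dynamics."""

    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("noise amplitude sigma must be non-negative")


def g_pre(r, params: HebbianParams):
    """Pre-synaptic drive: ``(1 + tanh(a_pre (r - b_pre))) / 2`` in [0, 1]."""
    return 0.5 * (1.0 + np.tanh(params.a_pre * (np.asarray(r, float) - params.b_pre)))


def f_post(r, params: HebbianParams):
    """Post-synaptic drive: ``(1 + tanh(a_post (r - b_post))) / 2`` in [0, 1]."""
    return 0.5 * (1.0 + np.tanh(params.a_post * (np.asarray(r, float) - params.b_post)))


def tau_w(r_post, r_pre_delayed, params: HebbianParams):
    """Activity-dependent plasticity time constant.

    Infinite (no plasticity) when both the post rate and the delayed pre
    rate are below ``r_w``; ``T_w`` otherwise.  Vectorized: broadcasting
    post against pre gives the pairwise matrix.
    """
    frozen = (np.asarray(r_post, float) < params.r_w) & (
        np.asarray(r_pre_delayed, float) < params.r_w
    )
    return np.where(frozen, np.inf, params.T_w)


def plastic_mask(r_post, r_pre_delayed, params: HebbianParams) -> np.ndarray:
    """Pairwise boolean matrix: True where plasticity is ongoing
    (post rate i or delayed pre rate j above ``r_w``)."""
    post = np.asarray(r_post, float)[:, None] >= params.r_w
    pre = np.asarray(r_pre_delayed, float)[None, :] >= params.r_w
    return post | pre


class PlasticState:
    """Fast Hebbian matrix, homeostatic vector, and delayed-rate buffer.

    The ring buffer stores past rate vectors at resolution ``dt``; the
    delayed rate ``r(t - D)`` is read with linear interpolation for
    non-integer ``D/dt``.  Before any pushes the buffer is filled with
    the initial rates.
    """

    def __init__(
        self,
        n: int,
        dt: float,
        D: float,
        W0: np.ndarray | None = None,
        H0: np.ndarray | None = None,
        r0: np.ndarray | None = None,
    ):
        self.n = n
        self.dt = dt
        self.W = np.zeros((n, n)) if W0 is None else np.array(W0, dtype=float)
        if self.W.shape != (n, n):
            raise ValueError(f"W0 must be ({n}, {n})")
        self.H = np.ones(n) if H0 is None else np.array(H0, dtype=float)
        if self.H.shape != (n,):
            raise ValueError(f"H0 must be ({n},)")
        depth = int(math.ceil(D / dt)) + 2
        init = np.zeros(n) if r0 is None else np.asarray(r0, float)
        self._buf = np.tile(init, (depth, 1))
        self._depth = depth
        self._ptr = 0  # slot holding the most recent rates

    def push(self, rates: np.ndarray) -> None:
        self._ptr = (self._ptr + 1) % self._depth
        self._buf[self._ptr] = rates

    def delayed(self, D: float) -> np.ndarray:
        """Rates a time ``D`` before the most recent push."""
        x = D / self.dt
        k = int(math.floor(x))
        frac = x - k
        if k >= self._depth - 1:
            raise ValueError(f"delay {D} exceeds buffer depth")
        a = self._buf[(self._ptr - k) % self._depth]
        if frac == 0.0:
            return a
        b = self._buf[(self._ptr - k - 1) % self._depth]
        return (1.0 - frac) * a + frac * b


def hebbian_step(
    state: PlasticState,
    rates_now: np.ndarray,
    dt: float,
    params: HebbianParams,
    normalize: bool = False,
) -> PlasticState:
    """Advance the fast Hebbian matrix by one Euler step.

    Pairs whose post and delayed-pre rates are both below ``r_w`` are
    frozen.  With ``normalize`` the row mean of the raw update is
    subtracted (synaptic normalization), conserving row sums exactly.
    The rate history is advanced with ``rates_now``.
    """
    r_pre_delayed = state.delayed(params.D)
    mask = plastic_mask(rates_now, r_pre_delayed, params)
    target = params.w_max * np.outer(
        f_post(rates_now, params), g_pre(r_pre_delayed, params)
    )
    dW = np.where(mask, (dt / params.T_w) * (target - state.W), 0.0)
    if normalize:
        dW = normalize_step(dW)
    state.W += dW
    state.push(np.asarray(rates_now, float))
    return state


def normalize_step(raw_updates: np.ndarray) -> np.ndarray:
    """Synaptic normalization: subtract each row's mean update so the
    total incoming weight to every population is conserved."""
    raw_updates = np.asarray(raw_updates, dtype=float)
    if raw_updates.ndim != 2 or raw_updates.shape[0] != raw_updates.shape[1]:
        raise ValueError("expected a square update matrix")
    return raw_updates - raw_updates.mean(axis=1, keepdims=True)


def homeostatic_step(
    H: np.ndarray,
    rates_now: np.ndarray,
    dt: float,
    params: HomeostaticParams,
) -> np.ndarray:
    """One Euler step of ``tau_H dH/dt = (1 - r/r_0) H - H^2``, clipped
    at zero."""
    H = np.asarray(H, dtype=float)
    r = np.asarray(rates_now, dtype=float)
    dH = (dt / params.tau_H) * ((1.0 - r / params.r_0) * H - H * H)
    return np.clip(H + dH, 0.0, None)


def effective_weights(state: PlasticState) -> np.ndarray:
    """Overall connectivity ``W_ij = H_i W_fast_ij`` (row-wise scaling of
    incoming excitatory weights; inhibition is not scaled)."""
    return state.H[:, None] * state.W


def coupled_step(
    net_state: NetworkState,
    plastic_state: PlasticState,
    input_vector: np.ndarray,
    dt: float,
    cfg: NetworkConfig,
    tf: TransferFunction,
    hebbian: HebbianParams | None,
    homeostatic: HomeostaticParams | None = None,
    normalize: bool = False,
    sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[NetworkState, PlasticState]:
    """Euler–Maruyama step of the coupled current + plasticity dynamics.

    Currents follow the reduced-inhibition network driven through the
    effective (homeostatically scaled) weights; the Hebbian matrix,
    optional normalization, and the homeostatic vector are then advanced
    with the pre-update rates, in that order.  Deterministic given the
    rng state.
    """
    u = net_state.u
    r = tf(u)
    drive = effective_weights(plastic_state) @ r - (cfg.w_I / cfg.n) * r.sum()
    du = input_vector - u + drive
    u_new = u + (dt / cfg.tau) * du
    if sigma > 0.0:
        if rng is None:
            raise ValueError("noise requires an rng")
        u_new = u_new + sigma * math.sqrt(dt / cfg.tau) * rng.standard_normal(cfg.n)
    m = float(np.max(np.abs(u_new)))
    if not np.isfinite(m) or m > OVERFLOW_GUARD:
        raise RunawayError(net_state.t + dt, m)

    if hebbian is not None:
        hebbian_step(plastic_state, r, dt, hebbian, normalize=normalize)
    else:
        plastic_state.push(r)
    if homeostatic is not None:
        plastic_state.H = homeostatic_step(plastic_state.H, r, dt, homeostatic)

    return NetworkState(u=u_new, u_I=net_state.u_I, t=net_state.t + dt), plastic_state
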