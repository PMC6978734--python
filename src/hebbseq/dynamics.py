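"""Fixed-connectivity firing-rate network dynamics.

A chain of ``n`` excitatory populations carries two connectivity motifs:
recurrent self-coupling ``w`` (each population onto itself) and
feedforward coupling ``s`` (population ``i`` onto ``i+1``).  Three
variants of the rate equations are integrated with forward Euler:

``excitatory``
    tau du_i/dt = I_i - u_i + w phi(u_i) + s phi(u_{i-1})

``full_inhibition``
    As above minus ``w_EI u_I``, with a single inhibitory population
    tau_I du_I/dt = -u_I + w_IE sum_j phi(u_j)  (linear inhibitory
    transfer function).

``reduced_inhibition``
    The tau_I -> 0 limit of the full model: a uniform subtractive term
    (w_I / n) sum_j phi(u_j) with ``w_I = n w_EI w_IE``.

Time is in milliseconds throughout; the excitatory time constant
defaults to ``tau = 10`` ms and the integration step to ``dt = 0.1`` ms.
Population indices are 0-based; population 0 receives no feedforward
input.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Literal

import numpy as np

from .transfer import TransferFunction

__all__ = [
    "NetworkConfig",
    "NetworkState",
    "Trajectory",
    "RunawayError",
    "build_rf_matrix",
    "step_excitatory",
    "step_full_inhibition",
    "step_reduced_inhibition",
    "simulate",
]

#: abort threshold on |u|; hitting it signals runaway dynamics
OVERFLOW_GUARD = 1.0e6

Variant = Literal["excitatory", "full_inhibition", "reduced_inhibition"]


class RunawayError(RuntimeError):
    """Raised when currents exceed the overflow guard (runaway dynamics)."""

    def __init__(self, t: float, max_u: float):
        super().__init__(
            f"currents exceeded the overflow guard ({OVERFLOW_GUARD:g}) at "
            f"t = {t:.3f} ms (max |u| = {max_u:.3g})"
        )
        self.t = t
        self.max_u = max_u


@dataclass(frozen=True)
class NetworkConfig:
    """Connectivity and time-constant parameters of the population network.

    ``w_I`` is the lumped inhibitory strength of the reduced model; when
    ``w_EI`` and ``w_IE`` are given instead, ``w_I = n w_EI w_IE``.
    """

    n: int
    tau: float = 10.0
    tau_I: float = 1.0
    w: float = 0.0
    s: float = 0.0
    w_I: float | None = None
    w_EI: float | None = None
    w_IE: float | None = None
    variant: Variant = "reduced_inhibition"

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"need at least 2 populations, got n={self.n}")
        if self.tau <= 0 or self.tau_I <= 0:
            raise ValueError("time constants tau and tau_I must be positive")
        if self.w < 0 or self.s < 0:
            raise ValueError("coupling strengths w and s must be non-negative")
        if self.w_EI is not None and self.w_IE is not None:
            lumped = self.n * self.w_EI * self.w_IE
            if self.w_I is None:
                object.__setattr__(self, "w_I", lumped)
            elif not np.isclose(self.w_I, lumped):
                raise ValueError(
                    f"inconsistent inhibition: w_I={self.w_I} but "
                    f"n*w_EI*w_IE={lumped}"
                )
        if self.w_I is None:
            object.__setattr__(self, "w_I", 0.0)
        if self.w_I < 0:
            raise ValueError("w_I must be non-negative")
        if self.variant == "full_inhibition" and (
            self.w_EI is None or self.w_IE is None
        ):
            # split the lumped strength symmetrically in n: w_EI = 1, w_IE = w_I/n
            object.__setattr__(self, "w_EI", 1.0)
            object.__setattr__(self, "w_IE", self.w_I / self.n)

    def with_couplings(self, w: float, s: float) -> "NetworkConfig":
        return replace(self, w=w, s=s)


@dataclass
class NetworkState:
    """Instantaneous state: excitatory currents, inhibitory current, time."""

    u: np.ndarray
    u_I: float = 0.0
    t: float = 0.0

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        if not np.all(np.isfinite(self.u)):
            raise ValueError("network state contains non-finite currents")


@dataclass
class Trajectory:
    """Sampled time course of currents and rates (time x population)."""

    times: np.ndarray
    currents: np.ndarray
    rates: np.ndarray
    u_I: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.currents.shape[1]

    def to_frame(self):
        """Return the trajectory as a tidy DataFrame (time, u_i, r_i columns)."""
        import pandas as pd

        n = self.n
        data = {"time": self.times}
        for i in range(n):
            data[f"u_{i + 1}"] = self.currents[:, i]
        for i in range(n):
            data[f"r_{i + 1}"] = self.rates[:, i]
        if self.u_I is not None:
            data["u_I"] = self.u_I
        return pd.DataFrame(data)


def build_rf_matrix(n: int, w: float, s: float) -> np.ndarray:
    """Recurrent + feedforward weight matrix: ``w`` on the diagonal and
    ``s`` on the first subdiagonal (entry (i, i-1))."""
    if n < 2:
        raise ValueError(f"need at least 2 populations, got n={n}")
    return w * np.eye(n) + s * np.eye(n, k=-1)


def _check_dt(dt: float, tau: float) -> None:
    if dt > tau / 10.0 + 1e-12:
        raise ValueError(f"dt={dt} too coarse; require dt <= tau/10 = {tau / 10.0}")


def _guard(u: np.ndarray, t: float) -> None:
    m = float(np.max(np.abs(u)))
    if not np.isfinite(m) or m > OVERFLOW_GUARD:
        raise RunawayError(t, m)


def step_excitatory(
    state: NetworkState,
    input_vector: np.ndarray,
    dt: float,
    tf: TransferFunction,
    W: np.ndarray,
    tau: float = 10.0,
) -> NetworkState:
    """One forward-Euler step of the pure excitatory network,
    ``u <- u + (dt/tau) (I - u + W phi(u))``."""
    _check_dt(dt, tau)
    u = state.u
    du = input_vector - u + W @ tf(u)
    u_new = u + (dt / tau) * du
    _guard(u_new, state.t + dt)
    return NetworkState(u=u_new, u_I=state.u_I, t=state.t + dt)


def step_full_inhibition(
    state: NetworkState,
    input_vector: np.ndarray,
    dt: float,
    tf: TransferFunction,
    cfg: NetworkConfig,
    W: np.ndarray | None = None,
) -> NetworkState:
    """One Euler step of the excitatory chain with an explicit inhibitory
    population (linear inhibitory transfer function)."""
    _check_dt(dt, min(cfg.tau, cfg.tau_I))
    if W is None:
        W = build_rf_matrix(cfg.n, cfg.w, cfg.s)
    u = state.u
    r = tf(u)
    du = input_vector - u + W @ r - cfg.w_EI * state.u_I
    du_I = -state.u_I + cfg.w_IE * float(np.sum(r))
    u_new = u + (dt / cfg.tau) * du
    u_I_new = state.u_I + (dt / cfg.tau_I) * du_I
    _guard(u_new, state.t + dt)
    return NetworkState(u=u_new, u_I=u_I_new, t=state.t + dt)


def step_reduced_inhibition(
    state: NetworkState,
    input_vector: np.ndarray,
    dt: float,
    tf: TransferFunction,
    cfg: NetworkConfig,
    W: np.ndarray | None = None,
) -> NetworkState:
    """One Euler step with instantaneous inhibition: a uniform
    ``(w_I/n) sum_j phi(u_j)`` subtracted from every population."""
    _check_dt(dt, cfg.tau)
    if W is None:
        W = build_rf_matrix(cfg.n, cfg.w, cfg.s)
    u = state.u
    r = tf(u)
    inh = (cfg.w_I / cfg.n) * float(np.sum(r))
    du = input_vector - u + W @ r - inh
    u_new = u + (dt / cfg.tau) * du
    _guard(u_new, state.t + dt)
    return NetworkState(u=u_new, u_I=state.u_I, t=state.t + dt)


InputFn = Callable[[float], np.ndarray]


def simulate(
    cfg: NetworkConfig,
    tf: TransferFunction,
    W: np.ndarray | None,
    input_fn: InputFn | None,
    u0: np.ndarray,
    duration: float,
    dt: float = 0.1,
    stride: int = 10,
    u_I0: float = 0.0,
) -> Trajectory:
    """Integrate the configured network variant and return the sampled
    trajectory.

    Parameters
    ----------
    W : optional explicit weight matrix; defaults to the recurrent +
        feedforward matrix built from ``cfg.w`` and ``cfg.s``.
    input_fn : maps time (ms) to the external input vector; ``None``
        means zero input.
    stride : record every ``stride``-th step (the initial state is always
        recorded).

    Raises
    ------
    RunawayError
        If any |u_i| exceeds the overflow guard, reporting the blow-up time.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = cfg.n
    u0 = np.asarray(u0, dtype=float)
    if u0.shape != (n,):
        raise ValueError(f"u0 must have shape ({n},), got {u0.shape}")
    if W is None:
        W = build_rf_matrix(n, cfg.w, cfg.s)
    W = np.asarray(W, dtype=float)

    tau_min = cfg.tau if cfg.variant != "full_inhibition" else min(cfg.tau, cfg.tau_I)
    _check_dt(dt, tau_min)

    n_steps = int(round(duration / dt))
    zero = np.zeros(n)

    u = u0.copy()
    u_I = float(u_I0)
    times = [0.0]
    currents = [u.copy()]
    u_I_trace = [u_I]

    reduced = cfg.variant == "reduced_inhibition"
    full = cfg.variant == "full_inhibition"
    g = cfg.w_I / n if reduced else 0.0

    for k in range(1, n_steps + 1):
        t = (k - 1) * dt
        I = input_fn(t) if input_fn is not None else zero
        r = tf(u)
        drive = W @ r
        if reduced:
            drive -= g * r.sum()
        elif full:
            drive -= cfg.w_EI * u_I
            u_I += (dt / cfg.tau_I) * (-u_I + cfg.w_IE * r.sum())
        u += (dt / cfg.tau) * (I - u + drive)
        m = np.max(np.abs(u))
        if not np.isfinite(m) or m > OVERFLOW_GUARD:
            raise RunawayError(k * dt, float(m))
        if k % stride == 0 or k == n_steps:
            times.append(k * dt)
            currents.append(u.copy())
            u_I_trace.append(u_I)

    currents_arr = np.array(currents)
    return Trajectory(
        times=np.array(times),
        currents=currents_arr,
        rates=tf(currents_arr),
        u_I=np.array(u_I_trace) if full else None,
    )
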