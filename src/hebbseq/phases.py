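"""Dynamical-regime classification and the (s, w) bifurcation diagram.

Starting a network with only the first population active (the *canonical
probe*), four qualitatively different behaviours occur depending on the
recurrent strength ``w`` and feedforward strength ``s``:

``PA``
    Persistent activity: the dynamics converge to a fixed point with one
    or more populations above threshold, without a traveling sequence.
``SA``
    Sequential activity: populations activate transiently in order, the
    wave reaches the last population, and all activity then dies out.
``dSA``
    Decaying sequential activity: the wave attenuates and dies before
    reaching the last population.
``SA_PA``
    A sequence that traverses the whole chain and terminates in a
    persistent state.

For the piecewise linear transfer function (slope ``nu``, normalized so
the maximum rate is 1) the region boundaries are analytic.  With global
inhibition of lumped strength ``w_I`` in a network of ``n`` populations,
let ``g = w_I / n``.  A block of ``p`` co-active saturated populations is
self-sustaining iff ``w >= 1/nu + g p``, and keeps the next population
silent iff ``s <= g p``.  This yields the staircase boundaries

* PA vs SA/PA (critical feedforward):  ``s_c = g ceil((w* - 1/nu - g)/g)``
* SA/PA vs PA (critical recurrent):    ``w_c = g ceil((s* - g)/g)``
  measured as an offset from the PA base line ``w = 1/nu + g``
* SA vs dSA (wave propagation):        ``w + s = 1/nu + 2 g``
  (during a hand-off two populations are co-active, so the front must
  saturate against the inhibition ``2 g`` they jointly recruit)

and the PA region splits into ``n(n+1)/2`` squares of side ``g`` indexed
by the minimum/maximum number of co-active populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .dynamics import NetworkConfig, Trajectory, simulate
from .transfer import PiecewiseLinearTF, TransferFunction, normalizer

__all__ = [
    "Regime",
    "RegimeLabel",
    "ClassifierSettings",
    "PhaseGrid",
    "classify",
    "canonical_probe",
    "critical_feedforward",
    "critical_recurrent",
    "pa_subregion",
    "analytic_label",
    "scan",
    "burst_duration_scaling",
]


class Regime(str, Enum):
    PA = "PA"
    SA = "SA"
    DSA = "dSA"
    SA_PA = "SA_PA"


@dataclass(frozen=True)
class RegimeLabel:
    """Classification of a probe trajectory plus its diagnostics."""

    label: Regime
    n_active_final: int
    sequence_reach: int
    order_violations: int
    settled: bool = True

    def __post_init__(self) -> None:
        # internal consistency of the label with its diagnostics
        if self.label is Regime.SA:
            assert self.n_active_final == 0
        if self.label is Regime.DSA:
            assert self.n_active_final == 0
        if self.label in (Regime.PA, Regime.SA_PA):
            assert self.n_active_final >= 1


@dataclass(frozen=True)
class ClassifierSettings:
    """Thresholds and horizons of the regime classifier.

    ``alpha`` is the active-rate threshold as a fraction of the reference
    maximum rate; ``settle_tol`` (rate-units/ms) bounds |du/dt| over the
    terminal window (``settle_window_tau`` times tau) for a state to
    count as a fixed point; the probe horizon is ``horizon_tau_n * tau *
    n`` so a full sequence can traverse the chain.
    """

    alpha: float = 0.5
    settle_tol: float = 1.0e-5
    settle_window_tau: float = 20.0
    horizon_tau_n: float = 50.0
    active_current: float | None = None  # probe initialization; default tf reference


def _first_crossings(
    times: np.ndarray, rates: np.ndarray, threshold: float
) -> np.ndarray:
    """Per-population time of first rate crossing above ``threshold``
    (NaN if never crossed)."""
    above = rates > threshold
    any_above = above.any(axis=0)
    idx = above.argmax(axis=0)
    out = np.where(any_above, times[idx], np.nan)
    return out


def _label_from_diagnostics(
    n: int,
    crossed: np.ndarray,
    first_cross: np.ndarray,
    active_final: np.ndarray,
    settled: bool,
) -> RegimeLabel:
    """Shared label logic for single-trajectory and batched classification.

    A sequence (SA or SA/PA) requires the wave to reach the last
    population; SA/PA additionally requires that some population which
    was transiently active has switched off, distinguishing a sequence
    terminating in a persistent block from a fixed point reached by
    monotone recruitment (plain PA).
    """
    reach = int(np.flatnonzero(crossed).max()) if crossed.any() else -1
    n_active = int(active_final.sum())
    deactivated = bool(np.any(crossed & ~active_final))

    fc = first_cross[crossed]
    order_violations = int(np.sum(np.diff(fc) < 0)) if fc.size > 1 else 0

    if n_active >= 1:
        if reach == n - 1 and deactivated:
            label = Regime.SA_PA
        else:
            label = Regime.PA
    else:
        label = Regime.SA if reach == n - 1 else Regime.DSA
    return RegimeLabel(
        label=label,
        n_active_final=n_active,
        sequence_reach=reach,
        order_violations=order_violations,
        settled=settled,
    )


def classify(
    trajectory: Trajectory,
    tf: TransferFunction,
    settings: ClassifierSettings = ClassifierSettings(),
    tau: float = 10.0,
) -> RegimeLabel:
    """Classify a canonical-probe trajectory into one of the four regimes.

    "Active" means rate above ``alpha`` times the reference maximum rate;
    the final state is judged at the end of the trajectory, which must be
    settled (max |du/dt| below ``settle_tol`` over the terminal window)
    for a persistent label to be trusted.
    """
    rates = trajectory.rates
    if not np.all(np.isfinite(rates)):
        raise ValueError("trajectory contains non-finite values")
    times = trajectory.times
    n = trajectory.n
    if times[-1] < 10 * tau:
        raise ValueError("trajectory too short to classify")
    threshold = settings.alpha * normalizer(tf)

    first_cross = _first_crossings(times, rates, threshold)
    crossed = np.isfinite(first_cross)
    active_final = rates[-1] > threshold

    # settled check over the terminal window via finite differences
    window = settings.settle_window_tau * tau
    sel = times >= times[-1] - window
    du = np.diff(trajectory.currents[sel], axis=0)
    dts = np.diff(times[sel])
    settled = bool(np.max(np.abs(du / dts[:, None])) < settings.settle_tol)

    return _label_from_diagnostics(n, crossed, first_cross, active_final, settled)


def canonical_probe(
    cfg: NetworkConfig,
    tf: TransferFunction,
    settings: ClassifierSettings = ClassifierSettings(),
    W: np.ndarray | None = None,
    dt: float = 0.5,
    stride: int = 4,
) -> Trajectory:
    """Simulate the canonical probe: population 0 initialized at the
    active current, all others silent, no external input."""
    u0 = np.zeros(cfg.n)
    u0[0] = (
        settings.active_current
        if settings.active_current is not None
        else tf.reference_current()
    )
    horizon = settings.horizon_tau_n * cfg.tau * cfg.n
    return simulate(cfg, tf, W, None, u0, horizon, dt=dt, stride=stride)


# ---------------------------------------------------------------------------
# analytic boundaries (piecewise linear transfer function)
# ---------------------------------------------------------------------------


def critical_feedforward(w_star: float, w_I: float, n: int, nu: float = 1.0) -> float:
    """Critical feedforward strength separating PA (below) from SA/PA
    (above) at recurrent strength ``w_star``."""
    g = w_I / n
    if not w_star > 1.0 / nu + g:
        raise ValueError(
            f"critical_feedforward requires w* > 1/nu + w_I/n = {1.0 / nu + g}"
        )
    return g * math.ceil((w_star - 1.0 / nu - g) / g)


def critical_recurrent(
    s_star: float, w_I: float, n: int, nu: float = 1.0
) -> tuple[float, float]:
    """Critical recurrent strength separating SA/PA (below) from PA
    (above) at feedforward strength ``s_star``.

    Returns ``(raw, absolute)``: the raw staircase value
    ``g ceil((s* - g)/g)`` and its interpretation as an offset from the
    PA base line, ``absolute = 1/nu + g + raw``.  The absolute value is
    the boundary verified by simulation.
    """
    g = w_I / n
    if not s_star > g:
        raise ValueError(f"critical_recurrent requires s* > w_I/n = {g}")
    raw = g * math.ceil((s_star - g) / g)
    return raw, 1.0 / nu + g + raw


def pa_subregion(
    s: float, w: float, w_I: float, n: int, nu: float = 1.0
) -> tuple[int, int]:
    """Lattice indices (i_min, i_max) of the PA square containing (s, w):
    the predicted minimum and maximum number of co-active populations at
    the persistent fixed point."""
    g = w_I / n
    if analytic_label(s, w, w_I, n, nu) is not Regime.PA:
        raise ValueError(f"(s={s}, w={w}) is not inside the PA region")
    i_min = int(np.clip(math.floor(s / g), 1, n)) if g > 0 else 1
    i_max = int(np.clip(math.floor((w - 1.0 / nu) / g), 1, n)) if g > 0 else n
    return i_min, i_max


def _propagation_peaks(
    s: np.ndarray,
    w: np.ndarray,
    w_I: float,
    n: int,
    nu: float = 1.0,
    u0: float = 1.0,
    horizon_tau: float | None = None,
) -> np.ndarray:
    """Peak rate of the *last* population in the sub-saturation reduced
    model, for a batch of (s, w) points.

    Below saturation the piecewise linear chain obeys the rectified
    linear system ``tau du_i/dt = -u_i + w nu [u_i]_+ + s nu [u_{i-1}]_+
    - (w_I nu / n) sum_j [u_j]_+``, started from the canonical probe.
    It is integrated here with classic RK4 (independent of the
    forward-Euler production integrator) and without the saturation
    nonlinearity, which only matters well inside the SA region.  Time is
    in units of tau.
    """
    s = np.atleast_1d(np.asarray(s, dtype=float))
    w = np.atleast_1d(np.asarray(w, dtype=float))
    m = s.size
    g = w_I * nu / n
    if horizon_tau is None:
        horizon_tau = 15.0 * n
    h = 0.02  # RK4 step, units of tau

    sc = s[:, None] * nu
    wc = w[:, None] * nu

    def rhs(u):
        r = np.maximum(u, 0.0)
        d = wc * r - u
        d[:, 1:] += sc * r[:, :-1]
        d -= g * r.sum(axis=1, keepdims=True)
        return d

    u = np.zeros((m, n))
    u[:, 0] = u0
    peak_last = np.zeros(m)
    for _ in range(int(horizon_tau / h)):
        k1 = rhs(u)
        k2 = rhs(u + 0.5 * h * k1)
        k3 = rhs(u + 0.5 * h * k2)
        k4 = rhs(u + h * k3)
        u = u + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        np.clip(u, -1e9, 1e9, out=u)
        np.maximum(peak_last, u[:, -1], out=peak_last)
        if np.max(np.abs(u)) < 1e-12:
            break
    return nu * peak_last


def sequence_propagates(
    s: float,
    w: float,
    w_I: float,
    n: int,
    nu: float = 1.0,
    alpha: float = 0.5,
) -> bool:
    """Whether a probe-triggered wave reaches the last population.

    Predicted from the sub-saturation reduced model: the wave propagates
    iff the last population's peak rate exceeds the active threshold
    ``alpha`` (as a fraction of the maximum rate).  For long chains this
    reduces to the asymptotic condition ``w + s > 1/nu``; at finite ``n``
    marginal amplification dies against the threshold before the end of
    the chain.
    """
    # normalized model: probe amplitude 1 = saturation current, max rate nu
    peak = _propagation_peaks(s, w, w_I, n, nu)[0]
    return bool(peak >= alpha * nu)


def analytic_label(
    s: float, w: float, w_I: float, n: int, nu: float = 1.0, alpha: float = 0.5
) -> Regime:
    """Regime predicted by the analytic piecewise-linear boundaries."""
    inv = 1.0 / nu
    g = w_I / n
    if w > inv + g:
        s_c = critical_feedforward(w, w_I, n, nu) if w_I > 0 else 0.0
        return Regime.PA if s <= s_c else Regime.SA_PA
    return Regime.SA if sequence_propagates(s, w, w_I, n, nu, alpha) else Regime.DSA


def analytic_grid(
    s_axis: np.ndarray,
    w_axis: np.ndarray,
    w_I: float,
    n: int,
    nu: float = 1.0,
    alpha: float = 0.5,
) -> np.ndarray:
    """Analytic regime prediction on a grid (same layout as ``scan``).

    The propagation boundary is evaluated for all points in one batched
    call, which is much faster than per-point ``analytic_label``.
    """
    s_axis = np.asarray(s_axis, dtype=float)
    w_axis = np.asarray(w_axis, dtype=float)
    ss, ww = np.meshgrid(s_axis, w_axis)
    peaks = _propagation_peaks(ss.ravel(), ww.ravel(), w_I, n, nu).reshape(ss.shape)
    g = w_I / n
    out = np.empty(ss.shape, dtype=object)
    for i, w in enumerate(w_axis):
        for j, s in enumerate(s_axis):
            if w > 1.0 / nu + g:
                s_c = critical_feedforward(w, w_I, n, nu) if w_I > 0 else 0.0
                out[i, j] = Regime.PA if s <= s_c else Regime.SA_PA
            else:
                out[i, j] = Regime.SA if peaks[i, j] >= alpha * nu else Regime.DSA
    return out


# ---------------------------------------------------------------------------
# grid scan (vectorized over (s, w) points)
# ---------------------------------------------------------------------------


@dataclass
class PhaseGrid:
    """Labels of a scanned (s, w) grid; ``labels[i, j]`` corresponds to
    ``(s_values[j], w_values[i])``."""

    s_values: np.ndarray
    w_values: np.ndarray
    labels: np.ndarray  # dtype=object array of Regime
    n_active_final: np.ndarray
    sequence_reach: np.ndarray

    def counts(self) -> dict[str, int]:
        flat = self.labels.ravel()
        return {r.value: sum(1 for x in flat if x is r) for r in Regime}


def _probe_batch(
    s: np.ndarray,
    w: np.ndarray,
    tf: TransferFunction,
    n: int,
    w_I: float = 0.0,
    tau: float = 10.0,
    tau_I: float | None = None,
    variant: str = "reduced_inhibition",
    dt: float = 0.5,
    settings: ClassifierSettings = ClassifierSettings(),
) -> list[RegimeLabel]:
    """Run the canonical probe for many (s, w) points simultaneously.

    All points are stepped in lockstep as a (M, n) array; integration
    stops early once every point has settled (max |du/dt| below the
    settle tolerance).  Produces the same diagnostics as ``classify``.
    """
    s = np.asarray(s, dtype=float)
    w = np.asarray(w, dtype=float)
    m = s.size
    if w.size != m:
        raise ValueError("s and w must have the same length")
    full = variant == "full_inhibition"
    if full:
        if tau_I is None:
            raise ValueError("full_inhibition requires tau_I")
        if dt > tau_I / 2.0:
            dt = tau_I / 2.0
        w_IE = w_I / n
        w_EI = 1.0

    horizon = settings.horizon_tau_n * tau * n
    n_steps = int(round(horizon / dt))
    threshold = settings.alpha * normalizer(tf)
    active_current = (
        settings.active_current
        if settings.active_current is not None
        else tf.reference_current()
    )

    u = np.zeros((m, n))
    u[:, 0] = active_current
    u_I = np.zeros(m)
    sc = s[:, None]
    wc = w[:, None]
    g = w_I / n

    first_cross = np.full((m, n), np.nan)
    crossed = np.zeros((m, n), dtype=bool)
    check_every = max(1, int(round(2 * tau / dt)))
    min_steps = int(round(20 * tau / dt))

    t = 0.0
    for k in range(1, n_steps + 1):
        r = tf(u)
        drive = wc * r
        drive[:, 1:] += sc * r[:, :-1]
        if full:
            drive -= w_EI * u_I[:, None]
            u_I += (dt / tau_I) * (-u_I + w_IE * r.sum(axis=1))
        elif w_I > 0:
            drive -= g * r.sum(axis=1, keepdims=True)
        du = (drive - u) / tau
        u = u + dt * du
        t = k * dt
        newly = (tf(u) > threshold) & ~crossed
        if newly.any():
            first_cross[newly] = t
            crossed |= newly
        if k % check_every == 0 and k >= min_steps:
            if np.max(np.abs(du)) < settings.settle_tol:
                break

    r = tf(u)
    du_final = np.abs(du)
    labels = []
    for i in range(m):
        labels.append(
            _label_from_diagnostics(
                n,
                crossed[i],
                first_cross[i],
                r[i] > threshold,
                bool(du_final[i].max() < settings.settle_tol),
            )
        )
    return labels


def scan(
    cfg_template: NetworkConfig,
    tf: TransferFunction,
    s_axis: np.ndarray,
    w_axis: np.ndarray,
    settings: ClassifierSettings = ClassifierSettings(),
    dt: float = 0.5,
) -> PhaseGrid:
    """Classify the canonical probe on every point of an (s, w) grid."""
    s_axis = np.asarray(s_axis, dtype=float)
    w_axis = np.asarray(w_axis, dtype=float)
    if s_axis.size == 0 or w_axis.size == 0:
        raise ValueError("axes must be nonempty")
    ss, ww = np.meshgrid(s_axis, w_axis)
    labels = _probe_batch(
        ss.ravel(),
        ww.ravel(),
        tf,
        cfg_template.n,
        w_I=cfg_template.w_I,
        tau=cfg_template.tau,
        tau_I=cfg_template.tau_I,
        variant=cfg_template.variant,
        dt=dt,
        settings=settings,
    )
    shape = ww.shape
    lab = np.array([l.label for l in labels], dtype=object).reshape(shape)
    nact = np.array([l.n_active_final for l in labels]).reshape(shape)
    reach = np.array([l.sequence_reach for l in labels]).reshape(shape)
    return PhaseGrid(
        s_values=s_axis,
        w_values=w_axis,
        labels=lab,
        n_active_final=nact,
        sequence_reach=reach,
    )


def burst_duration_scaling(
    trajectory: Trajectory,
    threshold: float,
    skip: int = 1,
    stop: int | None = None,
    relative: bool = False,
) -> float:
    """Least-squares slope of log(active-interval duration) versus
    log(position) along a sequential trajectory.

    The active interval of a population is the total time its rate
    exceeds ``threshold``; with ``relative`` the threshold is taken as
    ``threshold`` times the population's own peak rate, which measures
    the pulse *width* independently of the amplitude trend along the
    chain (in the saturated regime, where peaks are clamped at the
    maximum rate, the two definitions coincide).  Populations before
    index ``skip`` (the directly initialized ones) are excluded from the
    fit.  Requires at least 4 populations with a positive active
    interval.  ``stop`` excludes populations at the end of the chain,
    whose bursts are inflated by the boundary (no successor activates to
    recruit inhibition against them).
    """
    times = trajectory.times
    rates = trajectory.rates
    dts = np.diff(times)
    if relative:
        thr = threshold * rates.max(axis=0)
    else:
        thr = np.full(trajectory.n, threshold)
    above = rates > thr
    # duration = sum of step widths where the population is above threshold
    durations = (above[:-1] & above[1:]).T @ dts
    idx = np.arange(trajectory.n)
    sel = (durations > 0) & (idx >= skip)
    if stop is not None:
        sel &= idx < stop
    if sel.sum() < 4:
        raise ValueError(
            f"only {int(sel.sum())} populations crossed threshold; need >= 4"
        )
    slope = np.polyfit(np.log(idx[sel]), np.log(durations[sel]), 1)[0]
    return float(slope)
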