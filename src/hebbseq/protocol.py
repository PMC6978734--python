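"""Sequential stimulation protocols and learning experiments.

During training each of the ``n`` populations is stimulated once per
sequence repetition, one at a time: population ``i`` receives a constant
current ``I_amp`` for a duration ``T``, followed by an inter-stimulus
gap ``Delta`` before population ``i+1`` is driven.  The sequence is
repeated ``k`` times with an inter-repetition interval ``gap`` long
compared to the network time constants, which prevents the last
population's activity from concatenating onto the first.

Relative to the plasticity delay ``D``, the two timing parameters select
which connectivity motif grows (tie-breaks resolve to the growing side):

====================  =======================
T >= D and Delta <= D  both_grow
T >= D and Delta > D   recurrent_only
T < D and Delta <= D   feedforward_only
T < D and Delta > D    no_change
====================  =======================

``run_learning`` integrates the coupled current + plasticity dynamics
across the whole protocol plus a post-stimulation relaxation window, and
``retrieval_probe`` classifies what the learned connectivity generates
when the first population is transiently activated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .dynamics import NetworkConfig, NetworkState, RunawayError
from .phases import ClassifierSettings, Regime, RegimeLabel, canonical_probe, classify
from .plasticity import (
    HebbianParams,
    HomeostaticParams,
    PlasticState,
    coupled_step,
    effective_weights,
)
from .transfer import PiecewiseLinearTF, TransferFunction

__all__ = [
    "SequentialStimulation",
    "LearningRecord",
    "stimulus_at",
    "regime_of_stimulus",
    "run_learning",
    "retrieval_probe",
    "noise_robustness_suite",
    "LearningSetup",
    "make_preset",
    "STIMULUS_TIMINGS",
    "EXPECTED_RETRIEVAL",
]


@dataclass(frozen=True)
class SequentialStimulation:
    """Timing and amplitude of the sequential stimulation protocol.

    ``T``: stimulus duration (ms); ``Delta``: inter-stimulus gap (ms);
    ``I_amp``: stimulus current; ``k``: number of sequence repetitions;
    ``gap``: interval between repetitions (ms), which must dominate the
    fast network time constants.

    ``u_bg`` is a constant background current applied to every
    population throughout the run (default 0).  A slightly negative
    background models a resting drive below the firing threshold: input
    noise then only rarely elicits spurious rates, so spontaneous
    activity stays far below the homeostatic set point and the
    homeostatic variables recover after training even in the presence
    of noise.
    """

    T: float
    Delta: float
    I_amp: float = 2.0
    k: int = 100
    gap: float = 100.0
    u_bg: float = 0.0

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("stimulus duration T must be positive")
        if self.Delta < 0:
            raise ValueError("inter-stimulus gap Delta must be non-negative")
        if self.k < 1:
            raise ValueError("need at least one repetition")
        if self.gap < 2 * max(self.T, self.Delta):
            warnings.warn(
                "inter-repetition gap is not much longer than T and Delta; "
                "the last and first stimuli may concatenate",
                stacklevel=2,
            )

    def period(self, n: int) -> float:
        """Duration of one repetition for an n-population network."""
        return n * (self.T + self.Delta) + self.gap


def stimulus_at(t: float, protocol: SequentialStimulation, n: int) -> np.ndarray:
    """External input vector at time ``t``: ``I_amp`` on the population
    whose stimulation window contains ``t``, background elsewhere.  At
    most one population is driven at any time."""
    if t < 0:
        raise ValueError("t must be non-negative")
    out = np.full(n, protocol.u_bg)
    P = protocol.period(n)
    rep, t_loc = divmod(t, P)
    if rep >= protocol.k:
        return out
    slot = protocol.T + protocol.Delta
    i, t_in = divmod(t_loc, slot)
    if i < n and t_in < protocol.T:
        out[int(i)] += protocol.I_amp
    return out


def regime_of_stimulus(T: float, Delta: float, D: float) -> str:
    """Which connectivity motif the stimulus timing makes grow.

    Boundary equalities resolve to the growing side.  Timings with
    ``2T + Delta < D`` allow potentiation between non-nearest-neighbor
    populations; they are permitted but flagged with a warning.
    """
    if T <= 0 or Delta < 0 or D <= 0:
        raise ValueError("timings must be positive (Delta may be zero)")
    if 2 * T + Delta < D:
        warnings.warn(
            "2T + Delta < D: non-nearest-neighbor potentiation is possible "
            "in this regime and is untested",
            stacklevel=2,
        )
    recurrent = T >= D
    feedforward = Delta <= D
    if recurrent and feedforward:
        return "both_grow"
    if recurrent:
        return "recurrent_only"
    if feedforward:
        return "feedforward_only"
    return "no_change"


@dataclass
class LearningRecord:
    """Time series and end state of a learning run.

    ``wbar``/``sbar`` trace the mean diagonal / first-subdiagonal of the
    effective (homeostatically scaled) connectivity; ``rep_end`` holds
    the fast Hebbian means at the end of each completed repetition,
    which is what the reduced learning map predicts.
    """

    times: np.ndarray
    wbar: np.ndarray
    sbar: np.ndarray
    H_mean: np.ndarray
    H_min: np.ndarray
    rep_end: np.ndarray  # (completed reps, 2): fast (wbar, sbar)
    W_fast: np.ndarray
    H: np.ndarray
    converged_at: int | None = None
    runaway_rep: int | None = None

    @property
    def W_effective(self) -> np.ndarray:
        return self.H[:, None] * self.W_fast

    def increments(self) -> np.ndarray:
        """Per-repetition increments of the fast (wbar, sbar)."""
        start = np.zeros((1, 2))
        return np.diff(np.vstack([start, self.rep_end]), axis=0)


def _mean_diag_sub(W: np.ndarray) -> tuple[float, float]:
    return float(np.mean(np.diag(W))), float(np.mean(np.diag(W, k=-1)))


def run_learning(
    cfg: NetworkConfig,
    tf: TransferFunction,
    protocol: SequentialStimulation,
    hebbian: HebbianParams,
    homeostatic: HomeostaticParams | None = None,
    normalize: bool = False,
    sigma: float = 0.0,
    seed: int = 0,
    dt: float = 0.5,
    W0: np.ndarray | None = None,
    record_every: float = 10.0,
    relax_tau_H: float = 5.0,
    conv_tol: float = 1.0e-3,
    conv_reps: int = 3,
    early_stop: bool = True,
    noise_during_relaxation: bool = False,
) -> LearningRecord:
    """Run the full coupled learning experiment.

    The protocol's ``k`` repetitions are integrated with Euler–Maruyama
    at step ``dt``, followed by a relaxation window (``relax_tau_H`` times
    tau_H with homeostasis, 20 tau otherwise) with no input, during
    which the homeostatic variables recover and unmask the learned
    weights.  Convergence of the learned (wbar, sbar) is declared when
    the per-repetition change stays below ``conv_tol * w_max`` for
    ``conv_reps`` consecutive repetitions; with ``early_stop`` the
    remaining repetitions are skipped.

    A runaway abort (currents beyond the overflow guard, the expected
    outcome of Hebbian-only learning in the both-grow regime) is caught
    and reported through ``runaway_rep`` rather than raised.
    """
    n = cfg.n
    regime_of_stimulus(protocol.T, protocol.Delta, hebbian.D)  # timing warnings
    if tf(protocol.I_amp) <= hebbian.r_w:
        raise ValueError(
            "stimulus amplitude too weak: phi(I_amp) must exceed the "
            f"plasticity threshold r_w={hebbian.r_w}"
        )
    if homeostatic is not None:
        homeostatic.check_separation(hebbian.T_w)
    rng = np.random.default_rng(seed)

    state = NetworkState(u=np.zeros(n))
    plastic = PlasticState(n, dt, hebbian.D, W0=W0)

    P = protocol.period(n)
    steps_per_rep = int(round(P / dt))
    record_stride = max(1, int(round(record_every / dt)))

    times, wbar, sbar, h_mean, h_min = [], [], [], [], []
    rep_end: list[tuple[float, float]] = []
    converged_at = None
    runaway_rep = None

    def record(t: float) -> None:
        W_eff = effective_weights(plastic)
        wv, sv = _mean_diag_sub(W_eff)
        times.append(t)
        wbar.append(wv)
        sbar.append(sv)
        h_mean.append(float(plastic.H.mean()))
        h_min.append(float(plastic.H.min()))

    record(0.0)
    step_idx = 0
    try:
        for rep in range(protocol.k):
            for _ in range(steps_per_rep):
                I = stimulus_at(state.t, protocol, n)
                state, plastic = coupled_step(
                    state, plastic, I, dt, cfg, tf, hebbian,
                    homeostatic=homeostatic, normalize=normalize,
                    sigma=sigma, rng=rng,
                )
                step_idx += 1
                if step_idx % record_stride == 0:
                    record(state.t)
            rep_end.append(_mean_diag_sub(plastic.W))
            if converged_at is None and len(rep_end) > conv_reps:
                recent = np.array(rep_end[-(conv_reps + 1):])
                if np.all(
                    np.abs(np.diff(recent, axis=0)) < conv_tol * hebbian.w_max
                ):
                    converged_at = rep + 1
                    if early_stop:
                        break
    except RunawayError:
        runaway_rep = len(rep_end) + 1

    # post-stimulation relaxation: no input, homeostasis recovers
    relax = relax_tau_H * homeostatic.tau_H if homeostatic is not None else 20 * cfg.tau
    if runaway_rep is not None:
        relax = 0.0
    background = np.full(n, protocol.u_bg)
    relax_sigma = sigma if noise_during_relaxation else 0.0
    for _ in range(int(round(relax / dt))):
        state, plastic = coupled_step(
            state, plastic, background, dt, cfg, tf, hebbian,
            homeostatic=homeostatic, normalize=normalize,
            sigma=relax_sigma, rng=rng,
        )
        step_idx += 1
        if step_idx % record_stride == 0:
            record(state.t)
    if not times or state.t > times[-1]:
        record(state.t)

    return LearningRecord(
        times=np.array(times),
        wbar=np.array(wbar),
        sbar=np.array(sbar),
        H_mean=np.array(h_mean),
        H_min=np.array(h_min),
        rep_end=np.array(rep_end).reshape(-1, 2),
        W_fast=plastic.W.copy(),
        H=plastic.H.copy(),
        converged_at=converged_at,
        runaway_rep=runaway_rep,
    )


def retrieval_probe(
    cfg: NetworkConfig,
    W_learned: np.ndarray,
    tf: TransferFunction,
    settings: ClassifierSettings = ClassifierSettings(),
    dt: float = 0.5,
) -> RegimeLabel:
    """Classify what the learned connectivity generates.

    The first population is initialized at the active rate against the
    full learned effective weight matrix (homeostasis assumed relaxed)
    with the fixed global inhibition, and the resulting trajectory is
    classified into PA / SA / dSA / SA-PA.
    """
    traj = canonical_probe(cfg, tf, settings, W=W_learned, dt=dt)
    return classify(traj, tf, settings, tau=cfg.tau)


# ---------------------------------------------------------------------------
# experiment presets
# ---------------------------------------------------------------------------

#: (T, Delta) stimulus timings (ms) whose learned outcome spans the four
#: regimes with weak inhibition (w_I = 1, w_max = 3) and delay D = 14.5 ms
STIMULUS_TIMINGS: dict[str, tuple[float, float]] = {
    "sa": (7.0, 14.0),
    "pa": (50.0, 40.0),
    "dsa": (5.0, 15.0),
    "sa_pa": (22.0, 8.5),
}

EXPECTED_RETRIEVAL: dict[str, Regime] = {
    "sa": Regime.SA,
    "pa": Regime.PA,
    "dsa": Regime.DSA,
    "sa_pa": Regime.SA_PA,
}


@dataclass(frozen=True)
class LearningSetup:
    """A fully specified learning experiment (network + rules + stimulus)."""

    cfg: NetworkConfig
    tf: TransferFunction
    protocol: SequentialStimulation
    hebbian: HebbianParams
    homeostatic: HomeostaticParams | None
    normalize: bool = False
    sigma: float = 0.0
    dt: float = 0.5
    W0: np.ndarray | None = None

    def run(self, seed: int = 0, **kwargs) -> LearningRecord:
        kwargs.setdefault("W0", self.W0)
        return run_learning(
            self.cfg, self.tf, self.protocol, self.hebbian,
            homeostatic=self.homeostatic, normalize=self.normalize,
            sigma=self.sigma, seed=seed, dt=self.dt, **kwargs,
        )


def make_preset(
    name: str,
    n: int = 10,
    k: int = 100,
    stabilization: str = "homeostatic",
    sigma: float = 0.0,
    desk_scale: bool = True,
) -> LearningSetup:
    """Build a named learning experiment.

    ``name`` is a stimulus-timing key (``sa``, ``pa``, ``dsa``,
    ``sa_pa``) or a timing-equivalent alias ``runaway`` /
    ``normalization`` (both-grow timing T=19, Delta=10 with the
    corresponding stabilization).  ``stabilization`` is one of
    ``hebbian_only``, ``normalization``, ``homeostatic``.

    With ``desk_scale`` the slow time constants are shortened
    (T_w = 500 ms, tau_H = 5000 ms instead of 2000 / 20000 ms) while
    preserving their ordering tau << T_w << tau_H, so that learning
    converges within a desk-scale run; the timing parameters T, Delta, D
    that select the learned regime are untouched.
    """
    if name in ("runaway", "normalization"):
        timing = (19.0, 10.0)
        stabilization = "hebbian_only" if name == "runaway" else "normalization"
    else:
        timing = STIMULUS_TIMINGS[name]
    T, Delta = timing
    T_w = 500.0 if desk_scale else 2000.0
    tau_H = 3000.0 if desk_scale else 20000.0
    hebbian = HebbianParams(w_max=3.0, D=12.0, T_w=T_w, r_w=0.4)
    homeo = HomeostaticParams(tau_H=tau_H, r_0=0.08)
    cfg = NetworkConfig(n=n, w_I=1.0)
    proto = SequentialStimulation(T=T, Delta=Delta, I_amp=6.0, k=k, gap=100.0, u_bg=-0.2)
    if stabilization == "hebbian_only":
        return LearningSetup(cfg, PiecewiseLinearTF(), proto, hebbian, None, sigma=sigma)
    if stabilization == "normalization":
        # normalization conserves each row sum at C = 3; inhibition is
        # raised so the homogeneous all-active state is not self-
        # sustaining (C - w_I < 1) while concentrated assemblies are,
        # which keeps the synaptic dynamics in the fluctuating regime
        rng = np.random.default_rng(12345)
        W0 = rng.uniform(0.5, 1.5, size=(n, n))
        W0 *= 3.0 / W0.sum(axis=1, keepdims=True)
        cfg_norm = NetworkConfig(n=n, w_I=2.5)
        return LearningSetup(
            cfg_norm, PiecewiseLinearTF(), proto, hebbian, None,
            normalize=True, sigma=sigma, W0=W0,
        )
    if stabilization == "homeostatic":
        return LearningSetup(cfg, PiecewiseLinearTF(), proto, hebbian, homeo, sigma=sigma)
    raise ValueError(f"unknown stabilization {stabilization!r}")


def noise_robustness_suite(
    presets: Mapping[str, LearningSetup] | Iterable[str],
    sigma: float = 0.3,
    seeds: Iterable[int] = (0, 1, 2, 3, 4),
    settings: ClassifierSettings = ClassifierSettings(),
    **preset_kwargs,
):
    """Learned retrieval labels per (preset, seed) under input noise.

    Returns a DataFrame with one row per run and the per-preset majority
    label.  With at least 3 seeds the majority is well-defined up to
    ties, which are reported as the lexicographically first label.
    """
    import pandas as pd

    seeds = list(seeds)
    if len(seeds) < 3:
        raise ValueError("need at least 3 seeds for a majority label")
    if not isinstance(presets, Mapping):
        presets = {
            name: make_preset(name, sigma=sigma, **preset_kwargs) for name in presets
        }
    rows = []
    for name, setup in presets.items():
        for seed in seeds:
            rec = setup.run(seed=seed)
            label = retrieval_probe(
                setup.cfg, rec.W_effective, setup.tf, settings, dt=setup.dt
            )
            rows.append(
                {
                    "preset": name,
                    "seed": seed,
                    "sigma": setup.sigma,
                    "label": label.label.value,
                    "wbar": rec.rep_end[-1, 0] if rec.rep_end.size else 0.0,
                    "sbar": rec.rep_end[-1, 1] if rec.rep_end.size else 0.0,
                }
            )
    df = pd.DataFrame(rows)
    majority = (
        df.groupby("preset")["label"]
        .agg(lambda x: x.value_counts().sort_index().idxmax())
        .rename("majority")
    )
    return df.merge(majority, on="preset")
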