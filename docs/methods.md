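# Methods

## Model

The network is a chain of `n` excitatory populations described by
current-based rate equations.  Population `i` carries a synaptic
current `u_i` with time constant `tau` (default 10 ms; all times in
ms); its rate is `r_i = phi(u_i)`.  Three transfer-function families
are provided, all normalized by default so that rates read as fractions
of the maximum rate: a tanh sigmoid (gain `a = 4`, offset `b = -0.5`),
a threshold-linear function with saturation (slope 1, threshold 0,
saturation current 1 — the analytically tractable default used
throughout), and a supralinear/square-root form typical of neurons near
a saddle-node bifurcation to firing (unbounded; relative thresholds are
normalized by the rate at twice the crossover current).

Connectivity has two motifs: recurrent self-coupling `w` and
feedforward coupling `s` from population `i` to `i+1` (population 0
receives none).  Inhibition is either an explicit linear population
with time constant `tau_I` driven by the summed excitatory rates
(`full_inhibition`), or its instantaneous limit, a uniform subtractive
term `(w_I/n) sum_j phi(u_j)` with `w_I = n w_EI w_IE`
(`reduced_inhibition`).  The reduction is validated in the test suite:
regime labels agree with the full model on an (s, w) sample for
`tau_I` up to `0.5 tau`, and peak rates differ by under 10% at
`tau_I = 0.1 tau`.

Integration is forward Euler (Euler–Maruyama when current noise is on)
with default step `dt = 0.1` ms for plain dynamics and 0.5 ms for the
long learning runs; `dt <= tau/10` is enforced, first-order convergence
is tested, and currents beyond 1e6 abort with the blow-up time
(runaway detection).  Noise enters the current update as
`sigma * sqrt(dt/tau) * xi` with standard normal `xi` per population
per step, so the stationary current fluctuation is `sigma/sqrt(2)` and
`sigma` is interpretable as the amplitude of a white input-current
noise.

## Regime classification and the bifurcation diagram

The canonical probe initializes population 0 at the active current (the
transfer function's reference current, i.e. saturation for the
piecewise linear family) with all others silent and no input, and
integrates for `50 n tau`.  A population is *active* when its rate
exceeds `alpha = 0.5` of the reference maximum rate.  Labels:

* **PA** — at least one population active at the settled end state,
  without any population having switched off along the way (monotone
  recruitment, including the all-active fixed point of strong purely
  excitatory networks, counts as a fixed point, not a sequence);
* **SA** — the activity wave reached the last population and everything
  then fell silent;
* **dSA** — the wave died before the end of the chain;
* **SA/PA** — the wave reached the end and a persistent block remains,
  with at least one population having been transiently active.

Settledness requires `|du/dt| < 1e-5` rate-units/ms over a terminal
window of `20 tau`.  Grid scans step every (s, w) point in lockstep as
one vectorized batch with early termination once all points settle;
batched and single-trajectory classification are tested to agree.

For the piecewise linear transfer function the boundaries are analytic.
With `g = w_I/n`, a saturated block of `p` populations persists iff
`w >= 1/nu + g p` and blocks its successor iff `s <= g p`, giving the
critical feedforward strength `s_c = g ceil((w - 1/nu - g)/g)` between
PA and SA/PA, the equivalent critical recurrent strength (reported both
as the raw staircase value and as an offset from the PA base line
`w = 1/nu + g`, which is the form the simulations confirm), and the
`n(n+1)/2` PA sub-squares of side `g` whose lattice indices
`(floor(s/g), floor((w-1/nu)/g))` bracket the number of co-active
populations at the fixed point.

The SA-vs-dSA boundary is the wave-propagation threshold.  Its
asymptotic form is `w + s = 1/nu`, but at finite `n` a wave with
near-marginal amplification dies against the `alpha` threshold before
reaching the last population, so the package predicts propagation from
the *sub-saturation reduced model*: the rectified linear chain
`tau du_i/dt = -u_i + w nu [u_i]+ + s nu [u_{i-1}]+ - g nu sum_j [u_j]+`
integrated with RK4 (a method independent of the production
forward-Euler path), asking whether the last population's peak exceeds
`alpha`.  With this predictor a 30x30 scan at `n = 10`, `w_I = 1`
matches the analytic label field with zero mismatches outside
boundary-adjacent cells.

Burst-width scaling: along a sequence, the linearized solution is a
gamma-shaped pulse whose width grows as the square root of the position
index.  The width is measured as the time above half of each
population's own peak rate, which removes the exponential amplitude
trend of the sub-saturation chain (in the saturated regime peaks are
clamped, so this coincides with the fixed half-maximum threshold).
Populations at the end of the chain are excluded from the fit: with no
successor to recruit inhibition against them their bursts are
boundary-inflated.  Measured exponents: 0.50 for the sub-saturation
excitatory chain (w = 0.3, s = 0.75, n = 40), 0.03 with global
inhibition (w = 0.5, s = 1.2, w_I = 3) — constant burst widths.

## Plasticity

The excitatory-to-excitatory matrix (the fast Hebbian variable `W`)
relaxes toward a separable target,
`dW_ij/dt = (w_max f[r_i(t)] g[r_j(t - D)] - W_ij)/tau_w`, with
logistic drives `f, g` (gain 10, midpoint 0.5 of the maximum rate).
The delay `D` applies to the pre-synaptic rate only, making the rule
order-selective.  `tau_w` is infinite — weights frozen — when both the
post rate and the delayed pre rate are below `r_w = 0.4`, and equals
`T_w` otherwise; this both prevents background forgetting and produces
LTD whenever one partner is active and the other is not (target near
zero).  The delayed rate is read from a ring buffer at resolution `dt`
with linear interpolation, pre-filled with the initial rates.

Stabilization mechanisms:

* **Synaptic normalization** subtracts each row's mean update from all
  entries of the row at every step, conserving each population's total
  incoming weight to machine precision.  Weights are deliberately not
  clipped under normalization (clipping would break the conservation
  law); the weight-bound invariant `W in [0, w_max]` holds for the
  plain Hebbian rule.
* **Generalized homeostatic scaling**: effective weights are
  `H_i W_ij` with `tau_H dH_i/dt = (1 - r_i/r_0) H_i - H_i^2`, clipped
  at 0.  At sustained high rates H collapses toward 0 (masking); at
  rest the quadratic term gives logistic recovery to `H = 1`
  (unmasking), which takes about `4.4 tau_H` from `H = 0.1` — hence
  masking depth must not be extreme if H is to recover within a
  `5 tau_H` relaxation window.  Inhibition is never scaled.

Within a coupled step the order is: rates, current update, Hebbian
update (optionally normalized), homeostatic update.

## Learning experiments and calibration

Sequential stimulation drives populations one at a time (duration `T`,
gap `Delta`, amplitude `I_amp`, `k` repetitions separated by a 100 ms
within-training gap — long relative to the fast dynamics, negligible
relative to `tau_H`, so H stays masked across repetitions; full H
recovery happens only in the final relaxation, `5 tau_H` by default).
Timing relative to `D` selects the growing motif: recurrent weights
need the post window `[0, T + tail]` to overlap the delayed pre window
(`T >~ D`), feedforward weights need the successor's window starting at
`T + Delta` to overlap it (`Delta <~ D`).  The `tail` is the time the
decaying rate stays above the sigmoid midpoints, `~tau ln(u_end/0.5)` —
several ms — which shifts the effective quadrant boundaries relative to
the bare inequalities.

Default learning parameters were set by scanning the reduced map (below)
over `(I_amp, D)` so that the four study timings land in their four
regimes, then verified by full simulation: `w_max = 3`, `w_I = 1`,
`D = 12`, `I_amp = 6`, `r_w = 0.4`, `r_0 = 0.08`, `a = 10`, `b = 0.5`.
`D = 12` ms is consistent with the rise time of NMDA-mediated calcium
transients that motivates the delay.  The preset timings `(T, Delta)` =
(7, 14), (50, 40), (5, 15), (22, 8.5) learn SA, PA, dSA (no effective
learning), and SA/PA respectively.

A constant background current `u_bg = -0.2` (a resting drive slightly
below the firing threshold) is applied throughout learning runs.  Its
role is to keep *noise-driven* spontaneous rates (~0.01 of max) far
below the homeostatic set point `r_0`; with a zero-threshold resting
point, half-Gaussian noise rates would be comparable to the training-
average rate and the homeostat could not distinguish stimulation from
rest, blocking recovery.  Noise is applied while the stimulation
protocol runs; the final relaxation is quiet, so retrieval assesses the
learned connectivity rather than the noise-reactivation balance (the
learned weights under noise match the noise-free values within ~5%).

Two slow time constants are run desk-scale in the presets, tests and
acceptance script: `T_w = 500` ms and `tau_H = 3000` ms (the model's
nominal values, 2000 ms and ~minutes, preserve the same ordering
`tau << T_w << tau_H` and are the package defaults for the plain
parameter classes).  This shortens convergence from hundreds to tens of
repetitions without changing which regime is learned; convergence is
declared when per-repetition changes of the mean weights stay below
`1e-3 w_max` for 3 consecutive repetitions.

The runaway experiment (Hebbian only, both-grow timing) saturates the
mean weight at `>= 0.99 w_max` and retrieves an all-active fixed point;
with the saturating transfer function currents stay bounded, so the
instability appears as weight saturation rather than numeric overflow.
The normalization experiment uses seeded random initial weights with
row sums `C = 3` and stronger inhibition `w_I = 2.5`, chosen so the
homogeneous all-active state is *not* self-sustaining (`C - w_I < 1`)
while concentrated assemblies are; outside this regime the run falls
into a uniform absorbing state in which normalization exactly cancels
the spatially uniform updates.  Inside it, the weights fluctuate
indefinitely (row sums conserved to 1e-13, no convergence), reproducing
the failure of normalization to stabilize learning.

## The reduced learning map

With homeostatic masking, the net recurrent input during training is
small and each population's response is nearly decoupled: an
exponential approach of its current to `u_bg + I_amp` during its
stimulus and an exponential decay back to `u_bg` afterwards.  When
global inhibition is present, the (unmasked) self-inhibition term
`-(w_I/n) phi(u)` is retained and the single-population trajectory is
integrated with RK4 at the quadrature step (0.05 ms); omitting it
shifts the thin plasticity windows of short stimuli by enough to
misestimate their increments by tens of percent.

One presentation acts affinely on each mean weight (the Hebbian ODE is
linear in `W` given the rate trajectories), so the per-presentation map
`(w_k, s_k) -> (w_{k+1}, s_{k+1})` is evaluated exactly from two
quadratures per pair — the recurrent pair (own rate vs own delayed
rate) and the feedforward pair (successor's rate vs own delayed rate) —
and iterated to its fixed point.  Locating the fixed point in the
analytic bifurcation diagram predicts the learned regime.  Regime of
validity: total masking during stimulation; agreement with the full
simulation is within 15% per presentation for the first five
presentations and the predicted regime matches simulated retrieval on
all four presets.

## What the experiments do and do not show

All learning experiments use `n = 10` populations, the normalized
piecewise linear transfer function, and the desk-scale time constants
above; classification thresholds are relative to the maximum rate.  The
synthetic protocols emulate clean sequential stimulation with optional
white current noise; they do not include heterogeneous population
sizes, distance-dependent or random connectivity, conduction delays,
multiple interfering sequences, spiking variability, or plasticity of
inhibitory synapses.  Finite-size effects are real and quantified: at
`n = 10` the SA/dSA boundary sits visibly above its asymptotic
`w + s = 1/nu` line, which is why the propagation predictor is the
finite-chain reduced model.  The background state of the model is
exactly zero rate — a simplification of the threshold-linear transfer
function — so "background-rate" quantities like `r_0` are set points of
the homeostatic rule, not observed spontaneous rates.
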