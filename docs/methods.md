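# Methods

## The modelling problem

The rapid delayed-rectifier potassium current I_Kr, carried by the hERG
channel, is classically modelled with a Hodgkin–Huxley structure: an
activation gate `a` and an inactivation gate `r`, each an independent
two-state process with open probability governed by

    dx/dt = α(V)(1 − x) − β(V) x,      α = A_α e^{B_α V},  β = A_β e^{B_β V},

and an Ohmic observation model

    I = g · a · r · (V − E),           E = (RT/zF) ln([K]_out/[K]_in).

For hERG, inactivation is fast and comparatively well described by this
structure, while activation is slow and structurally misspecified: real
channels pass through multiple closed conformations, so tail currents decay
with more than one time constant — something a single first-order linear
gate cannot produce. `ionode` treats the inactivation gate and the Ohmic
map as trusted, and replaces or corrects the activation right-hand side
with a feedforward neural network:

* **NN-f** (full): `da/dt = N(a, V)` — the network is the entire gate law.
* **NN-d** (discrepancy): `da/dt = f_cand(a, V) + N(a, V)` — the network
  corrects a mechanistic candidate model and is near zero when the
  candidate is right.
* **rates**: `da/dt = N_α(V)(1 − a) − N_β(V) a` with softplus-positive
  network outputs — relaxes only the exponential-rate assumption, keeps
  mass-action structure and hence solutions in [0, 1].

## State-space estimation (training-data construction)

Only the current is observable in a voltage-clamp experiment. The
activation state and its derivative are recovered per sample:

1. `r(t)` and its analytic derivative come from integrating the trusted
   inactivation model over the protocol.
2. The measured current is smoothed with a univariate cubic smoothing
   spline fitted **separately on every constant-voltage segment** (a step
   discontinuity in V produces a jump in I that must not be smoothed
   over). The default smoothing factor is `n · σ̂²` per segment, with σ̂ a
   robust (MAD of first differences) noise estimate; `smoothing=0` gives
   an interpolating spline for noise-free data.
3. Algebraic inversion: `a = I_smooth / (g · r · (V − E))`.
4. Product rule at constant V: `da/dt = (1/r) (İ / (g(V−E)) − a ṙ)`.

Samples are masked invalid where the inversion is near-singular
(`|V − E| < v_min`, default 1 mV; `r < r_min`, default 1e-3), in the
capacitance-blanking window after each step (5 ms for real recordings, 0
for synthetic data), and within `edge_trim` samples of segment ends where
spline derivatives are least reliable. Estimates are flagged, never
clipped, when they leave [0, 1].

The surviving `(a, V, da/dt)` tuples are scaled by `(1, 100, 1/1000)` —
`a` unchanged, `V` in units of 100 mV, `da/dt` in units of 10⁻³ ms⁻¹ —
so every regression variable is O(1).

In the study pipeline the singularity guard is raised to `v_min = 10 mV`:
the inversion amplifies observation noise by `1/(g·r·(V−E))`, and with the
holding potential only ~4 mV from the reversal potential those samples
carry derivative noise an order of magnitude above the rest of the data
while adding little kinetic information.

## Training

Training is plain derivative regression: the mean-squared error between
the network output and the scaled derivative targets (for NN-d, targets
minus the candidate RHS) is minimised with Adam. There is no
backpropagation through the ODE solver; a trained network is only ever
integrated at prediction time. The network is a fully connected
leaky-ReLU (slope 0.01) multilayer perceptron; weights use a seeded
uniform fan-in initialisation, and training is deterministic given its
seed. `NetworkSpec` defaults to 5×200 hidden nodes; the study driver uses
3×64 with minibatches of 2048 and 1200 epochs at learning rate 1e-3,
which fits the two-input gate surface to the same quality in a fraction
of the time. Decoupled (AdamW-style) weight decay is available as an
optimiser option and defaults to off; plateau early-stopping (relative
improvement < 1e-4 over 200 epochs) is on by default.

### Evaluation-time safeguards

A trained network is only trusted inside the `(a, V)` box its training
tuples covered (`input_range`, stored in the checkpoint):

* network inputs are clamped to the box — the network is held at its
  boundary value outside it;
* in `full` mode a linear restoring term (rate 0.1 ms⁻¹) pulls the state
  back toward the trained a-range. Without it, a positive derivative
  residual at the box edge has nothing opposing it and integrates into
  unbounded drift (occasionally outright solver divergence, depending on
  the initialisation seed). NN-d needs no such term: its mechanistic part
  already restores the state; `rates` mode is bounded by construction.

The steady state of a neural gate at a holding voltage is the bracketed
root of its RHS in [0, 1] (Brent's method on a sign change over a
101-point grid); when no bracket exists, a 10 s constant-voltage
relaxation is used instead and a warning is issued.

## Simulation

All gate ODEs are integrated with the adaptive Dormand–Prince 4(5) pair
(scipy `RK45`), `atol = 1e-6`, `rtol = 1e-8`, restarted at every voltage
step so the stepper never straddles a discontinuity of the driving term.
Output is sampled on a uniform grid (default 1 ms). On sampled
(time-varying) protocols the step size is additionally capped at the
sampling interval so no waveform feature is skipped. For two-state HH
gates on step protocols the exact per-segment closed form
`x∞ + (x0 − x∞) e^{−t/τ}` is available (`simulate_current_analytic`) and
serves as the fitting inner loop, where it removes all solver error from
the objective.

Observation noise is i.i.d. Gaussian on the current only (never the
states); the synthetic study default is SD 0.1 nA, for which a perfect
model scores a mean absolute error of `0.1·√(2/π) ≈ 0.0798 nA` against
its own noisy trace (half-normal mean) — the study's noise floor.

## The synthetic study

The study emulates a voltage-clamp characterisation of hERG activation
at T = 294.55 K with [K]_out = 4 mM, [K]_in = 110 mM (E ≈ −84.1 mV),
g = 1 μS, holding at −80 mV, 1 ms sampling:

* **Generator.** Either a three-state activation chain C1⇌C2⇌O (ground
  truth, with model discrepancy relative to the candidate) or the
  candidate itself (no-discrepancy control). Both share the same
  inactivation gate. The shipped ground-truth parameters make the
  C1⇌C2 pair identical to the candidate's activation rates (slow,
  seconds-scale) and the C2⇌O pair fast (τ ≈ 100 ms at −40 mV;
  eigen-time-constant ratio 38 at −40 mV). Two consequences, both
  deliberate: tail currents are decisively two-exponential (a
  one-exponential fit leaves ~24% relative residual where two leave
  <10⁻⁶), and the fast process quasi-equilibrates, so the effective
  one-state derivative surface is strongly **nonlinear in a but close to
  single-valued** — the regime in which a learned one-state gate can
  genuinely absorb the missing dynamics. (With a slow second process the
  surface becomes multivalued and no one-state model of any kind can
  track it.)
* **Protocols.** Parameterised surrogates of the classical protocol
  suite: `pr3_like` (activation steady-state: 6 test steps −60..+40 mV,
  3 s, each followed by a −40 mV tail), `pr5_like` (deactivation: +40 mV
  activation then 4 s tails at −120..−40 mV), `pr4_like` (inactivation:
  brief 50 ms probes after full activation — deliberately sparse coverage
  of the low-V deactivation region), a three-sinusoid waveform and an
  action-potential series. Exact published waveforms can be loaded from
  CSV instead; the surrogates exist so the whole study runs from source
  with no downloads.
* **Pipeline.** Simulate generator → add noise (per-protocol derived
  seeds from one master seed) → fit the candidate's 8 kinetic parameters
  + conductance by seeded multi-start least squares (A's on log10 scale,
  B's untransformed, bounds A ∈ [10⁻⁷, 10³] ms⁻¹, B ∈ [−1, 1] mV⁻¹) →
  state-space estimation with the shared trusted r gate and known g →
  train NN-f and NN-d → score every model on every protocol by mean
  absolute error against the noisy data (all samples; synthetic data has
  no capacitance artifact) → coverage diagnostics.
* **Coverage / extrapolation.** Trajectories in the (a, V) plane are
  histogrammed on a 50×50 grid over a ∈ [0,1], V ∈ [−140, 60] mV; the
  extrapolation fraction of a prediction is the share of its points whose
  bin has no occupied training bin within one bin's radius. Training on
  the activation+inactivation pair (pr3+pr4) leaves the deactivation
  branch uncovered, and the NN-f trained on it degrades exactly where
  those predictions extrapolate — the cautionary failure mode.

## What the synthetic data do and do not show

The generator reproduces the statistical structure the method needs —
slow/fast gating, step-protocol dynamics, additive white observation
noise, a controlled structural misspecification — but not experimental
artifacts (series-resistance and capacitance residuals, leak, drift),
non-white noise, or the exact published protocol waveforms and
supplementary parameter values. Passing the study therefore demonstrates
the estimation/training machinery and the qualitative claims (neural
gates capture the missing two-time-constant dynamics; they fail when
trained on protocols with poor state-space coverage); it does not certify
performance on real patch-clamp recordings, and the absolute MAE values
are not comparable with those obtained on the archived experimental data.

## Numerical choices and degenerate inputs

* Segment boundaries follow a half-open [start, end) convention
  everywhere (protocol lookup, spline segmentation, masking), so a
  boundary sample belongs to the new step and is never double-counted.
* Spline fitting requires ≥ 5 usable samples per segment; shorter
  segments are skipped with a warning and their samples masked.
* `three_state_steady_state` uses detailed balance along the chain
  (exact for a birth–death structure) and raises on a degenerate (zero
  backward rate) chain.
* Candidate fitting never returns a point worse than its initial guess;
  with all starts failed it raises rather than returning garbage.
* Training aborts on a non-finite loss rather than continuing silently.

## Known limitations

* One neural state only: dynamics requiring a genuinely multivalued
  one-state surface (slow hidden processes) are out of reach by
  construction; the package deliberately does not implement higher-order
  neural gates.
* Training uses step protocols only; time-varying segments are excluded
  from estimation (dV/dt ≠ 0 breaks the constant-V product rule, and
  condensed protocols cover the state space poorly anyway).
* The candidate fit is a local multi-start least squares, not a global
  or Bayesian method; with strongly discrepant data different starts can
  settle in different compromises (the study uses seeded starts for
  reproducibility).
* MAE values depend on the surrogate protocol suite and shipped default
  parameters; swap in archived protocols/parameters via the CSV/JSON
  loaders for like-for-like comparisons with published tables.
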