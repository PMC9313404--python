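# Methods

## The neural mass model

The simulator implements a Wendling-type lumped model of the hippocampal
circuit: a pyramidal population, an excitatory interneuron loop, and slow
(GABA_A,slow) and fast (GABA_A,fast) inhibitory interneuron populations.
Each synaptic pathway is a critically damped second-order filter
`h(t) = W w t e^{-wt}` with gain/rate pairs (A, a) for excitation, (B, b)
for slow inhibition and (G, g) for fast inhibition; each population's
potential-to-rate conversion is the sigmoid
`S(v) = 2 e_s / (1 + exp(h_s (v_s − v)))`.

State components: x1–x5 are postsynaptic potentials (mV), x6–x10 their
derivatives, and x11 the state of a first-order recorder stage. The
pyramidal potential is `z = x2 − x3 − x4`; the simulated EEG is
`y = C_S · x11`, where x11 realizes the high-pass `s/(s + 0.5)` applied to
z. The filter state is driven by the *derivative* combination
`x7 − x8 − x9`, which is the form that actually realizes a DC-blocking
transfer function and makes y decay to zero at every equilibrium; the
alternative (driving it with z itself) would realize a leaky integrator
instead. The fast-interneuron drive is `S(C5·x1 − C6·x5)`: fast
interneurons are excited by pyramidal feedback and inhibited by the slow
interneurons. With the plus sign the model's fold structure moves to
B/A ≈ 6.1/8.2, inconsistent with the bifurcation landmarks this model is
known for (see below), which pins down the minus sign.

### Constants

Defaults are the standard parameterization of this model family:
e_s = 2.5 s⁻¹, h_s = 0.56 mV⁻¹, v_s = 6 mV; a = 100, b = 50, g = 500 s⁻¹;
C = 135 with C1 = C, C2 = 0.8C, C3 = C4 = 0.25C, C5 = 0.3C, C6 = 0.1C,
C7 = 0.8C; output scale C_S = 1. The afferent pulse density u1 is drawn
per integration step as N(90, 30²) s⁻¹. Two checks validate this set: the
equilibrium structure reproduces the Andronov–Hopf point at B/A = 2.478
and the folds at 7.824 and 12.897 (A = 5, G = 10), and the five preset
regimes produce the expected activity morphologies. All constants are
config-exposed (`ModelParameters`, YAML round trip in `epikf.io`).

### Integration

Stochastic Euler at an internal step of 1/4800 s, decimated to the
analysis rate of 480 Hz (so a 5-s window has N = 2400 samples, matching
the sample-entropy setting). A 2-s burn-in is discarded. Trajectory-level
convergence (halving the step changes z by ≈ 0.1 % relative RMS) is
verified in the stable noise-driven regime; in limit-cycle regimes a
trajectory-wise comparison is ill-posed — O(dt) phase error accumulates
secularly — so those regimes are validated through equilibrium consistency
and the limit-cycle envelope instead. Trajectories exceeding |x| = 1e6
(physiological range is tens of mV) raise an integration error naming the
step.

### Activity-type presets

B/A = 3, 4, 6, 8, 10 for Types I–IV and Normal at A = 5 (the three-band
variant replicates them at A = 4, 5, 6). These place Type I just above the
Hopf point, II–III inside the limit-cycle range, IV slightly above the
saddle-node fold where input noise causes irregular escape spiking, and
Normal far enough beyond the fold that noise rarely lifts the state out of
the stable node's basin.

## The square-root cubature Kalman filter

The estimator augments the state with x12 = B(t) (zero drift; process
noise makes it a random walk) and discretizes the augmented dynamics with
one explicit Euler step per measurement sample at the segment's own rate —
deliberately the same coarse discretization a real-time implementation
would use, while the simulator integrates ten times finer; the
process-noise model absorbs the mismatch. Euler at T = 1/480 s is stable
for all model modes (the fastest pole, −g = −500 s⁻¹, gives |1 + λT| ≈
0.96).

Gaussian integrals use the 2n third-degree cubature points ±√n·eᵢ with
equal weights. The covariance is propagated as a lower-triangular factor
via QR triangularization; centered deviation matrices are scaled by 1/√m
(not 1/m), which is the scaling under which χχᵀ reproduces the
1/m-weighted sample covariance — verified against an independently coded
full-covariance cubature filter (agreement to 1e-9 relative Frobenius norm
over 50 steps) and against the textbook Kalman recursion on a linear
system (1e-10). The Kalman gain is formed by two triangular solves against
the innovation factor; a diagonal element below 1e-12 raises a
conditioning error rather than silently regularizing.

### Observation model

Two observation maps are provided: `y`-mode observes the recorder output
C_S·x11 (AC-coupled EEG) and `z`-mode observes x2 − x3 − x4 directly
(DC-preserved output). `FilterConfig.for_segment` picks the map from the
segment kind, so estimates on z-segments use the DC information — the
condition under which the ratio is identifiable.

### Noise model, initialization, constraint

No canonical values exist for Q, R, the initial state or the constraint
in this estimator family, so these are engineering defaults, all
config-exposed:

* Q diagonal: 1e-8 on x1..x11 (the dynamics are trusted), 1e-2 mV²/step on
  x12 (fast enough to track a changing gain within a segment).
* R = 1e-2 mV² — loose enough to tolerate the discretization mismatch,
  tight enough to lock onto the oscillation.
* x̂₀ = 0 for x1..x11; x12 starts at the midpoint of its feasible
  interval; S₀ = I (mV scale). The per-segment summary uses only the
  second half of the trace, so initialization details wash out.
* Constraint: x12 is clipped to [0, 100] mV after every measurement
  update. Clipping is the cheapest projection consistent with a
  "constrained" filter and is isolated in `apply_constraint` so a
  covariance-aware projection could be swapped in. The upper bound is set
  at 100 rather than tighter values because AC-coupled Type I segments
  legitimately drive the estimate to B/A ≈ 15–19 (x12 ≈ 75–95); a tighter
  bound would pin the upper cluster at the clip and hide the split
  phenomenon rather than express it.

The per-segment summary `I_B/A` is the mean of x12/A over the final half
of the trace; among the candidate summaries (mean, median, terminal
value) the post-burn-in mean is the least noisy and is the adopted
convention.

## Severity indicators

* **Band power**: Welch PSD (1-s Hann windows, 50 % overlap) integrated
  over 4–50 Hz, reported as log10 — group band-power values in this
  literature are negative, which identifies the log scale; a linear
  accessor is kept. A periodogram option is config-exposed.
* **Teager energy**: the printed operator
  `(1/N) Σ_{k=4}^{N+3} (x[k−1]x[k−2] − x[k]x[k−3])` (1-based) is
  implemented literally, although it differs from the textbook
  Teager–Kaiser form; for a sinusoid its phase-averaged value is
  `0.5 A² (cos ω − cos 3ω)`, used as the closed-form oracle. Non-positive
  averages are flagged, not logged.
* **Sample entropy**: SEn = ln(B_m/A_{m+1}) with m = 4, r = 0.1·SD,
  N = 2400, Chebyshev distance, self-matches excluded, both counts over
  the same N − m templates (so the ratio is a conditional probability).
  The vectorized counts equal an exhaustive-pair oracle exactly.
  White noise at these settings frequently has *no* length-5 template
  matches — a flagged degenerate result; EEG-like (band-limited) signals
  do not hit this.

Degenerate inputs (flat segments, zero band power, empty template counts)
return flagged NaNs rather than infinities.

## Bifurcation analysis

At the deterministic input mean, every state component at equilibrium is
an explicit function of the pyramidal potential v, so fixed points are the
roots of a scalar residual — bracketed on a 4001-point grid over
[−60, 60] mV and polished by Brent's method to ~1e-13, giving residual
norms below 1e-8 in the full vector field. Stability comes from the
analytic 11×11 Jacobian (the recorder state contributes one fixed −0.5
eigenvalue and cannot affect the detected events).

Continuation is a plain parameter sweep over B/A with per-ratio root
finding; the branch has a simple fold pair, so pseudo-arclength machinery
is unnecessary. Folds are detected as equilibrium-count changes and
refined by bisection to |ΔB/A| < 1e-4; a fold is labelled SN if the
merging pair (the two closest roots on the many-root side) contains a
stable point and SS if both are unstable. Hopf points are detected where
the real part of the leading complex pair crosses zero along a
count-preserving stretch of a branch *and* the point's stability actually
changes — the second condition rejects spurious events where a complex
pair merely turns real near a fold. Supercriticality is not established
via the first Lyapunov coefficient; it is confirmed numerically by the
small-amplitude onset of the limit-cycle envelope just above the Hopf
point.

The limit-cycle envelope is simulation-based (noise off, 10 s per ratio
with 5 s discarded, extrema of z, initial condition perturbed 1e-3 off the
lowest equilibrium); it approximates the cycle extrema without Floquet
analysis and is not a continuation of the periodic branch.

## Signal pipeline

* **Artifact filter**: Parks–McClellan equiripple, order 209 at 3840 Hz,
  bands 0–50 / 100–1920 Hz. Band weights are set from the target ripples
  (δ_p from 0.1 dB, δ_s from 60 dB), then a short deterministic walk over
  extra stopband emphasis (×1.2, ×1.5, …) accepts the first design whose
  measured response clears both targets — order 209 sits exactly at the
  edge of feasibility for this transition width, and equal-budget
  weighting alone lands ~0.15 dB short in the stopband while leaving
  unused passband slack.
* **Stimulation waveforms**: RPS is a 128 Hz biphasic train (+458.5 μA ×
  781.25 μs / −50.94 μA × 7031.25 μs; phase durations exactly fill the
  period) built by epsilon-guarded phase comparison so samples landing
  exactly on a phase boundary classify deterministically at any rate; the
  printed phase products balance charge to 0.009 %. RNS is white noise
  FIR-bandpassed to 101–640 Hz and rescaled so the extremes are ±500 μA.
  Sham waveforms are the same shapes at 1 % height.
* **Segmentation** is non-overlapping 5-s windows (discrete
  before/during/after windows need no overlap); a trailing partial window
  is dropped. When recordings at other rates are analyzed, indicators
  resample to 480 Hz (polyphase, anti-aliased) so N = 2400 covers the full
  window; the artifact filter, when enabled, is applied to the continuous
  record before segmentation.
* **Outlier rule**: values outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR] with
  linearly interpolated quartiles (the numpy default; documented because
  exclusion counts depend on the convention). Groups smaller than 4 pass
  through with a warning. Summaries are mean ± sample SD (ddof = 1) after
  exclusion.

## What the synthetic data does and does not show

The generator produces exactly the study conditions the estimator is
designed for: single-channel, stationary-parameter segments from the same
model family the filter assumes, with per-step Gaussian input noise.
Passing tests therefore demonstrate *internal* consistency — that the
filter recovers the generating ratio when the model is right and the DC
component is observed — and the observability failure on AC-coupled
output. They do not demonstrate robustness to model mismatch, electrode
artifacts, nonstationary gains within a segment, or multi-channel volume
conduction, all of which real recordings add. Experimental group
statistics from animal recordings are out of scope (the recordings are not
distributable); the filter-vs-oracle equivalences stand in as the
verifiable counterpart.

## Problem sizes

Default test and demonstration sizes: 10 segments per regime for recovery
checks (the full 50-segment experiment runs in the acceptance script),
30 segments for the bimodality check, 1000-point continuation sweeps, and
50-step runs for the square-root/plain-filter equivalence. These sizes
give comfortably resolvable effects (e.g. the recovery means land within
±0.05 of the target ratios) while keeping a full run of everything within
a few minutes on one core.
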