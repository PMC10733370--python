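# Methods

This note documents the models implemented in `okrcircuit`, the tunable
parameters and their defaults, what the synthetic generators do and do not
emulate, and the numerical choices made where the procedure was genuinely
open.

## OKR gain

Eye position is sampled uniformly (default 100 Hz, the frame rate of the
video-oculography it emulates). Saccade-like fast movements are detected on
the central-difference velocity with a threshold of **25 °/s** (±2 samples
padding). The threshold is configurable; 25 °/s sits an order of magnitude
above the peak slow-phase velocity of the standard stimulus
(2π · 0.4 Hz · 5° ≈ 12.6 °/s at gain 1) and well below step velocities of
even small (≈1°) saccades at 100 Hz.

Flagged samples are removed in the *increment* domain: the per-sample
position differences touching a flagged sample are replaced by linear
interpolation between the flanking clean increments and the position is
re-integrated (anchored at the first clean sample, flat extrapolation at the
boundaries). This reconstructs the slow-phase trajectory: both the rapid
excursion and the persistent step displacement a saccade leaves behind are
removed, so only slow eye movements enter the gain. Interpolating flagged
*positions* instead would keep the post-saccade offset, which leaks into the
Fourier bin and inflates single-trial gain errors several-fold.

Amplitude extraction is a single-bin discrete Fourier projection at the
drum frequency, `(2/M)|Σ x e^{-iωt}|` after mean subtraction, over an
integer number of stimulus cycles (half-open window starting at stimulus
onset). Because the window holds whole cycles the projection is
leakage-free; the drum amplitude is computed by the identical projection of
the drum trajectory, so perfect tracking gives gain exactly 1 and a
constant eye exactly 0 (to round-off). Gain is invariant to DC offset and
to phase lag; a linear drift of d °/s leaks ≈ d/(πf) degrees into the bin
(0.04° at d = 0.05 °/s), negligible against the 5° drum.

Per-trial gains are the default; cycle-averaging is available by windowing.
Unidirectional (constant-speed) trials use the same desaccading operator —
nystagmus fast phases are saccades to it — and define gain as the fitted
slow-phase velocity over the drum speed.

## Calcium analysis

ΔF/F uses the mean fluorescence in the 1 s before stimulus onset as F₀ per
trial. The response amplitude of a trial is the mean ΔF/F over the 3-s
stimulation window; per stimulus, trials outside the Tukey fences
(Q1 − 1.5·IQR, Q3 + 1.5·IQR; type-7 linear-interpolation quartiles; fences
undefined below 4 trials, in which case nothing is removed) are dropped
before averaging. A neuron is responsive when its maximum trial-averaged
amplitude reaches 0.06 (the 6% criterion) *and* the preferred-stimulus
trial amplitudes exceed the blank-trial amplitudes in a one-sided
two-sample t-test at p < 0.05. With zero-variance (noise-free) inputs the
t-test is replaced by a direct mean comparison. Without blank trials the
flag is undetermined (`None`), not false, unless the amplitude gate already
fails.

Preferred orientation/direction follow the two-branch vector-sum rule:
neurons with OSI ≥ 0.1 take the half-argument of the doubled-angle sum and
then the stronger of the two directions along the nearest sampled
orientation; others take the argument of the plain direction sum snapped to
the nearest sampled direction. OSI is defined as |Σ R e^{2iρ}| / Σ R over
rectified responses — the global vector-sum magnitude, i.e. the quantity
whose argument the orientation estimate uses. Negative amplitudes are
clipped to zero inside vector sums (complex arguments are unstable under
sign flips) but kept signed in the DSI, whose denominator uses absolute
values for exactly that reason. SF/TF selectivity uses
(R_pref − R_base)/(R_pref + R_base) with R_base the mean of the two
smallest amplitudes.

Deconvolution inverts the exponential calcium kernel as an AR(1) recursion
(g = e^{−Δt/τ}, τ = 1.5 s for GCaMP6s) with truncation of negative
excursions; re-convolving the estimate reproduces a noise-free trace
exactly. A sparsity-regularized variant was deliberately not added: at the
noise levels and frame rates modelled here the exact inverse is already
consistent, and the model downstream only needs trial-averaged rate
time courses.

Spiking units: evoked rate is the stimulation-window rate minus the
spontaneous (pre-stimulus) rate at the best direction; responsiveness is a
one-sided paired t-test across trials at p < 0.01. Antidromic latency is
the first 0.5-ms PSTH bin whose pulse-aligned rate exceeds the spontaneous
mean by 3 spontaneous SDs (spontaneous statistics from identically binned
pre-pulse windows); jitter is the SD of the first post-pulse spike time.
The 0.5-ms bin is a default; the criterion is bin-resolution limited.

## Plasticity

PI = (R_post − R_pre)/(R_post + R_pre) and ΔR = (R_post − R_pre)/R_pre are
computed at a probe direction (temporo-nasal). They satisfy
PI = ΔR/(ΔR + 2) and share sign. Neurons enter the pre/post comparison only
if responsive in the *pre* session (pre-session gating avoids
regression-to-the-mean artifacts); grouping uses the pre-session sampled
preferred direction. Group plasticity strength is the group mean ± SEM of
ΔR; empty groups are reported missing, not zero.

ΔR is a ratio estimator: with noisy pre-session amplitudes its expectation
exceeds the true value by ≈ (1 + ΔR)·CV²(R_pre), a bias that does not
shrink with the number of neurons. It is small only when the probe response
is well above the noise floor in every group — which constrains the
synthetic world (below) and should be kept in mind with real data for
groups probed far from their preferred direction.

The potentiation-versus-plasticity line is fitted two ways: ordinary least
squares (the Gaussian maximum-likelihood line, closed form) and
minimum-vertical-distance, read as the L1 line (sum of absolute vertical
residuals) minimized by Nelder–Mead from the least-squares start — the
natural "vertical distance" objective that actually differs from least
squares. R² = 1 − SS_res/SS_tot is reported for whichever line was fitted.

## Feedforward model

The NOT-DTN is a single passive node: τ dI/dt = −I + Σ_b w_b u_b(t) with
τ = 3.9 ms (AMPA EPSC decay), uniform w = 0.005, N = 100 neurons split
into TN/UP/NT/DN groups by largest-remainder rounding of the composition
fractions. Group rate templates come from deconvolved responses to the
temporo-nasal probe, each neuron normalized **to its preferred-direction
response** (not its own trace peak — otherwise all templates collapse to
one shape and direction selectivity cannot influence the model), averaged
within group, scaled by one common factor so the group-size-weighted mean
of the post-onset mean rates equals the population mean rate (default
10 spikes/s), and baseline-subtracted. Plasticity multiplies a group's rate
by (1 + ΔR_g); negative post-baseline rates are passed through unmodified
(the ODE is linear; no rectification).

Integration uses the exact solution for piecewise-linear input per step
(default Δt = 0.5 ms ≤ τ/5), and the charge over the 3.5-s window from
stimulus onset is the per-step analytic integral of that solution, so both
current and charge are independent of the step size to round-off.
Trapezoidal charge was tried first and rejected: at Δt = τ/8 it deviates
from a 100×-finer reference by ~1.5 × 10⁻⁶ relative, violating the
refinement-invariance the model's identities are tested against.

Because the system is linear, ΔC = Σ_g s_g·ΔR_g exactly, where s_g is
group g's share of the pre-potentiation charge; `charge_shares` computes
these coefficients, and the scenario/sweep tests verify the identity, the
flat uniform-plasticity curve, the affine ΔC-vs-ΔR_TN sweep (slope = TN
charge share) and the monotone ΔC-vs-TN-fraction sweep numerically. In the
TN-fraction sweep the non-TN remainder is split proportionally to the
original non-TN fractions. The "swapped plasticity" scenario exchanges the
TN and NT strengths. The printed magnitudes of ΔC for the real populations
depend on recorded rate traces that are not available; only orderings
between scenarios are reproducible, and that is what is asserted.

## Population statistics

The direction-bias randomization test assigns the n observed neurons to the
k bins uniformly at random and uses the focal-bin count as the statistic;
the one-sided Monte-Carlo p-value is (1 + #{null ≥ observed})/(1 + M), with
floor 1/(M + 1). Under this null the statistic is Binomial(n, 1/k), which
is what is simulated and which supplies the exact tail as an oracle.
Neurons are pooled across animals (a within-animal permutation scheme would
need per-animal labels, which the inputs do not carry). Because the
statistic is discrete no exact 0.05 level exists; with n = 1000, k = 8 and
M = 10⁴ the exact type-I error at nominal 0.05 is 0.0455, which is the
configuration the calibration test uses (computed analytically before
implementation, not tuned).

Density maps count cells in fixed 100 µm squares (half-open membership —
boundary points belong to the higher square) and divide by the square area;
the default origin snaps to the grid multiple below the data minimum, so
grids are translation-equivariant under shifts by grid multiples.
Volumetric density is count/volume per labelled area. Ratios of aligned
grids are undefined (NaN + mask), not infinite, where the denominator is
empty. Surface projection of 3-D coordinates is an upstream step; the
package consumes projected 2-D positions.

## Synthetic world

Defaults state the emulated experiments: 100-Hz oculography of a ±5°,
0.4-Hz, 10-s drum; 10-Hz two-photon imaging with 1-s baseline, 3-s
stimulation and τ = 1.5 s kernel; 2-s grating trials for spiking units;
antidromic pulses at 4 Hz. Where the emulated studies state no value, one
realistic value was chosen and fixed:

- **Saccades**: Poisson-timed steps of 2° (resetting fast phases of
  head-fixed mice are a few degrees) with random sign, completed within 3
  samples — steps are the worst case for interpolation-based desaccading.
  Eye noise 0.05° SD, lag 50 ms.
- **Tuning shape**: double von Mises with lobes at the preferred direction
  and its opposite (height ratio `dir_null_ratio`), each lobe rescaled to
  vanish exactly 180° from its peak, so DSI = (1 − r)/(1 + r) in closed
  form. **Width 40°** (σ of the equivalent circular Gaussian): realistic
  for mouse V1 and, importantly, it keeps the orthogonal-direction response
  (~14% of peak) above the fluorescence noise floor — the precondition for
  the ΔR ratio estimator to be usable in every group. At 30° the
  orthogonal response (~2.5% of peak) sits at the noise level and ΔR
  averages for orthogonal groups become heavy-tailed and biased.
- **Plasticity** is multiplicative and direction-independent per neuron,
  with group-specific factors; the synthetic template bank uses a
  TN-enriched composition (37/21/21/21%) with factors
  (1.4, 1.1, 1.05, 1.1) for the corticofugal population and a flat,
  weakly selective (dir_null_ratio 0.6), uniformly weak (1.1) control
  population.
- **Fluorescence noise** is i.i.d. Gaussian per frame (default SD 0.02).

What a green test does *not* establish: the generators have no shared
(neuropil-like) noise, no bleaching or slow drift in F₀, no eye-position
dependence of visual responses, no adaptation across trials, no correlated
trial-to-trial variability, and eye traces have no pursuit-like smooth
deviations; saccades are pure steps. Recovery results quantify estimator
correctness under the stated model, not robustness to those real-data
features.

## Error handling conventions

Invalid parameters raise `InvalidParameterError`; degenerate analyses raise
specific errors (`DegenerateBaselineError` for F₀ ≤ 0, `UndefinedMetricError`
for 0/0 metrics, `UnusableTraceError` when every sample is saccadic,
`InsufficientDataError` below minimum trials/cycles/pulses,
`MissingGroupError` for absent direction groups). A motionless control gain
of exactly 0 raises `ZeroDivisionError` in the cortical-contribution ratio
rather than returning infinity.
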