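# okrcircuit

Quantitative pipeline for studying how visual cortex drives the brainstem
circuit of the horizontal optokinetic reflex (OKR): the corticofugal
projection from layer-5 pyramidal neurons of visual cortex to the nucleus of
the optic tract / dorsal terminal nucleus (NOT-DTN), and onward to the
inferior olive. The package is aimed at systems neuroscientists who want to
analyze eye-tracking behaviour, two-photon calcium imaging and extracellular
recordings from this pathway — or to test the analysis chain end to end on
synthetic data with known ground truth.

## What it computes

**OKR gain** (`oculography`). Saccade-like fast eye movements are detected
as surges in the velocity trace and excised by interpolating the position
increments (slow-phase reconstruction); the gain of an oscillatory-drum
trial is the Fourier amplitude ratio

```
gain = Amp_eye / Amp_drum
```

evaluated in a single frequency bin over an integer number of stimulus
cycles: 1 for perfect tracking, 0 for a motionless eye. Derived behavioural
metrics: cortical contribution ΔV(%) = 100·(V_control − V_silencing)/V_control
(trials enter summaries only when V_control ≥ 0.02) and OKR potentiation
(V_post − V_pre)/V_pre.

**Direction tuning** (`tuning`). ΔF/F = (F − F₀)/F₀ against a 1-s
pre-stimulus baseline; Tukey-fence outlier-trial removal; responsiveness
(max amplitude ≥ 6% and one-sided t-test against blank trials, p < 0.05);
preferred orientation/direction from response-weighted vector sums
(θ_pref = ½·arg Σ R·e^{2iρ}, ρ_pref = arg Σ R·e^{iρ});
DSI = (R_pref − R_null)/(|R_pref| + |R_null|); SF/TF selectivity; evoked
rates and antidromic latency/jitter for spiking units; exponential-kernel
calcium deconvolution (τ = 1.5 s, GCaMP6s).

**Plasticity** (`plasticity`). Per-neuron plasticity index
PI = (R_post − R_pre)/(R_post + R_pre) and strength
ΔR = (R_post − R_pre)/R_pre at a probe direction (temporo-nasal by
default), averaged per direction group; linear regression of behavioural
potentiation on mean PI by least squares or by minimum summed vertical
distance (L1).

**Feedforward model** (`circuit_model`). N = 100 cortical neurons in four
direction groups drive one NOT-DTN node through uniform weights w = 0.005;
the synaptic current obeys τ dI/dt = −I + Σ w·u(t) with τ = 3.9 ms, and the
charge C = ∫ I dt over 3.5 s from stimulus onset yields
ΔC = (C_post − C_pre)/C_pre under group-specific plasticity. Scenario
machinery swaps composition, response and plasticity sources between
populations and sweeps the temporo-nasal fraction or plasticity strength.

**Population statistics** (`popstats`). One-sided randomization test for an
excess of neurons preferring a focal direction (exact binomial tail as the
small-n oracle); volumetric densities and 100 µm × 100 µm area-density
grids with per-square density ratios.

**Synthetic data** (`synthetic`). Seeded generators for every input —
drum-tracking eye traces with gain, lag, drift, noise and step saccades;
direction-tuned calcium populations with group-specific multiplicative
plasticity; Poisson spiking units with antidromic responses; spatial point
clouds with area-dependent density. Every object carries its generative
parameters, so each estimator can be scored for recovery.

## Worked example

```python
import okrcircuit as oc

drum = oc.DrumStimulus()            # ±5 deg, 0.4 Hz, 10 s
spec = oc.SyntheticEyeSpec(true_gain=0.6, saccade_rate_hz=0.2,
                           noise_sd_deg=0.05, seed=1)
trace = oc.gen_eye_trace(drum, spec)
res = oc.okr_gain(trace, drum)
print(f"gain={res.gain:.3f} over {res.n_cycles_used} cycles, "
      f"{100 * res.saccade_fraction:.1f}% samples desaccaded")

bank = oc.circuit_model.synthetic_bank(seed=0)
dc = oc.run_scenario(oc.ScenarioSpec(), bank)
dc_mid = oc.run_scenario(oc.ScenarioSpec(composition_source="midbrain",
                                         response_source="midbrain",
                                         plasticity_source="midbrain"), bank)
print(f"charge increase: NOT-DTN-projecting {100 * dc:.1f}% "
      f"vs midbrain-projecting {100 * dc_mid:.1f}%")
```

prints

```
gain=0.599 over 4 cycles, 1.5% samples desaccaded
charge increase: NOT-DTN-projecting 32.3% vs midbrain-projecting 10.0%
```

The first line shows the Fourier-ratio gain recovering the generative gain
0.6 after two injected saccades were excised. The second line runs the
feedforward model on two synthetic populations built through the full
calcium pipeline: the temporo-nasally biased, strongly direction-selective,
TN-plastic population converts the same plasticity into a much larger
increase of synaptic charge than the unbiased control population.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the two analytic OKR-gain benchmarks from scratch — a synthetic
eye trajectory identical to the drum (perfect tracking) and a motionless
eye, both run through the complete saccade-removal + Fourier pipeline — and
writes the resulting gains to the JSON file.

See `docs/methods.md` for the models, parameter choices and limitations.
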