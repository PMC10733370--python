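"""Synthetic generators for every input the analysis consumes.

Each generator is seeded and stores its generative parameters on the object it
returns, so downstream estimators (OKR gain, preferred direction, plasticity
strength, antidromic latency, spatial density) can be scored for parameter
recovery.  With all noise terms at zero the generators are exact: every
analysis stage then has a closed-form expected output.

Emulated acquisition conditions: video-oculography at 100 Hz tracking a
+/-5 degree, 0.4 Hz oscillating drum; two-photon GCaMP6s calcium imaging at
10 Hz with a 1 s pre-stimulus baseline and 3 s drifting-grating stimulation;
extracellular units driven by 2 s gratings with optogenetic antidromic pulses;
cell coordinate maps with area-dependent density.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidParameterError

GROUPS_4DIR = ("TN", "UP", "NT", "DN")
#: sampled direction (degrees) represented by each 4-direction group;
#: 0 deg = temporo-nasal by convention.
GROUP_DIRECTIONS = {"TN": 0.0, "UP": 90.0, "NT": 180.0, "DN": 270.0}


# ---------------------------------------------------------------------------
# Drum stimulus
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DrumStimulus:
    """Parametric description of the grating drum driving the OKR.

    In ``oscillatory`` mode the drum angle follows ``A sin(2 pi f t)`` during
    the stimulation window; in ``unidirectional`` mode it ramps at the
    constant speed ``tf_hz / sf_cpd`` (deg/s), signed by ``direction_deg``
    (0 deg = temporo-nasal = positive).
    """

    mode: str = "oscillatory"
    amplitude_deg: float = 5.0
    oscillation_freq_hz: float = 0.4
    sf_cpd: float = 0.1
    duration_s: float = 10.0
    pre_s: float = 0.0
    post_s: float = 0.0
    direction_deg: float = 0.0
    tf_hz: float = 0.4

    def __post_init__(self) -> None:
        if self.mode not in ("oscillatory", "unidirectional"):
            raise InvalidParameterError(f"unknown drum mode {self.mode!r}")
        if self.duration_s <= 0:
            raise InvalidParameterError("duration_s must be positive")
        if self.mode == "oscillatory":
            if self.amplitude_deg <= 0:
                raise InvalidParameterError("amplitude_deg must be positive")
            if self.oscillation_freq_hz <= 0:
                raise InvalidParameterError("oscillation_freq_hz must be positive")
        if self.pre_s < 0 or self.post_s < 0:
            raise InvalidParameterError("padding must be non-negative")

    @property
    def total_s(self) -> float:
        return self.pre_s + self.duration_s + self.post_s

    @property
    def drift_speed_deg_per_s(self) -> float:
        """Constant drum speed in unidirectional mode (signed)."""
        sign = 1.0 if np.cos(np.deg2rad(self.direction_deg)) >= 0 else -1.0
        return sign * self.tf_hz / self.sf_cpd


def drum_position(stim: DrumStimulus, t: np.ndarray) -> np.ndarray:
    """Analytic drum angle (degrees) at arbitrary times ``t`` (seconds).

    Zero in the pre padding; in the post padding the unidirectional drum
    holds its final angle while the oscillatory drum returns to zero.
    """
    t = np.asarray(t, dtype=float)
    ts = np.clip(t - stim.pre_s, 0.0, stim.duration_s)
    if stim.mode == "oscillatory":
        pos = stim.amplitude_deg * np.sin(2 * np.pi * stim.oscillation_freq_hz * ts)
        pos = np.where((t - stim.pre_s) > stim.duration_s, 0.0, pos)
    else:
        pos = stim.drift_speed_deg_per_s * ts
    return pos


def gen_drum_trajectory(
    stim: DrumStimulus, sampling_rate_hz: float
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the drum trajectory on a uniform grid.

    Returns ``(time_s, position_deg)`` with
    ``round(total_s * rate) + 1`` samples.
    """
    if sampling_rate_hz <= 0:
        raise InvalidParameterError("sampling_rate_hz must be positive")
    n = int(round(stim.total_s * sampling_rate_hz)) + 1
    t = np.arange(n) / sampling_rate_hz
    return t, drum_position(stim, t)


# ---------------------------------------------------------------------------
# Eye traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticEyeSpec:
    """Generative parameters of a synthetic eye-position trace.

    ``true_gain`` scales the (lagged) drum trajectory; saccades are
    Poisson-timed steps of ``saccade_amp_deg`` with random sign, completed
    within 3 samples (30 ms at 100 Hz) and persisting afterwards, the way
    resetting fast phases displace the eye.
    """

    true_gain: float = 0.6
    lag_s: float = 0.05
    saccade_rate_hz: float = 0.2
    saccade_amp_deg: float = 2.0
    drift_deg_per_s: float = 0.0
    noise_sd_deg: float = 0.05
    sampling_rate_hz: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_gain < 0:
            raise InvalidParameterError("true_gain must be >= 0")
        if self.sampling_rate_hz <= 0:
            raise InvalidParameterError("sampling_rate_hz must be positive")
        if self.noise_sd_deg < 0 or self.saccade_rate_hz < 0:
            raise InvalidParameterError("noise and saccade rate must be >= 0")


def gen_eye_trace(stim: DrumStimulus, spec: SyntheticEyeSpec):
    """Simulate video-oculography of an eye tracking the drum.

    eye(t) = gain * drum(t - lag) + drift * t + noise + saccade steps.
    Returns an :class:`~okrcircuit.oculography.EyeTrace` whose
    ``ground_truth`` dict holds the full generative spec and the saccade
    event times.
    """
    from .oculography import EyeTrace  # deferred: oculography imports this module

    if spec.sampling_rate_hz <= 2 * stim.oscillation_freq_hz:
        raise InvalidParameterError("sampling rate below Nyquist for the drum")
    rng = np.random.default_rng(spec.seed)
    n = int(round(stim.total_s * spec.sampling_rate_hz)) + 1
    t = np.arange(n) / spec.sampling_rate_hz
    pos = spec.true_gain * drum_position(stim, t - spec.lag_s)
    pos = pos + spec.drift_deg_per_s * t
    n_sacc = rng.poisson(spec.saccade_rate_hz * stim.total_s)
    sacc_times = np.sort(rng.uniform(0.0, stim.total_s, n_sacc))
    sacc_signs = rng.choice([-1.0, 1.0], n_sacc)
    dt = 1.0 / spec.sampling_rate_hz
    for t0, s in zip(sacc_times, sacc_signs):
        # step ramps up over 3 samples, then persists
        pos = pos + s * spec.saccade_amp_deg * np.clip((t - t0) / (3 * dt), 0.0, 1.0)
    if spec.noise_sd_deg > 0:
        pos = pos + rng.normal(0.0, spec.noise_sd_deg, n)
    truth = {
        "spec": asdict(spec),
        "saccade_times_s": sacc_times.tolist(),
        "saccade_signs": sacc_signs.tolist(),
    }
    return EyeTrace(
        time_s=t,
        position_deg=pos,
        sampling_rate_hz=spec.sampling_rate_hz,
        stimulus=stim,
        ground_truth=truth,
    )


# ---------------------------------------------------------------------------
# Direction-tuned neurons and calcium trials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeuronSpec:
    """Ground-truth tuning of one synthetic neuron.

    The tuning curve is a double von Mises in direction: a primary lobe of
    height 1 at ``pref_direction_deg`` and a secondary lobe of height
    ``dir_null_ratio`` at the opposite direction, each rescaled so the lobe
    is exactly zero 180 deg away from its own peak.  ``peak_amp`` is the
    asymptotic fluorescence response (F units) at the preferred direction;
    with baseline ``b`` the asymptotic dF/F at pref is ``peak_amp / b``.
    """

    pref_direction_deg: float = 0.0
    tuning_width_deg: float = 40.0
    peak_amp: float = 0.3
    dir_null_ratio: float = 0.25
    baseline: float = 1.0
    plasticity_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.peak_amp < 0:
            raise InvalidParameterError("peak_amp must be >= 0")
        if not 0 <= self.dir_null_ratio <= 1:
            raise InvalidParameterError("dir_null_ratio must lie in [0, 1]")
        if self.plasticity_factor <= 0:
            raise InvalidParameterError("plasticity_factor must be positive")

    @property
    def kappa(self) -> float:
        sigma = np.deg2rad(self.tuning_width_deg)
        return 1.0 / sigma**2


def _vm_lobe(delta_deg: np.ndarray, kappa: float) -> np.ndarray:
    """Von Mises lobe rescaled to 1 at 0 deg and exactly 0 at 180 deg."""
    raw = np.exp(kappa * (np.cos(np.deg2rad(delta_deg)) - 1.0))
    floor = np.exp(-2.0 * kappa)
    return (raw - floor) / (1.0 - floor)


def tuning_amplitude(neuron: NeuronSpec, direction_deg) -> np.ndarray:
    """Asymptotic response (F units, relative weight of ``peak_amp``)."""
    d = np.asarray(direction_deg, dtype=float)
    shape = _vm_lobe(d - neuron.pref_direction_deg, neuron.kappa)
    shape = shape + neuron.dir_null_ratio * _vm_lobe(
        d - neuron.pref_direction_deg - 180.0, neuron.kappa
    )
    return neuron.peak_amp * shape


def calcium_response_profile(
    t: np.ndarray, t_on: float, t_off: float, tau_s: float
) -> np.ndarray:
    """Unit-amplitude fluorescence time course for a box-car firing rate.

    Convolution of a box [t_on, t_off] with a normalized exponential
    indicator kernel: rises as 1 - exp(-(t-t_on)/tau), decays exponentially
    after stimulus offset.
    """
    t = np.asarray(t, dtype=float)
    rise = 1.0 - np.exp(-np.clip(t - t_on, 0.0, None) / tau_s)
    peak = 1.0 - np.exp(-(t_off - t_on) / tau_s)
    decay = peak * np.exp(-np.clip(t - t_off, 0.0, None) / tau_s)
    return np.where(t < t_on, 0.0, np.where(t <= t_off, rise, decay))


def expected_trial_amplitude(
    neuron: NeuronSpec,
    direction_deg: float,
    *,
    kernel_tau_s: float = 1.5,
    frame_rate_hz: float = 10.0,
    pre_s: float = 1.0,
    stim_s: float = 3.0,
    post_s: float = 3.0,
    phase: str = "pre",
) -> float:
    """Closed-form noise-free amplitude metric (mean dF/F over the
    stimulation window, on the generator's frame grid) that the tuning
    analysis should recover."""
    a = float(tuning_amplitude(neuron, direction_deg))
    if phase == "post":
        a *= neuron.plasticity_factor
    n_frames = int(round((pre_s + stim_s + post_s) * frame_rate_hz))
    t = np.arange(n_frames) / frame_rate_hz
    profile = calcium_response_profile(t, pre_s, pre_s + stim_s, kernel_tau_s)
    sel = (t >= pre_s) & (t < pre_s + stim_s)
    return a * float(profile[sel].mean()) / neuron.baseline


@dataclass
class TrialSet:
    """Trial-structured fluorescence for a population of neurons.

    ``F`` has shape (n_neurons, n_stimuli, n_trials, n_frames); the last
    stimulus slot is the blank (grey screen) condition when
    ``has_blank`` is True.  Frame times start at 0; stimulus onset is at
    ``pre_window_s``.
    """

    F: np.ndarray
    frame_times_s: np.ndarray
    directions_deg: tuple
    has_blank: bool
    pre_window_s: float
    stim_window_s: float
    neurons: tuple = ()
    phase: str = "pre"
    kernel_tau_s: float = 1.5

    @property
    def n_neurons(self) -> int:
        return self.F.shape[0]

    @property
    def n_trials(self) -> int:
        return self.F.shape[2]

    @property
    def blank_index(self) -> int | None:
        return self.F.shape[1] - 1 if self.has_blank else None

    def stimulus_frames(self) -> np.ndarray:
        t = self.frame_times_s
        return (t >= self.pre_window_s) & (t < self.pre_window_s + self.stim_window_s)

    def baseline_frames(self) -> np.ndarray:
        return self.frame_times_s < self.pre_window_s

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: neuron_id, direction_deg (NaN for blank), trial, time_s, F."""
        n_neu, n_stim, n_tr, n_fr = self.F.shape
        dirs = list(self.directions_deg) + ([np.nan] if self.has_blank else [])
        idx = pd.MultiIndex.from_product(
            [range(n_neu), dirs, range(n_tr), self.frame_times_s],
            names=["neuron_id", "direction_deg", "trial", "time_s"],
        )
        return pd.DataFrame({"F": self.F.ravel()}, index=idx).reset_index()


def gen_calcium_trials(
    neurons: Sequence[NeuronSpec],
    directions: Sequence[float],
    n_trials: int = 15,
    *,
    kernel_tau_s: float = 1.5,
    frame_rate_hz: float = 10.0,
    noise_sd: float = 0.02,
    seed: int = 0,
    phase: str = "pre",
    pre_s: float = 1.0,
    stim_s: float = 3.0,
    post_s: float = 3.0,
    include_blank: bool = True,
) -> TrialSet:
    """Simulate per-trial GCaMP fluorescence for a tuned population.

    Each trial is baseline + tuned response (box-car rate convolved with an
    exponential kernel, tau = ``kernel_tau_s``) + i.i.d. Gaussian noise.
    In ``phase='post'`` every neuron's tuned response is multiplied by its
    ``plasticity_factor`` (multiplicative plasticity, direction-independent).
    """
    if len(neurons) == 0:
        raise InvalidParameterError("need at least one neuron")
    if n_trials < 2:
        raise InvalidParameterError("need at least two trials per stimulus")
    if phase not in ("pre", "post"):
        raise InvalidParameterError("phase must be 'pre' or 'post'")
    rng = np.random.default_rng(seed)
    n_frames = int(round((pre_s + stim_s + post_s) * frame_rate_hz))
    t = np.arange(n_frames) / frame_rate_hz
    profile = calcium_response_profile(t, pre_s, pre_s + stim_s, kernel_tau_s)
    dirs = np.asarray(directions, dtype=float)
    n_stim = len(dirs) + (1 if include_blank else 0)
    F = np.empty((len(neurons), n_stim, n_trials, n_frames))
    for i, neuron in enumerate(neurons):
        amps = tuning_amplitude(neuron, dirs)
        if phase == "post":
            amps = amps * neuron.plasticity_factor
        for j in range(n_stim):
            amp = amps[j] if j < len(dirs) else 0.0
            F[i, j] = neuron.baseline + amp * profile
    if noise_sd > 0:
        F = F + rng.normal(0.0, noise_sd, F.shape)
    return TrialSet(
        F=F,
        frame_times_s=t,
        directions_deg=tuple(dirs),
        has_blank=include_blank,
        pre_window_s=pre_s,
        stim_window_s=stim_s,
        neurons=tuple(neurons),
        phase=phase,
        kernel_tau_s=kernel_tau_s,
    )


# ---------------------------------------------------------------------------
# Population composition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationComposition:
    """Direction-group structure of a population (fractions sum to 1)."""

    group_fractions: Mapping[str, float]
    n_neurons: int = 100

    def __post_init__(self) -> None:
        fr = dict(self.group_fractions)
        if self.n_neurons < 1:
            raise InvalidParameterError("n_neurons must be >= 1")
        if any(v < 0 for v in fr.values()):
            raise InvalidParameterError("fractions must be >= 0")
        if abs(sum(fr.values()) - 1.0) > 1e-9:
            raise InvalidParameterError("fractions must sum to 1")
        object.__setattr__(self, "group_fractions", fr)

    def counts(self) -> dict[str, int]:
        """Integer group counts by the largest-remainder method (sum exactly
        ``n_neurons``)."""
        items = list(self.group_fractions.items())
        raw = np.array([f * self.n_neurons for _, f in items])
        base = np.floor(raw).astype(int)
        remainder = self.n_neurons - int(base.sum())
        order = np.argsort(-(raw - base), kind="stable")
        for k in order[:remainder]:
            base[k] += 1
        return {name: int(c) for (name, _), c in zip(items, base)}


def sample_population(
    composition: PopulationComposition,
    *,
    seed: int = 0,
    tuning_width_deg: float = 40.0,
    peak_amp: float = 0.3,
    dir_null_ratio: float = 0.25,
    baseline: float = 1.0,
    plasticity_factors: Mapping[str, float] | None = None,
) -> list[NeuronSpec]:
    """Draw a population of NeuronSpecs whose preferred directions follow the
    group composition (each group at its canonical direction, jittered within
    +/-22.5 deg so preferences are not all identical)."""
    rng = np.random.default_rng(seed)
    neurons: list[NeuronSpec] = []
    for group, count in composition.counts().items():
        center = GROUP_DIRECTIONS[group]
        factor = 1.0 if plasticity_factors is None else plasticity_factors[group]
        for _ in range(count):
            pref = (center + rng.uniform(-22.5, 22.5)) % 360.0
            neurons.append(
                NeuronSpec(
                    pref_direction_deg=pref,
                    tuning_width_deg=tuning_width_deg,
                    peak_amp=peak_amp,
                    dir_null_ratio=dir_null_ratio,
                    baseline=baseline,
                    plasticity_factor=factor,
                )
            )
    return neurons


# ---------------------------------------------------------------------------
# Spiking units
# ---------------------------------------------------------------------------

@dataclass
class UnitRecording:
    """Spike times of one unit across direction trials, plus an optional
    antidromic identification sweep.

    Trial clock: spontaneous window [0, pre_s), stimulation
    [pre_s, pre_s + stim_s), then post padding.  ``spikes[d][k]`` is the
    sorted spike-time array of trial ``k`` of direction ``d``.
    """

    directions_deg: tuple
    spikes: list  # [n_directions][n_trials] -> np.ndarray
    pre_s: float
    stim_s: float
    post_s: float
    antidromic_pulse_times_s: np.ndarray | None = None
    antidromic_spike_times_s: np.ndarray | None = None
    ground_truth: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return len(self.spikes[0])

    @property
    def trial_duration_s(self) -> float:
        return self.pre_s + self.stim_s + self.post_s

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for d, direction in enumerate(self.directions_deg):
            for k, st in enumerate(self.spikes[d]):
                for s in st:
                    rows.append((direction, k, s))
        return pd.DataFrame(rows, columns=["direction_deg", "trial", "spike_time_s"])


def _poisson_times(rng, rate_hz: float, t0: float, t1: float) -> np.ndarray:
    if rate_hz <= 0 or t1 <= t0:
        return np.empty(0)
    n = rng.poisson(rate_hz * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, n))


def gen_spike_unit(
    pref_direction_deg: float,
    peak_rate_hz: float,
    baseline_hz: float,
    n_trials: int = 25,
    antidromic: Mapping[str, float] | None = None,
    seed: int = 0,
    *,
    directions: Sequence[float] | None = None,
    tuning_width_deg: float = 40.0,
    dir_null_ratio: float = 0.25,
    pre_s: float = 1.0,
    stim_s: float = 2.0,
    post_s: float = 1.0,
) -> UnitRecording:
    """Inhomogeneous-Poisson unit with direction tuning and, optionally, a
    near-deterministic antidromic spike per optogenetic pulse
    (``antidromic={'latency_ms', 'jitter_ms', 'n_pulses'}``)."""
    if peak_rate_hz < 0 or baseline_hz < 0:
        raise InvalidParameterError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    if directions is None:
        directions = np.arange(0.0, 360.0, 45.0)
    dirs = np.asarray(directions, dtype=float)
    shape_neuron = NeuronSpec(
        pref_direction_deg=pref_direction_deg,
        tuning_width_deg=tuning_width_deg,
        peak_amp=1.0,
        dir_null_ratio=dir_null_ratio,
    )
    evoked = peak_rate_hz * tuning_amplitude(shape_neuron, dirs)
    spikes = []
    for d in range(len(dirs)):
        trials = []
        for _ in range(n_trials):
            st = np.concatenate(
                [
                    _poisson_times(rng, baseline_hz, 0.0, pre_s),
                    _poisson_times(rng, baseline_hz + evoked[d], pre_s, pre_s + stim_s),
                    _poisson_times(rng, baseline_hz, pre_s + stim_s, pre_s + stim_s + post_s),
                ]
            )
            trials.append(np.sort(st))
        spikes.append(trials)
    pulse_times = spike_times = None
    if antidromic is not None:
        n_pulses = int(antidromic["n_pulses"])
        latency = antidromic["latency_ms"] / 1000.0
        jitter = antidromic["jitter_ms"] / 1000.0
        pulse_times = 0.1 + 0.25 * np.arange(n_pulses)
        evoked_times = pulse_times + latency + (
            rng.normal(0.0, jitter, n_pulses) if jitter > 0 else 0.0
        )
        background = _poisson_times(rng, baseline_hz, 0.0, pulse_times[-1] + 0.25)
        spike_times = np.sort(np.concatenate([background, evoked_times]))
    return UnitRecording(
        directions_deg=tuple(dirs),
        spikes=spikes,
        pre_s=pre_s,
        stim_s=stim_s,
        post_s=post_s,
        antidromic_pulse_times_s=pulse_times,
        antidromic_spike_times_s=spike_times,
        ground_truth={
            "pref_direction_deg": pref_direction_deg,
            "peak_rate_hz": peak_rate_hz,
            "baseline_hz": baseline_hz,
            "antidromic": dict(antidromic) if antidromic else None,
        },
    )


# ---------------------------------------------------------------------------
# Spatial cell maps
# ---------------------------------------------------------------------------

@dataclass
class CellMap:
    """Labelled cell coordinates (micrometres) on the cortical surface plane."""

    x_um: np.ndarray
    y_um: np.ndarray
    area: np.ndarray  # str labels, one per point
    ground_truth: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return len(self.x_um)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x_um": self.x_um, "y_um": self.y_um, "area": self.area})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CellMap":
        return cls(
            x_um=df["x_um"].to_numpy(float),
            y_um=df["y_um"].to_numpy(float),
            area=df["area"].to_numpy(object),
        )


def gen_cell_map(
    area_polygons: Mapping[str, object],
    per_area_density: Mapping[str, float],
    n_total: int | None = None,
    seed: int = 0,
) -> CellMap:
    """Spatial Poisson point cloud with area-dependent intensity.

    ``area_polygons`` maps labels to shapely polygons (or (xmin, ymin, xmax,
    ymax) tuples).  Counts per area are Poisson(density * area); when
    ``n_total`` is given they are multinomial with probabilities
    proportional to density * area instead.
    """
    from shapely.geometry import Point, box

    rng = np.random.default_rng(seed)
    polys = {}
    for name, poly in area_polygons.items():
        if isinstance(poly, (tuple, list)):
            poly = box(*poly)
        if poly.area <= 0:
            raise InvalidParameterError(f"area {name!r} has zero area")
        polys[name] = poly
    names = list(polys)
    weights = np.array([per_area_density[nm] * polys[nm].area for nm in names])
    if n_total is None:
        counts = rng.poisson(weights)
    else:
        if weights.sum() <= 0:
            counts = np.zeros(len(names), dtype=int)
        else:
            counts = rng.multinomial(n_total, weights / weights.sum())
    xs, ys, labels = [], [], []
    for name, count in zip(names, counts):
        poly = polys[name]
        minx, miny, maxx, maxy = poly.bounds
        got = 0
        while got < count:
            m = max(4 * (count - got), 16)
            px = rng.uniform(minx, maxx, m)
            py = rng.uniform(miny, maxy, m)
            inside = np.fromiter(
                (poly.covers(Point(a, b)) for a, b in zip(px, py)), bool, m
            )
            take = min(int(inside.sum()), count - got)
            xs.append(px[inside][:take])
            ys.append(py[inside][:take])
            got += take
        labels.extend([name] * count)
    x = np.concatenate(xs) if xs else np.empty(0)
    y = np.concatenate(ys) if ys else np.empty(0)
    return CellMap(
        x_um=x,
        y_um=y,
        area=np.array(labels, dtype=object),
        ground_truth={
            "per_area_density": dict(per_area_density),
            "area_um2": {nm: polys[nm].area for nm in names},
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# Disk I/O
# ---------------------------------------------------------------------------

def save_eye_trace(trace, path) -> None:
    """CSV (time_s, position_deg) plus a JSON ground-truth sidecar."""
    path = Path(path)
    pd.DataFrame(
        {"time_s": trace.time_s, "position_deg": trace.position_deg}
    ).to_csv(path, index=False)
    sidecar = {
        "sampling_rate_hz": trace.sampling_rate_hz,
        "stimulus": asdict(trace.stimulus) if trace.stimulus else None,
        "ground_truth": trace.ground_truth,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_eye_trace(path):
    from .oculography import EyeTrace

    path = Path(path)
    df = pd.read_csv(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    stim = DrumStimulus(**sidecar["stimulus"]) if sidecar["stimulus"] else None
    t = df["time_s"].to_numpy(float)
    return EyeTrace(
        time_s=t,
        position_deg=df["position_deg"].to_numpy(float),
        sampling_rate_hz=sidecar["sampling_rate_hz"],
        stimulus=stim,
        ground_truth=sidecar.get("ground_truth") or {},
    )


def spec_to_yaml(spec, path) -> None:
    """Serialize any generator spec dataclass to YAML."""
    Path(path).write_text(yaml.safe_dump(asdict(spec)))


def eye_spec_from_yaml(path) -> SyntheticEyeSpec:
    return SyntheticEyeSpec(**yaml.safe_load(Path(path).read_text()))


def drum_from_yaml(path) -> DrumStimulus:
    return DrumStimulus(**yaml.safe_load(Path(path).read_text()))
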