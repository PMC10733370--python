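"""Tuning-curve and selectivity analysis of calcium and spiking responses.

Pipeline for calcium data: per-trial dF/F against the 1 s pre-stimulus
baseline; response amplitude = trial-averaged mean dF/F over the stimulation
window after Tukey-fence outlier-trial removal; responsiveness = max
amplitude >= 6% (0.06) AND two-sample t-test vs blank trials, p < 0.05.
Preferred orientation/direction come from response-weighted complex vector
sums (doubled angles for orientation); the direction-selectivity index is
DSI = (R_pref - R_null) / (|R_pref| + |R_null|), defined with absolute
values because visually driven amplitudes may be negative.

Spiking units: evoked rate = stimulation-window rate minus spontaneous rate,
responsive by paired t-test (p < 0.01); antidromic identification by the
first PSTH bin crossing spontaneous mean + 3 SD, jitter = SD of the first
post-pulse spike time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateBaselineError,
    InsufficientDataError,
    InvalidParameterError,
    UndefinedMetricError,
)
from .synthetic import TrialSet, UnitRecording

RESPONSE_AMPLITUDE_THRESHOLD = 0.06  # "maximum response amplitudes are at least 6%"
RESPONSIVE_P = 0.05
OSI_THRESHOLD = 0.1
DSI_THRESHOLD = 0.33
UNIT_RESPONSIVE_P = 0.01


@dataclass(frozen=True)
class TuningCurve:
    stimulus_values: tuple
    amplitudes: tuple
    blank_amplitude: float | None
    n_trials: tuple  # retained trials per stimulus


@dataclass(frozen=True)
class DirectionPreference:
    theta_pref_deg: float | None  # preferred orientation, [0, 180)
    rho_pref_deg: float | None  # vector-sum preferred direction, [0, 360)
    sampled_pref_deg: float
    osi: float
    dsi: float
    is_orientation_selective: bool
    is_direction_selective: bool


@dataclass(frozen=True)
class UnitMetrics:
    evoked_rate_hz: float
    responsive: bool
    p_value: float
    antidromic_latency_ms: float | None = None
    antidromic_jitter_ms: float | None = None


# ---------------------------------------------------------------------------
# dF/F and trial amplitudes
# ---------------------------------------------------------------------------

def compute_dff(trialset: TrialSet) -> np.ndarray:
    """Per-trial dF/F = (F - F0)/F0 with F0 the mean fluorescence over the
    baseline window preceding stimulus onset.  Same shape as ``trialset.F``."""
    base = trialset.baseline_frames()
    if not base.any():
        raise InvalidParameterError("trial set has no pre-stimulus baseline window")
    f0 = trialset.F[..., base].mean(axis=-1, keepdims=True)
    if np.any(f0 <= 0):
        raise DegenerateBaselineError("baseline fluorescence F0 <= 0 in some trial")
    return (trialset.F - f0) / f0


def trial_amplitudes(trialset: TrialSet) -> np.ndarray:
    """Mean dF/F over the stimulation window, per neuron/stimulus/trial."""
    dff = compute_dff(trialset)
    stim = trialset.stimulus_frames()
    return dff[..., stim].mean(axis=-1)


def remove_outlier_trials(amplitudes: np.ndarray) -> np.ndarray:
    """Indices of trials retained by the Tukey rule for one stimulus.

    Trials outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR] (type-7 linear-interpolation
    quartiles) are dropped; with fewer than 4 trials the fences are
    ill-defined and all trials are kept.
    """
    a = np.asarray(amplitudes, dtype=float)
    if len(a) < 4:
        return np.arange(len(a))
    q1, q3 = np.percentile(a, [25, 75])
    iqr = q3 - q1
    keep = (a >= q1 - 1.5 * iqr) & (a <= q3 + 1.5 * iqr)
    return np.flatnonzero(keep)


def response_amplitude_and_responsiveness(
    trialset: TrialSet,
    neuron: int = 0,
    *,
    amplitude_threshold: float = RESPONSE_AMPLITUDE_THRESHOLD,
    p_threshold: float = RESPONSIVE_P,
) -> tuple[TuningCurve, bool | None]:
    """Tuning curve (trial-averaged amplitudes after outlier removal) and the
    two-criterion responsiveness flag for one neuron.

    Responsive iff max amplitude >= ``amplitude_threshold`` and the
    preferred-stimulus trial amplitudes exceed the blank-trial amplitudes by
    a two-sample t-test at ``p_threshold`` (one-sided, greater).  Without
    blank trials the test cannot run and the flag is None (undetermined).
    """
    amps = trial_amplitudes(trialset)[neuron]  # (n_stimuli, n_trials)
    n_dir = len(trialset.directions_deg)
    means, kept_counts, kept_trials = [], [], []
    for j in range(amps.shape[0]):
        keep = remove_outlier_trials(amps[j])
        kept_trials.append(amps[j][keep])
        means.append(float(amps[j][keep].mean()))
        kept_counts.append(len(keep))
    curve = TuningCurve(
        stimulus_values=trialset.directions_deg,
        amplitudes=tuple(means[:n_dir]),
        blank_amplitude=means[n_dir] if trialset.has_blank else None,
        n_trials=tuple(kept_counts[:n_dir]),
    )
    passes_amp = max(means[:n_dir]) >= amplitude_threshold
    if not trialset.has_blank:
        return curve, (False if not passes_amp else None)
    pref = int(np.argmax(means[:n_dir]))
    if np.ptp(kept_trials[pref]) == 0 and np.ptp(kept_trials[n_dir]) == 0:
        # degenerate noise-free case: constant responses, compare means directly
        p = 0.0 if kept_trials[pref].mean() > kept_trials[n_dir].mean() else 1.0
    else:
        p = stats.ttest_ind(
            kept_trials[pref], kept_trials[n_dir], alternative="greater"
        ).pvalue
    return curve, bool(passes_amp and p < p_threshold)


# ---------------------------------------------------------------------------
# Preferred direction and selectivity indices
# ---------------------------------------------------------------------------

def _rectified(amplitudes) -> np.ndarray:
    """Negative amplitudes are clipped to 0 inside vector sums; arguments of
    complex sums are unstable under sign flips."""
    return np.clip(np.asarray(amplitudes, dtype=float), 0.0, None)


def orientation_vector_sum(curve: TuningCurve) -> complex:
    r = _rectified(curve.amplitudes)
    ang = np.deg2rad(np.asarray(curve.stimulus_values, dtype=float))
    return complex(np.sum(r * np.exp(2j * ang)))


def direction_vector_sum(curve: TuningCurve) -> complex:
    r = _rectified(curve.amplitudes)
    ang = np.deg2rad(np.asarray(curve.stimulus_values, dtype=float))
    return complex(np.sum(r * np.exp(1j * ang)))


def osi(curve: TuningCurve) -> float:
    """Orientation selectivity: |sum R e^{2 i rho}| / sum R over rectified
    responses (global vector-sum magnitude, the estimator the 0.1 gate
    applies to)."""
    r = _rectified(curve.amplitudes)
    total = r.sum()
    if total == 0:
        raise UndefinedMetricError("all-zero tuning curve; OSI undefined")
    return float(np.abs(orientation_vector_sum(curve)) / total)


def dsi(curve: TuningCurve, sampled_pref_deg: float) -> float:
    """DSI = (R_pref - R_null)/(|R_pref| + |R_null|) at the sampled preferred
    direction and its 180-degree opposite (signed amplitudes)."""
    values = np.asarray(curve.stimulus_values, dtype=float) % 360.0
    amps = np.asarray(curve.amplitudes, dtype=float)
    pref = sampled_pref_deg % 360.0
    null = (sampled_pref_deg + 180.0) % 360.0
    i_pref = _index_of_direction(values, pref)
    i_null = _index_of_direction(values, null)
    r_pref, r_null = amps[i_pref], amps[i_null]
    denom = abs(r_pref) + abs(r_null)
    if denom == 0:
        raise UndefinedMetricError("R_pref = R_null = 0; DSI undefined")
    return float((r_pref - r_null) / denom)


def _index_of_direction(values: np.ndarray, direction: float) -> int:
    diff = np.abs((values - direction + 180.0) % 360.0 - 180.0)
    i = int(np.argmin(diff))
    if diff[i] > 1e-6:
        raise InvalidParameterError(f"direction {direction} deg not sampled")
    return i


def _circular_nearest(values: np.ndarray, target: float, period: float) -> int:
    half = period / 2.0
    diff = np.abs((values - target + half) % period - half)
    return int(np.argmin(diff))


def preferred_direction(
    curve: TuningCurve, *, osi_threshold: float = OSI_THRESHOLD
) -> DirectionPreference:
    """Preferred direction by the two-branch vector-sum rule.

    Orientation-selective neurons (OSI >= threshold): preferred orientation
    = half the argument of the doubled-angle vector sum; the sampled
    preferred direction is whichever of the two directions along the nearest
    sampled orientation evoked the larger response.  Other neurons: the
    argument of the plain direction vector sum, snapped to the nearest
    sampled direction.  DSI is evaluated at the sampled preferred direction.
    """
    values = np.asarray(curve.stimulus_values, dtype=float) % 360.0
    amps = np.asarray(curve.amplitudes, dtype=float)
    if not np.any(_rectified(amps) > 0):
        raise UndefinedMetricError("all responses <= 0; preference undefined")
    osi_val = osi(curve)
    theta_pref = rho_pref = None
    if osi_val >= osi_threshold:
        vec = orientation_vector_sum(curve)
        theta_pref = float(np.rad2deg(np.angle(vec)) / 2.0 % 180.0)
        orientations = np.unique(values % 180.0)
        near_ori = orientations[_circular_nearest(orientations, theta_pref, 180.0)]
        # the two sampled directions along that orientation
        cand = np.flatnonzero(np.isclose(values % 180.0, near_ori))
        sampled = float(values[cand[np.argmax(amps[cand])]])
    else:
        vec = direction_vector_sum(curve)
        rho_pref = float(np.rad2deg(np.angle(vec)) % 360.0)
        sampled = float(values[_circular_nearest(values, rho_pref, 360.0)])
    dsi_val = dsi(curve, sampled)
    return DirectionPreference(
        theta_pref_deg=theta_pref,
        rho_pref_deg=rho_pref,
        sampled_pref_deg=sampled,
        osi=osi_val,
        dsi=dsi_val,
        is_orientation_selective=osi_val >= osi_threshold,
        is_direction_selective=dsi_val >= DSI_THRESHOLD,
    )


def sf_tf_selectivity(curve: TuningCurve) -> tuple[float, float]:
    """Spatial/temporal-frequency preference and selectivity.

    Preferred value = argmax amplitude; selectivity =
    (R_pref - R_base)/(R_pref + R_base) with R_base the mean of the two
    smallest amplitudes.
    """
    values = np.asarray(curve.stimulus_values, dtype=float)
    amps = np.asarray(curve.amplitudes, dtype=float)
    if len(amps) < 3:
        raise InsufficientDataError("need at least 3 sampled SF/TF values")
    r_pref = float(amps.max())
    r_base = float(np.sort(amps)[:2].mean())
    if r_pref + r_base == 0:
        raise UndefinedMetricError("R_pref + R_base = 0; selectivity undefined")
    return float(values[np.argmax(amps)]), (r_pref - r_base) / (r_pref + r_base)


# ---------------------------------------------------------------------------
# Population convenience
# ---------------------------------------------------------------------------

def analyze_population(trialset: TrialSet) -> pd.DataFrame:
    """Per-neuron metric table: tuning-curve amplitudes, responsiveness,
    OSI/DSI and preferred directions, for downstream plasticity pairing."""
    rows = []
    for i in range(trialset.n_neurons):
        curve, responsive = response_amplitude_and_responsiveness(trialset, i)
        row: dict = {"neuron_id": i, "responsive": responsive}
        try:
            pref = preferred_direction(curve)
            row.update(
                sampled_pref_deg=pref.sampled_pref_deg,
                osi=pref.osi,
                dsi=pref.dsi,
                is_orientation_selective=pref.is_orientation_selective,
                is_direction_selective=pref.is_direction_selective,
            )
        except UndefinedMetricError:
            row.update(
                sampled_pref_deg=np.nan,
                osi=np.nan,
                dsi=np.nan,
                is_orientation_selective=False,
                is_direction_selective=False,
            )
        for d, a in zip(curve.stimulus_values, curve.amplitudes):
            row[f"amp_{d:g}"] = a
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Spiking units
# ---------------------------------------------------------------------------

def _window_rates(unit: UnitRecording, d: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial (spontaneous, stimulation) rates for direction index ``d``."""
    t0, t1 = unit.pre_s, unit.pre_s + unit.stim_s
    spont, stim = [], []
    for st in unit.spikes[d]:
        spont.append(np.sum(st < t0) / unit.pre_s)
        stim.append(np.sum((st >= t0) & (st < t1)) / unit.stim_s)
    return np.asarray(spont), np.asarray(stim)


def unit_evoked_rate_and_responsiveness(
    unit: UnitRecording, *, p_threshold: float = UNIT_RESPONSIVE_P
) -> UnitMetrics:
    """Baseline-subtracted evoked rate at the preferred stimulus and the
    paired-t responsiveness flag (stimulation vs spontaneous rates across
    trials of the best direction, p < 0.01)."""
    if unit.n_trials < 2:
        raise InsufficientDataError("need at least 2 trials")
    evoked_by_dir = []
    for d in range(len(unit.directions_deg)):
        spont, stim = _window_rates(unit, d)
        evoked_by_dir.append(stim.mean() - spont.mean())
    best = int(np.argmax(evoked_by_dir))
    spont, stim = _window_rates(unit, best)
    diffs = stim - spont
    if np.ptp(diffs) == 0:
        p = 1.0 if diffs[0] <= 0 else 0.0
    else:
        p = stats.ttest_rel(stim, spont, alternative="greater").pvalue
    return UnitMetrics(
        evoked_rate_hz=float(evoked_by_dir[best]),
        responsive=bool(p < p_threshold),
        p_value=float(p),
    )


def unit_tuning_curve(unit: UnitRecording) -> TuningCurve:
    """Direction tuning of a unit from evoked (baseline-subtracted) rates."""
    amps = []
    for d in range(len(unit.directions_deg)):
        spont, stim = _window_rates(unit, d)
        amps.append(float(stim.mean() - spont.mean()))
    return TuningCurve(
        stimulus_values=unit.directions_deg,
        amplitudes=tuple(amps),
        blank_amplitude=None,
        n_trials=tuple(unit.n_trials for _ in unit.directions_deg),
    )


def antidromic_metrics(
    unit: UnitRecording,
    pulse_times_s: np.ndarray | None = None,
    psth_bin_ms: float = 0.5,
    *,
    window_ms: float = 25.0,
) -> dict | None:
    """Latency and jitter of optogenetically evoked antidromic spikes.

    Latency = first pulse-aligned PSTH bin edge where the rate exceeds the
    spontaneous mean by 3 spontaneous SDs; jitter = SD of the first spike
    after each pulse (within the analysis window).  Returns None when the
    3 SD criterion is never crossed.
    """
    if pulse_times_s is None:
        pulse_times_s = unit.antidromic_pulse_times_s
    spikes = unit.antidromic_spike_times_s
    if pulse_times_s is None or spikes is None:
        raise InvalidParameterError("unit has no antidromic sweep")
    if len(pulse_times_s) < 20:
        raise InsufficientDataError("need at least 20 pulses")
    bin_s = psth_bin_ms / 1000.0
    win_s = window_ms / 1000.0
    n_bins = int(round(win_s / bin_s))
    counts = np.zeros(n_bins)
    first_spikes = []
    for p in pulse_times_s:
        rel = spikes[(spikes >= p) & (spikes < p + win_s)] - p
        counts += np.histogram(rel, bins=n_bins, range=(0.0, win_s))[0]
        if len(rel):
            first_spikes.append(rel[0])
    rate = counts / (len(pulse_times_s) * bin_s)
    # spontaneous statistics from equally binned pre-pulse activity
    pre_counts = []
    for p in pulse_times_s:
        rel = spikes[(spikes >= p - win_s) & (spikes < p)] - (p - win_s)
        pre_counts.append(np.histogram(rel, bins=n_bins, range=(0.0, win_s))[0])
    pre_rate = np.concatenate(pre_counts) / bin_s
    thresh = pre_rate.mean() + 3.0 * pre_rate.std()
    crossing = np.flatnonzero(rate > thresh)
    if len(crossing) == 0:
        return None
    latency_ms = crossing[0] * psth_bin_ms
    jitter_ms = float(np.std(first_spikes) * 1000.0) if first_spikes else None
    return {"latency_ms": float(latency_ms), "jitter_ms": jitter_ms}


# ---------------------------------------------------------------------------
# Calcium deconvolution
# ---------------------------------------------------------------------------

def deconvolve_calcium(
    dff: np.ndarray,
    kernel_tau_s: float = 1.5,
    frame_rate_hz: float = 10.0,
    *,
    nonneg: bool = True,
) -> np.ndarray:
    """Invert the exponential calcium kernel (tau = 1.5 s for GCaMP6s).

    The trace is modelled as an AR(1) process f[t] = g f[t-1] + r[t] with
    g = exp(-dt/tau); the inversion r[t] = f[t] - g f[t-1] is exact, and
    negative excursions (noise) are truncated at zero unless
    ``nonneg=False``.  Units: event amplitude per frame.
    """
    if kernel_tau_s <= 0:
        raise InvalidParameterError("kernel_tau_s must be positive")
    if frame_rate_hz <= 0:
        raise InvalidParameterError("frame_rate_hz must be positive")
    f = np.asarray(dff, dtype=float)
    g = np.exp(-1.0 / (frame_rate_hz * kernel_tau_s))
    r = np.empty_like(f)
    r[..., 0] = f[..., 0]
    r[..., 1:] = f[..., 1:] - g * f[..., :-1]
    return np.clip(r, 0.0, None) if nonneg else r


def reconvolve(rate: np.ndarray, kernel_tau_s: float, frame_rate_hz: float) -> np.ndarray:
    """Forward model matching :func:`deconvolve_calcium` (consistency checks)."""
    g = np.exp(-1.0 / (frame_rate_hz * kernel_tau_s))
    out = np.empty_like(np.asarray(rate, dtype=float))
    acc = np.zeros(out.shape[:-1])
    for t in range(out.shape[-1]):
        acc = acc * g + rate[..., t]
        out[..., t] = acc
    return out
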