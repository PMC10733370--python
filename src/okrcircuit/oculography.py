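"""Optokinetic-reflex (OKR) gain analysis of eye-position traces.

The OKR gain of an oscillatory drum trial is the ratio of the eye's Fourier
amplitude at the drum frequency to the drum's own amplitude:
gain = Amp_eye / Amp_drum, 1 for perfect tracking, 0 for a motionless eye.
Saccade-like fast eye movements are detected as surges in the velocity trace
and replaced by linear interpolation before the amplitude is extracted, so
only slow (tracking) eye movements enter the gain.

The amplitude is a single-bin discrete Fourier projection over an integer
number of stimulus cycles (leakage-free) after mean subtraction; the same
projection applied to the drum trajectory yields Amp_drum, so gain is exactly
1 when the eye reproduces the drum and exactly 0 when it is constant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    InsufficientDataError,
    InvalidParameterError,
    UnusableTraceError,
)
from .synthetic import DrumStimulus, drum_position

#: default saccade-detection threshold (deg/s).  Slow tracking of a 5 deg,
#: 0.4 Hz drum peaks at 2*pi*0.4*5 ~ 12.6 deg/s; saccades are an order of
#: magnitude faster.
DEFAULT_VELOCITY_THRESHOLD = 25.0
DEFAULT_PAD_SAMPLES = 2


@dataclass
class EyeTrace:
    """Uniformly sampled horizontal eye position (degrees)."""

    time_s: np.ndarray
    position_deg: np.ndarray
    sampling_rate_hz: float
    stimulus: DrumStimulus | None = None
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.position_deg = np.asarray(self.position_deg, dtype=float)
        if self.time_s.shape != self.position_deg.shape:
            raise InvalidParameterError("time and position must have equal length")
        if len(self.time_s) > 1:
            dt = np.diff(self.time_s)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
                raise InvalidParameterError("time grid must be uniform and increasing")
        if not np.all(np.isfinite(self.position_deg)):
            raise InvalidParameterError("positions must be finite")


@dataclass(frozen=True)
class GainResult:
    """Fourier-amplitude-ratio OKR gain of one trial."""

    gain: float
    amp_eye_deg: float
    amp_drum_deg: float
    n_cycles_used: int
    saccade_fraction: float


@dataclass(frozen=True)
class ContributionResult:
    """Percentage reduction of OKR gain under cortical silencing."""

    v_control: float
    v_silencing: float
    delta_v_pct: float
    included: bool


def velocity(trace: EyeTrace) -> np.ndarray:
    """Central-difference eye velocity (deg/s), one-sided at the ends."""
    return np.gradient(trace.position_deg, trace.time_s)


def remove_saccades(
    trace: EyeTrace,
    velocity_threshold_deg_per_s: float = DEFAULT_VELOCITY_THRESHOLD,
    pad_samples: int = DEFAULT_PAD_SAMPLES,
) -> tuple[EyeTrace, np.ndarray]:
    """Detect velocity surges and replace them by linear interpolation.

    Samples whose |velocity| exceeds the threshold, padded by
    ``pad_samples`` on each side, are flagged; their position *increments*
    are replaced by linear interpolation between the flanking clean
    increments (flat extrapolation at the trace boundaries) and the
    position is reintegrated.  This reconstructs the slow-phase trajectory:
    the rapid excursion and the step offset it leaves behind are both
    removed, so only slow eye movements remain.  Returns the cleaned trace
    and the boolean mask of replaced samples.
    """
    if velocity_threshold_deg_per_s <= 0:
        raise InvalidParameterError("velocity threshold must be positive")
    v = velocity(trace)
    mask = np.abs(v) > velocity_threshold_deg_per_s
    if pad_samples > 0 and mask.any():
        idx = np.flatnonzero(mask)
        for k in range(1, pad_samples + 1):
            lo = np.clip(idx - k, 0, len(mask) - 1)
            hi = np.clip(idx + k, 0, len(mask) - 1)
            mask[lo] = True
            mask[hi] = True
    if mask.all():
        raise UnusableTraceError("every sample flagged as saccadic")
    pos = trace.position_deg.copy()
    if mask.any():
        # increment k spans samples k -> k+1; it is saccadic if either end is
        inc = np.diff(pos)
        bad = mask[1:] | mask[:-1]
        if bad.all():
            raise UnusableTraceError("no clean increments; trace unusable")
        k = np.arange(len(inc))
        inc[bad] = np.interp(k[bad], k[~bad], inc[~bad])
        rebuilt = np.concatenate([[0.0], np.cumsum(inc)])
        anchor = int(np.flatnonzero(~mask)[0])
        pos = rebuilt - rebuilt[anchor] + pos[anchor]
    cleaned = EyeTrace(
        time_s=trace.time_s,
        position_deg=pos,
        sampling_rate_hz=trace.sampling_rate_hz,
        stimulus=trace.stimulus,
        ground_truth=trace.ground_truth,
    )
    return cleaned, mask


def _fourier_amplitude(x: np.ndarray, t: np.ndarray, freq_hz: float) -> float:
    """Amplitude of the sinusoidal component at ``freq_hz``: (2/M)|sum x e^{-i w t}|
    after mean subtraction, over the M supplied samples."""
    x = x - x.mean()
    phasor = np.exp(-2j * np.pi * freq_hz * t)
    return float(2.0 / len(x) * np.abs(np.sum(x * phasor)))


def okr_gain(
    trace: EyeTrace,
    stim: DrumStimulus | None = None,
    *,
    velocity_threshold_deg_per_s: float = DEFAULT_VELOCITY_THRESHOLD,
    pad_samples: int = DEFAULT_PAD_SAMPLES,
    window_cycles: int | None = None,
    desaccade: bool = True,
) -> GainResult:
    """OKR gain of one oscillatory-drum trial.

    The analysis window starts at stimulus onset and spans
    ``window_cycles`` full drum cycles (default: as many as fit in the
    stimulation period).  Interpolated (formerly saccadic) samples stay in
    the window.
    """
    if stim is None:
        stim = trace.stimulus
    if stim is None or stim.mode != "oscillatory":
        raise InvalidParameterError("okr_gain requires an oscillatory drum stimulus")
    f = stim.oscillation_freq_hz
    max_cycles = int(np.floor(stim.duration_s * f + 1e-9))
    n_cycles = max_cycles if window_cycles is None else int(window_cycles)
    if n_cycles < 1 or n_cycles > max_cycles:
        raise InsufficientDataError(
            f"window of {n_cycles} cycles does not fit in the stimulation period"
        )
    if desaccade:
        cleaned, mask = remove_saccades(
            trace, velocity_threshold_deg_per_s, pad_samples
        )
    else:
        cleaned, mask = trace, np.zeros(len(trace.time_s), dtype=bool)
    rate = trace.sampling_rate_hz
    i0 = int(round(stim.pre_s * rate))
    m = int(round(n_cycles / f * rate))  # half-open integer-cycle window
    if i0 + m > len(trace.time_s):
        raise InsufficientDataError("trace shorter than the analysis window")
    sl = slice(i0, i0 + m)
    t_win = cleaned.time_s[sl]
    amp_eye = _fourier_amplitude(cleaned.position_deg[sl], t_win, f)
    drum = drum_position(stim, t_win)
    amp_drum = _fourier_amplitude(drum, t_win, f)
    return GainResult(
        gain=amp_eye / amp_drum,
        amp_eye_deg=amp_eye,
        amp_drum_deg=amp_drum,
        n_cycles_used=n_cycles,
        saccade_fraction=float(mask[sl].mean()),
    )


def unidirectional_gain(
    trace: EyeTrace,
    stim: DrumStimulus | None = None,
    *,
    velocity_threshold_deg_per_s: float = DEFAULT_VELOCITY_THRESHOLD,
    pad_samples: int = DEFAULT_PAD_SAMPLES,
) -> float:
    """Gain of a unidirectional-drift trial: slow-phase eye velocity (linear
    fit of the desaccaded trace over the stimulation window) divided by the
    drum speed.  Nystagmus fast phases are handled by the same
    saccade-removal operator as oscillatory trials."""
    if stim is None:
        stim = trace.stimulus
    if stim is None or stim.mode != "unidirectional":
        raise InvalidParameterError("requires a unidirectional stimulus")
    cleaned, _ = remove_saccades(trace, velocity_threshold_deg_per_s, pad_samples)
    sel = (cleaned.time_s >= stim.pre_s) & (
        cleaned.time_s < stim.pre_s + stim.duration_s
    )
    if sel.sum() < 2:
        raise InsufficientDataError("stimulation window too short")
    slope = np.polyfit(cleaned.time_s[sel], cleaned.position_deg[sel], 1)[0]
    return float(slope / stim.drift_speed_deg_per_s)


def cortical_contribution(v_control: float, v_silencing: float) -> ContributionResult:
    """Percentage reduction of OKR gain under cortical silencing:
    dV = 100 (V_control - V_silencing) / V_control; trials enter the summary
    only when V_control >= 0.02."""
    if v_control < 0 or v_silencing < 0:
        raise InvalidParameterError("gains must be >= 0")
    if v_control == 0:
        raise ZeroDivisionError("v_control is zero; contribution undefined")
    delta = 100.0 * (v_control - v_silencing) / v_control
    return ContributionResult(
        v_control=v_control,
        v_silencing=v_silencing,
        delta_v_pct=delta,
        included=v_control >= 0.02,
    )


def okr_potentiation(v_pre: float, v_post: float) -> float:
    """Fractional change of OKR gain after the induction protocol:
    (V_post - V_pre) / V_pre."""
    if v_pre <= 0:
        raise InvalidParameterError("v_pre must be positive")
    return (v_post - v_pre) / v_pre


def gain_report(results, path=None) -> dict:
    """JSON-serializable summary of per-trial gains plus their average."""
    rows = [
        {
            "gain": r.gain,
            "amp_eye_deg": r.amp_eye_deg,
            "amp_drum_deg": r.amp_drum_deg,
            "n_cycles_used": r.n_cycles_used,
            "saccade_fraction": r.saccade_fraction,
        }
        for r in results
    ]
    report = {
        "trials": rows,
        "mean_gain": float(np.mean([r.gain for r in results])) if rows else None,
    }
    if path is not None:
        Path(path).write_text(json.dumps(report, indent=1))
    return report
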