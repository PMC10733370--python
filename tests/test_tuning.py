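"""Calcium/spiking tuning metrics: dF/F, outlier fences, responsiveness,
vector-sum preferences, DSI/OSI, antidromic identification, deconvolution."""

import cmath

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import okrcircuit as oc
from okrcircuit.errors import (
    DegenerateBaselineError,
    InsufficientDataError,
    UndefinedMetricError,
)
from okrcircuit.tuning import TuningCurve, reconvolve


def curve(amps, dirs=None, blank=None):
    if dirs is None:
        dirs = tuple(np.arange(0.0, 360.0, 360.0 / len(amps)))
    return TuningCurve(
        stimulus_values=tuple(dirs),
        amplitudes=tuple(float(a) for a in amps),
        blank_amplitude=blank,
        n_trials=tuple(10 for _ in amps),
    )


class TestDff:
    def test_flat_trace_zero(self):
        ts = oc.gen_calcium_trials(
            [oc.NeuronSpec(peak_amp=0.0)], [0.0], 2, noise_sd=0.0
        )
        np.testing.assert_allclose(oc.compute_dff(ts), 0.0, atol=1e-14)

    def test_six_percent_case(self):
        ts = oc.gen_calcium_trials([oc.NeuronSpec(peak_amp=0.0)], [0.0], 2, noise_sd=0.0)
        ts.F[...] = 100.0
        stim = ts.stimulus_frames()
        ts.F[..., stim] = 106.0
        dff = oc.compute_dff(ts)
        assert dff[..., stim].max() == pytest.approx(0.06)

    def test_degenerate_baseline(self):
        ts = oc.gen_calcium_trials([oc.NeuronSpec()], [0.0], 2, noise_sd=0.0)
        ts.F[..., ts.baseline_frames()] = 0.0
        with pytest.raises(DegenerateBaselineError):
            oc.compute_dff(ts)


class TestOutlierTrials:
    def test_identical_amplitudes_kept(self):
        assert len(oc.remove_outlier_trials(np.ones(6))) == 6

    def test_single_outlier_dropped(self):
        keep = oc.remove_outlier_trials([1, 1, 1, 1, 1, 100])
        assert list(keep) == [0, 1, 2, 3, 4]

    def test_fewer_than_four_pass_through(self):
        assert len(oc.remove_outlier_trials([1.0, 5.0, 100.0])) == 3

    def test_tukey_calibration_gaussian(self):
        """Per-trial removal probability stays below 0.15 for i.i.d. Gaussian
        samples of 15 trials (Tukey-rule false-positive calibration)."""
        rng = np.random.default_rng(0)
        removed = sum(
            15 - len(oc.remove_outlier_trials(rng.normal(size=15)))
            for _ in range(2000)
        )
        assert removed / (2000 * 15) < 0.15


class TestResponsiveness:
    def test_small_amplitude_never_responsive(self):
        neuron = oc.NeuronSpec(peak_amp=0.05, baseline=1.0, dir_null_ratio=0.0)
        ts = oc.gen_calcium_trials([neuron], [0.0, 180.0], 6, noise_sd=0.0)
        _, responsive = oc.response_amplitude_and_responsiveness(ts)
        assert responsive is False

    def test_noise_free_tuned_neuron_responsive(self):
        neuron = oc.NeuronSpec(peak_amp=0.3)
        ts = oc.gen_calcium_trials([neuron], [0.0, 90.0, 180.0, 270.0], 6, noise_sd=0.0)
        _, responsive = oc.response_amplitude_and_responsiveness(ts)
        assert responsive is True

    def test_without_blank_undetermined(self):
        neuron = oc.NeuronSpec(peak_amp=0.3)
        ts = oc.gen_calcium_trials(
            [neuron], [0.0, 180.0], 6, noise_sd=0.0, include_blank=False
        )
        _, responsive = oc.response_amplitude_and_responsiveness(ts)
        assert responsive is None

    def test_null_calibration(self):
        """Stimulus and blank trials drawn identically: the 6% amplitude gate
        makes the responsive rate ~0 while the t-test alone rejects ~5%."""
        from scipy import stats

        n_rep = 1000
        n_flagged = n_ttest = 0
        for rep in range(n_rep):
            ts = oc.gen_calcium_trials(
                [oc.NeuronSpec(peak_amp=0.0)], [0.0], 10, noise_sd=0.02, seed=rep
            )
            _, responsive = oc.response_amplitude_and_responsiveness(ts)
            n_flagged += bool(responsive)
            amps = oc.trial_amplitudes(ts)[0]
            p = stats.ttest_ind(amps[0], amps[1], alternative="greater").pvalue
            n_ttest += p < 0.05
        assert n_flagged / n_rep < 0.01
        assert 0.03 < n_ttest / n_rep < 0.07


class TestPreferredDirection:
    def test_single_peak(self):
        pref = oc.preferred_direction(curve([1, 0, 0, 0, 0, 0, 0, 0]))
        assert pref.sampled_pref_deg == 0.0

    def test_axial_tie_break_by_response(self):
        pref = oc.preferred_direction(curve([1.0, 0, 0, 0, 0.9, 0, 0, 0]))
        assert pref.is_orientation_selective
        # orientation angle compared on the 180-degree circle
        assert (pref.theta_pref_deg + 90.0) % 180.0 - 90.0 == pytest.approx(0.0, abs=1e-9)
        assert pref.sampled_pref_deg == 0.0

    def test_non_orientation_selective_uses_direction_sum(self):
        # pure first-harmonic curve: no orientation component, clear
        # direction bias towards 0 degrees
        dirs = np.arange(0.0, 360.0, 45.0)
        amps = 0.6 + 0.4 * np.cos(np.deg2rad(dirs))
        c = curve(amps)
        assert oc.osi(c) < 0.1
        pref = oc.preferred_direction(c)
        assert pref.rho_pref_deg is not None
        assert pref.sampled_pref_deg == 0.0

    def test_vector_sum_matches_bruteforce_oracle(self):
        """Implementation arguments agree with a direct complex-sum
        enumeration to 1e-9 on random rectified curves."""
        rng = np.random.default_rng(42)
        dirs = np.arange(0.0, 360.0, 45.0)
        for _ in range(200):
            amps = np.clip(rng.normal(0.3, 0.4, 8), 0, None)
            if amps.sum() == 0:
                continue
            c = curve(amps)
            oracle_dir = cmath.phase(
                sum(a * cmath.exp(1j * np.deg2rad(d)) for a, d in zip(amps, dirs))
            )
            oracle_ori = cmath.phase(
                sum(a * cmath.exp(2j * np.deg2rad(d)) for a, d in zip(amps, dirs))
            )
            from okrcircuit.tuning import direction_vector_sum, orientation_vector_sum

            assert cmath.phase(direction_vector_sum(c)) == pytest.approx(
                oracle_dir, abs=1e-9
            )
            assert cmath.phase(orientation_vector_sum(c)) == pytest.approx(
                oracle_ori, abs=1e-9
            )

    def test_all_zero_curve_undefined(self):
        with pytest.raises(UndefinedMetricError):
            oc.preferred_direction(curve([0, 0, 0, 0]))


class TestDsi:
    def test_double_response_threshold(self):
        assert oc.dsi(curve([2, 0, 1, 0]), 0.0) == pytest.approx(1 / 3)

    def test_zero_null_gives_one(self):
        assert oc.dsi(curve([2, 0, 0, 0]), 0.0) == 1.0

    def test_negative_null_absolute_denominator(self):
        assert oc.dsi(curve([1, 0, -1, 0]), 0.0) == 1.0

    def test_zero_over_zero_undefined(self):
        with pytest.raises(UndefinedMetricError):
            oc.dsi(curve([0, 1, 0, 1]), 0.0)

    @given(c=st.floats(0.01, 100.0))
    def test_scale_invariance(self, c):
        amps = np.array([1.2, 0.4, 0.3, 0.6, 0.1, 0.2, 0.9, 0.5])
        base = curve(amps)
        scaled = curve(c * amps)
        assert oc.dsi(scaled, 0.0) == pytest.approx(oc.dsi(base, 0.0), abs=1e-12)
        assert oc.osi(scaled) == pytest.approx(oc.osi(base), abs=1e-12)


class TestSfTfSelectivity:
    def test_flat_curve_zero(self):
        _, sel = oc.sf_tf_selectivity(curve([1, 1, 1, 1], dirs=[0.04, 0.08, 0.16, 0.32]))
        assert sel == 0.0

    def test_two_zero_minima(self):
        _, sel = oc.sf_tf_selectivity(curve([0, 0, 1], dirs=[0.04, 0.08, 0.16]))
        assert sel == 1.0

    def test_bandpass_curve(self):
        vals = [0.04, 0.08, 0.16, 0.32, 0.45]
        pref, sel = oc.sf_tf_selectivity(curve([1, 2, 4, 2, 1], dirs=vals))
        assert pref == 0.16
        assert sel == pytest.approx(0.6)

    def test_selectivity_in_unit_interval_for_nonneg(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            amps = rng.uniform(0, 2, 5)
            _, sel = oc.sf_tf_selectivity(curve(amps, dirs=[1, 2, 3, 4, 5]))
            assert 0.0 <= sel <= 1.0

    def test_needs_three_values(self):
        with pytest.raises(InsufficientDataError):
            oc.sf_tf_selectivity(curve([1, 2], dirs=[0.04, 0.08]))


class TestUnitMetrics:
    def test_zero_spikes_not_responsive(self):
        unit = oc.gen_spike_unit(0.0, 0.0, 0.0, n_trials=5, seed=0)
        m = oc.unit_evoked_rate_and_responsiveness(unit)
        assert m.evoked_rate_hz == 0.0
        assert not m.responsive

    def test_doubled_rate_responsive(self):
        unit = oc.gen_spike_unit(
            0.0, 10.0, 10.0, n_trials=25, seed=1, directions=[0.0, 180.0]
        )
        m = oc.unit_evoked_rate_and_responsiveness(unit)
        assert m.responsive
        assert m.evoked_rate_hz == pytest.approx(10.0, rel=0.3)

    def test_type_one_error_calibration(self):
        """Baseline-only units are called responsive at roughly the nominal
        1% rate (paired t-test at p < 0.01, one direction, 20 trials)."""
        hits = 0
        n_rep = 1000
        for rep in range(n_rep):
            unit = oc.gen_spike_unit(
                0.0, 0.0, 8.0, n_trials=20, seed=rep, directions=[0.0]
            )
            hits += oc.unit_evoked_rate_and_responsiveness(unit).responsive
        assert hits / n_rep < 0.03

    def test_insufficient_trials(self):
        unit = oc.gen_spike_unit(0.0, 5.0, 1.0, n_trials=1, seed=0, directions=[0.0])
        with pytest.raises(InsufficientDataError):
            oc.unit_evoked_rate_and_responsiveness(unit)


class TestAntidromic:
    def test_exact_latency_zero_jitter(self):
        unit = oc.gen_spike_unit(
            0.0, 0.0, 0.0, n_trials=2,
            antidromic={"latency_ms": 5.0, "jitter_ms": 0.0, "n_pulses": 50},
            seed=0,
        )
        m = oc.antidromic_metrics(unit)
        assert m["latency_ms"] == pytest.approx(5.0, abs=0.5)
        assert m["jitter_ms"] == pytest.approx(0.0, abs=1e-9)

    def test_generator_recovery(self):
        unit = oc.gen_spike_unit(
            0.0, 0.0, 5.0, n_trials=2,
            antidromic={"latency_ms": 5.5, "jitter_ms": 0.4, "n_pulses": 200},
            seed=3,
        )
        m = oc.antidromic_metrics(unit)
        assert m["latency_ms"] == pytest.approx(5.5, abs=0.5)
        assert m["jitter_ms"] == pytest.approx(0.4, abs=0.1)

    def test_no_locked_spikes_returns_none(self):
        unit = oc.gen_spike_unit(
            0.0, 0.0, 5.0, n_trials=2,
            antidromic={"latency_ms": 5.0, "jitter_ms": 0.0, "n_pulses": 100},
            seed=4,
        )
        # strip the evoked spikes, keep only background
        rng = np.random.default_rng(9)
        unit.antidromic_spike_times_s = np.sort(
            rng.uniform(0, unit.antidromic_pulse_times_s[-1], 100)
        )
        assert oc.antidromic_metrics(unit) is None

    def test_needs_twenty_pulses(self):
        unit = oc.gen_spike_unit(
            0.0, 0.0, 1.0, n_trials=2,
            antidromic={"latency_ms": 5.0, "jitter_ms": 0.0, "n_pulses": 10},
            seed=0,
        )
        with pytest.raises(InsufficientDataError):
            oc.antidromic_metrics(unit)


class TestDeconvolution:
    def test_impulse_recovery(self):
        tau, rate_hz = 1.5, 10.0
        g = np.exp(-1 / (rate_hz * tau))
        trace = np.zeros(50)
        trace[20:] = g ** np.arange(30)
        est = oc.deconvolve_calcium(trace, tau, rate_hz)
        assert np.argmax(est) == 20
        assert est[20] == pytest.approx(1.0)
        others = np.delete(est, 20)
        assert np.abs(others).max() < 1e-12

    def test_zero_trace(self):
        np.testing.assert_array_equal(oc.deconvolve_calcium(np.zeros(30)), np.zeros(30))

    def test_reconvolution_consistency(self):
        rng = np.random.default_rng(5)
        rate = np.clip(rng.normal(0, 1, 80), 0, None)
        trace = reconvolve(rate, 1.5, 10.0)
        est = oc.deconvolve_calcium(trace, 1.5, 10.0)
        back = reconvolve(est, 1.5, 10.0)
        assert np.sqrt(np.mean((back - trace) ** 2)) < 1e-6
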