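"""Filtering, detection and kinetics tests against analytic oracles."""

import numpy as np
import pytest

from nmjquant import (
    GaussianLowpass,
    ReleaseModelConfig,
    VoltageTrace,
    detect_mepps,
    extract_evoked,
    gaussian_lowpass,
    match_events,
    measure_kinetics,
    mepp_frequency,
    simulate_evoked,
    simulate_spontaneous,
)
from nmjquant.events import SynapticEvent, estimate_noise_sd
from nmjquant.waveforms import biexp_rise_time_ms, biexp_waveform

from conftest import make_template_trace


class TestGaussianLowpass:
    def test_dc_gain_is_one_on_constant(self):
        trace = VoltageTrace(np.full(10_000, -68.3))
        out = gaussian_lowpass(trace, 2000.0)
        np.testing.assert_allclose(out.samples, -68.3, atol=1e-9)

    def test_impulse_response_sums_to_one(self):
        x = np.zeros(4001)
        x[2000] = 1.0
        out = GaussianLowpass(2000.0, sample_rate_hz=10_000.0).transform(x)
        assert abs(out.sum() - 1.0) < 1e-9

    def test_sinusoid_attenuation_matches_transfer_function(self):
        # |H(f)| = exp(-2 pi^2 sigma_t^2 f^2) with sigma_t = sqrt(ln2)/(2 pi fc)
        fs, fc, f0 = 10_000.0, 2000.0, 3000.0
        t = np.arange(int(fs)) / fs
        x = np.sin(2 * np.pi * f0 * t)
        y = GaussianLowpass(fc, sample_rate_hz=fs).transform(x)
        sigma_t = np.sqrt(np.log(2)) / (2 * np.pi * fc)
        expected = np.exp(-2 * np.pi**2 * sigma_t**2 * f0**2)
        mid = slice(2000, 8000)  # avoid edges
        gain = np.sqrt(np.mean(y[mid] ** 2) / np.mean(x[mid] ** 2))
        assert abs(gain - expected) / expected < 0.01

    def test_mean_preserved(self):
        rng = np.random.default_rng(0)
        trace = VoltageTrace(rng.normal(-70, 0.5, 50_000))
        out = gaussian_lowpass(trace)
        assert abs(out.samples.mean() - trace.samples.mean()) < 1e-9

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            gaussian_lowpass(VoltageTrace(np.zeros(100)), 6000.0)


class TestDetectMepps:
    def test_noiseless_injected_events_recovered_exactly(self):
        times = [0.5, 1.2, 2.0]
        trace = make_template_trace(times, [0.23] * 3, 3.0)
        events = detect_mepps(trace)
        assert len(events) == 3
        onsets = np.array([ev.onset_s for ev in events])
        np.testing.assert_allclose(onsets, times, atol=2e-4)  # within 2 samples
        for ev in events:
            assert abs(ev.amplitude_mv - 0.23) / 0.23 < 0.03

    def test_events_within_min_interval_merge_to_earlier(self):
        trace = make_template_trace([1.0, 1.003], [0.23, 0.23], 2.0)
        events = detect_mepps(trace, min_interval_ms=5.0)
        assert len(events) == 1
        assert abs(events[0].onset_s - 1.0) < 2e-4

    def test_exclusion_windows_drop_events(self):
        trace = make_template_trace([0.5, 1.5], [0.23, 0.23], 2.0)
        events = detect_mepps(trace, exclusion_windows_s=[(1.4, 1.6)])
        assert len(events) == 1
        assert events[0].peak_s < 1.0

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_mepps(VoltageTrace(np.array([])))

    def test_sensitivity_and_fdr_at_moderate_noise(self):
        # amplitude/noise-SD = 5 (hardest admissible ratio), 3 short seeds
        cfg = ReleaseModelConfig(noise_sd_mv=0.23 / 5.0, q_cv=0.0)
        tps = fns = fps = 0
        for seed in range(3):
            trace, truth = simulate_spontaneous(cfg, 30.0, seed=seed)
            events = detect_mepps(trace)
            tp, fn, fp = match_events(
                np.asarray(truth.event_times_s),
                np.array([ev.onset_s for ev in events]),
            )
            tps, fns, fps = tps + tp, fns + fn, fps + fp
        assert tps / (tps + fns) >= 0.9
        assert fps / max(tps + fps, 1) <= 0.05

    def test_noise_sd_estimator_on_white_noise(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.0, 0.05, 200_000)
        assert abs(estimate_noise_sd(x) - 0.05) / 0.05 < 0.02


class TestExtractEvoked:
    def test_identical_epps_equal_amplitudes(self):
        stim = np.array([0.5, 1.0, 1.5])
        trace = make_template_trace(stim + 0.0, [12.0] * 3, 2.5)
        trace.stimulus_times_s = stim
        events = extract_evoked(trace, stim, window_ms=25.0)
        amps = [ev.amplitude_mv for ev in events]
        assert len(amps) == 3
        np.testing.assert_allclose(amps, amps[0], rtol=1e-12)

    def test_amplitudes_match_simulator_truth(self, quiet_config):
        trace, truth = simulate_evoked(quiet_config, n_stimuli=10, seed=5)
        events = extract_evoked(trace, window_ms=25.0)
        amps = np.array([ev.amplitude_mv for ev in events])
        # sampled peak vs continuous peak: sub-0.1% discretisation only
        np.testing.assert_allclose(
            amps, np.asarray(truth.observed_amplitudes_mv), rtol=1e-3
        )

    def test_failure_flagging(self):
        stim = np.array([0.5, 1.0])
        trace = make_template_trace([0.5], [10.0], 1.6)
        events = extract_evoked(trace, stim, window_ms=25.0, min_amplitude_mv=0.5)
        assert not events[0].is_failure
        assert events[1].is_failure

    def test_window_past_end_rejected(self):
        trace = make_template_trace([0.5], [10.0], 1.0)
        with pytest.raises(ValueError):
            extract_evoked(trace, [0.99], window_ms=25.0)

    def test_missing_stimulus_times_rejected(self):
        trace = make_template_trace([0.5], [10.0], 1.0)
        with pytest.raises(ValueError):
            extract_evoked(trace, None)


class TestKinetics:
    def _template_trace_and_event(self, rise_tau, decay_tau, amp=1.0, fs=100_000.0,
                                  offset=0.0):
        t_ms = np.arange(int(0.05 * fs)) / fs * 1e3
        v = amp * biexp_waveform(t_ms, rise_tau, decay_tau) + offset
        trace = VoltageTrace(v, fs)
        pk = int(np.argmax(v))
        ev = SynapticEvent(onset_s=0.0, peak_s=pk / fs, amplitude_mv=amp)
        return trace, ev

    def test_rise_time_matches_analytic_value(self):
        trace, ev = self._template_trace_and_event(0.2, 3.5)
        kin = measure_kinetics(trace, ev)
        expected = biexp_rise_time_ms(0.2, 3.5)
        assert kin.measurable
        assert abs(kin.rise_time_ms - expected) / expected < 0.02

    def test_decay_tau_matches_generating_constant(self):
        trace, ev = self._template_trace_and_event(0.2, 3.5)
        kin = measure_kinetics(trace, ev)
        assert abs(kin.decay_time_ms - 3.5) / 3.5 < 0.02
        assert kin.fit_quality > 0.99

    def test_scale_and_offset_invariance(self):
        t1, e1 = self._template_trace_and_event(0.3, 4.0, amp=1.0)
        t2, e2 = self._template_trace_and_event(0.3, 4.0, amp=2.0, offset=-70.0)
        k1 = measure_kinetics(t1, e1)
        k2 = measure_kinetics(t2, e2)
        assert abs(k1.rise_time_ms - k2.rise_time_ms) < 1e-9
        assert abs(k1.decay_time_ms - k2.decay_time_ms) / k1.decay_time_ms < 1e-6

    def test_pure_exponential_decay_recovered(self):
        fs = 10_000.0
        t_ms = np.arange(int(0.05 * fs)) / fs * 1e3
        rise = np.clip(t_ms / 1.0, 0, 1)  # 1 ms linear ramp
        decay = np.exp(-np.maximum(t_ms - 1.0, 0) / 4.0)
        v = rise * decay
        pk = int(np.argmax(v))
        ev = SynapticEvent(onset_s=0.0, peak_s=pk / fs, amplitude_mv=1.0)
        kin = measure_kinetics(VoltageTrace(v, fs), ev)
        assert abs(kin.decay_time_ms - 4.0) / 4.0 < 0.01

    def test_unbracketable_rise_flagged_not_dropped(self):
        # pure decay from the first sample: no rising phase exists, so the
        # 10/90 crossings cannot be bracketed and the event is flagged
        fs = 10_000.0
        t_ms = np.arange(500) / fs * 1e3
        v = np.exp(-t_ms / 3.0)
        ev = SynapticEvent(onset_s=0.0, peak_s=0.0, amplitude_mv=1.0)
        kin = measure_kinetics(VoltageTrace(v, fs), ev)
        assert not kin.measurable


class TestFrequency:
    def test_rate_arithmetic(self):
        assert mepp_frequency(300, 60.0) == 5.0
        assert mepp_frequency([], 10.0) == 0.0

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            mepp_frequency(10, 0.0)

    def test_rate_recovered_from_simulation(self):
        cfg = ReleaseModelConfig(noise_sd_mv=0.0, q_cv=0.0, mepp_rate_hz=5.33)
        rates = []
        for seed in range(10):
            _, truth = simulate_spontaneous(cfg, 60.0, seed=seed)
            rates.append(mepp_frequency(len(truth.event_times_s), 60.0))
        se = np.sqrt(5.33 / 60.0 / 10)
        assert abs(np.mean(rates) - 5.33) < 3 * se
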