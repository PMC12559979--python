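import numpy as np
import pytest

from nmjquant import ReleaseModelConfig, VoltageTrace
from nmjquant.waveforms import biexp_waveform


@pytest.fixture
def quiet_config() -> ReleaseModelConfig:
    """Noise-free, CV-free release model for exact-recovery tests."""
    return ReleaseModelConfig(noise_sd_mv=0.0, q_cv=0.0)


@pytest.fixture
def default_config() -> ReleaseModelConfig:
    return ReleaseModelConfig()


def make_template_trace(
    times_s,
    amplitudes_mv,
    duration_s,
    rise_tau_ms=0.8,
    decay_tau_ms=3.5,
    sample_rate_hz=10_000.0,
    baseline_mv=-70.0,
    noise_sd_mv=0.0,
    seed=0,
) -> VoltageTrace:
    """Trace with difference-of-exponentials events injected at known times."""
    n = int(round(duration_s * sample_rate_hz))
    v = np.full(n, float(baseline_mv))
    t_ms = np.arange(int(10 * decay_tau_ms * 1e-3 * sample_rate_hz)) / sample_rate_hz * 1e3
    tmpl = biexp_waveform(t_ms, rise_tau_ms, decay_tau_ms)
    for t0, a in zip(np.atleast_1d(times_s), np.atleast_1d(amplitudes_mv)):
        i0 = int(round(t0 * sample_rate_hz))
        seg = tmpl[: max(n - i0, 0)]
        v[i0 : i0 + seg.size] += a * seg
    if noise_sd_mv > 0:
        v += np.random.default_rng(seed).normal(0, noise_sd_mv, n)
    return VoltageTrace(v, sample_rate_hz)
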