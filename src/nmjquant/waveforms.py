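"""Canonical synaptic-event waveform: a difference of exponentials.

A postsynaptic potential is modelled as

    w(t) = (exp(-t / tau_d) - exp(-t / tau_r)) / w_peak,   t >= 0

normalised so its maximum is exactly 1.  The same shape serves as the
simulated mEPP/EPP template and as the analytic ground truth for kinetics
oracles (its peak time and fractional rise crossings have closed forms or
one-dimensional root-finding solutions).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "biexp_waveform",
    "biexp_peak_time_ms",
    "biexp_rise_time_ms",
]


def biexp_peak_time_ms(rise_tau_ms: float, decay_tau_ms: float) -> float:
    """Time of the waveform maximum, in ms.

    Setting dw/dt = 0 gives t_peak = ln(tau_d/tau_r) * tau_r*tau_d / (tau_d - tau_r).
    """
    tr, td = float(rise_tau_ms), float(decay_tau_ms)
    if tr <= 0 or td <= 0:
        raise ValueError("time constants must be positive")
    if tr >= td:
        raise ValueError("rise_tau_ms must be smaller than decay_tau_ms")
    return np.log(td / tr) * tr * td / (td - tr)


def biexp_waveform(
    t_ms: np.ndarray, rise_tau_ms: float, decay_tau_ms: float
) -> np.ndarray:
    """Unit-peak difference-of-exponentials waveform evaluated at ``t_ms``.

    Zero for t < 0; the peak value is exactly 1 at ``biexp_peak_time_ms``.
    """
    tr, td = float(rise_tau_ms), float(decay_tau_ms)
    tp = biexp_peak_time_ms(tr, td)
    peak = np.exp(-tp / td) - np.exp(-tp / tr)
    t = np.asarray(t_ms, dtype=float)
    w = np.where(t >= 0, (np.exp(-np.maximum(t, 0) / td) - np.exp(-np.maximum(t, 0) / tr)) / peak, 0.0)
    return w


def _frac_crossing_ms(frac: float, rise_tau_ms: float, decay_tau_ms: float) -> float:
    tp = biexp_peak_time_ms(rise_tau_ms, decay_tau_ms)
    f = lambda t: biexp_waveform(np.array([t]), rise_tau_ms, decay_tau_ms)[0] - frac
    return brentq(f, 1e-12, tp)


def biexp_rise_time_ms(
    rise_tau_ms: float,
    decay_tau_ms: float,
    lo: float = 0.1,
    hi: float = 0.9,
) -> float:
    """Analytic fractional rise time (default 10-90%) of the unit-peak waveform.

    Solved by root finding on the continuous waveform; independent of any
    sampled-trace measurement, so it can serve as an oracle for
    :func:`nmjquant.events.measure_kinetics`.
    """
    if not 0 < lo < hi < 1:
        raise ValueError("need 0 < lo < hi < 1")
    return _frac_crossing_ms(hi, rise_tau_ms, decay_tau_ms) - _frac_crossing_ms(
        lo, rise_tau_ms, decay_tau_ms
    )
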