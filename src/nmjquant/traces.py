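"""Voltage-trace container and plain-text I/O.

Intracellular records are uniformly sampled membrane potential (mV), by
default at 10 kHz, optionally annotated with nerve-stimulus times.  Traces
are exchanged as two-column CSV (``time_s``, ``v_mv``); stimulus times
travel in a JSON side-car or in the ``meta`` mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["VoltageTrace", "read_trace_csv", "write_trace_csv"]


@dataclass
class VoltageTrace:
    """Uniformly sampled membrane potential record.

    Parameters
    ----------
    samples : ndarray
        Membrane potential in mV.
    sample_rate_hz : float
        Sampling rate; must be positive.
    stimulus_times_s : ndarray or None
        Nerve stimulation times (s), all within the trace duration.
    meta : dict
        Free-form provenance (age group, synapse id, generator config, ...).
    """

    samples: np.ndarray
    sample_rate_hz: float = 10_000.0
    stimulus_times_s: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not self.sample_rate_hz > 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.stimulus_times_s is not None:
            st = np.asarray(self.stimulus_times_s, dtype=float)
            if st.size and (st.min() < 0 or st.max() > self.duration_s):
                raise ValueError("stimulus times must lie within the trace")
            self.stimulus_times_s = st

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate_hz

    def index_of(self, t_s: float) -> int:
        """Nearest 0-based sample index for a time in seconds."""
        return int(round(t_s * self.sample_rate_hz))


def write_trace_csv(trace: VoltageTrace, path: str | Path) -> None:
    """Write a trace as two-column CSV (time_s, v_mv)."""
    pd.DataFrame({"time_s": trace.times_s, "v_mv": trace.samples}).to_csv(
        path, index=False
    )


def read_trace_csv(
    path: str | Path,
    sample_rate_hz: float | None = None,
    stimulus_times_s=None,
) -> VoltageTrace:
    """Read a two-column CSV trace; the rate is inferred from the time column
    unless given explicitly."""
    df = pd.read_csv(path)
    if not {"time_s", "v_mv"} <= set(df.columns):
        raise ValueError("trace CSV needs columns time_s and v_mv")
    if sample_rate_hz is None:
        dt = np.diff(df["time_s"].to_numpy())
        if dt.size == 0 or not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("cannot infer sample rate from a non-uniform time column")
        sample_rate_hz = 1.0 / dt[0]
    return VoltageTrace(
        samples=df["v_mv"].to_numpy(),
        sample_rate_hz=float(sample_rate_hz),
        stimulus_times_s=stimulus_times_s,
        meta={"source": str(path)},
    )
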