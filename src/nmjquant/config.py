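"""Quantal release-model configuration.

``ReleaseModelConfig`` collects every knob of the binomial
depletion-replenishment release model and of the recording it produces.
Default magnitudes follow the young-adult (4-month) mouse NMJ phenotype:
mEPP amplitude 0.23 mV at 5.33 events/s, first-stimulus quantal content
n0 * p = 80, and a 10-90% mEPP rise time of ~0.86 ms (rise tau 0.8 ms with
decay tau 3.5 ms).  The recording-noise SD is not a measured quantity; the
default 0.02 mV is a declared choice representative of a quiet sharp-electrode
baseline and is stated here, in config, rather than inferred from data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["ReleaseModelConfig"]


@dataclass
class ReleaseModelConfig:
    """Parameters of the synthetic release model and recording.

    Attributes
    ----------
    n0 : int
        Initial releasable pool size (quanta).
    p_release : float
        Per-vesicle release probability per stimulus, in [0, 1].
    q_mv : float
        Mean quantal (mEPP) amplitude, mV.
    q_cv : float
        Coefficient of variation of quantal amplitude (>= 0); amplitudes are
        drawn from a normal truncated at zero.
    replenish_per_s : float
        Pool refill rate, quanta/s (deterministic per inter-stimulus interval
        with fractional carry-over unless ``replenish_poisson``).
    pool_cap : int or None
        Maximum pool size; ``None`` means equal to ``n0``.
    mepp_rate_hz : float
        Spontaneous (Poisson) event rate, events/s.
    rise_tau_ms, decay_tau_ms : float
        Waveform time constants of the difference-of-exponentials event shape.
    noise_sd_mv : float
        Additive Gaussian recording-noise SD, mV.
    v_rest_mv : float
        Resting membrane potential, mV (trace baseline).
    e_drive_mv : float
        Driving force E for the saturation/non-linear-summation model, mV.
    f_nls : float
        Non-linear summation factor in [0, 1].
    sample_rate_hz : float
        Digitisation rate of rendered traces.
    replenish_poisson : bool
        Draw per-interval replenishment from a Poisson distribution instead
        of the deterministic carry-over scheme.
    """

    n0: int = 1000
    p_release: float = 0.08
    q_mv: float = 0.23
    q_cv: float = 0.39
    replenish_per_s: float = 1000.0
    pool_cap: int | None = None
    mepp_rate_hz: float = 5.33
    rise_tau_ms: float = 0.8
    decay_tau_ms: float = 3.5
    noise_sd_mv: float = 0.02
    v_rest_mv: float = -70.0
    e_drive_mv: float = 50.0
    f_nls: float = 0.8
    sample_rate_hz: float = 10_000.0
    replenish_poisson: bool = False

    def __post_init__(self) -> None:
        if self.n0 < 0 or int(self.n0) != self.n0:
            raise ValueError("n0 must be a non-negative integer")
        if not 0.0 <= self.p_release <= 1.0:
            raise ValueError("p_release must be in [0, 1]")
        if self.q_mv <= 0:
            raise ValueError("q_mv must be positive")
        for name in ("q_cv", "replenish_per_s", "mepp_rate_hz", "noise_sd_mv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("rise_tau_ms", "decay_tau_ms", "e_drive_mv", "sample_rate_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.f_nls <= 1.0:
            raise ValueError("f_nls must be in [0, 1]")
        if self.pool_cap is None:
            self.pool_cap = int(self.n0)
        if self.pool_cap < self.n0:
            raise ValueError("pool_cap must be >= n0")

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ReleaseModelConfig":
        return cls(**d)

    def save(self, path: str | Path) -> None:
        """Write the config as YAML (or JSON when the suffix is .json)."""
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "ReleaseModelConfig":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)
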