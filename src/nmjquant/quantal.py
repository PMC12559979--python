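"""Non-linear summation correction and quantal content.

Quantal depolarisations add sublinearly as the membrane potential approaches
the transmitter reversal potential.  The classical correction divides the
recorded amplitude v by (1 - f*v/E), where E is the driving force (resting
minus reversal potential) and f is an empirical factor; f = 0.8 with
E = 50 mV are the standard recommendations and both are exposed because the
source constants of any given study vary.  Quantal content (QC) is the mean
corrected EPP amplitude divided by the mean (uncorrected) mEPP amplitude of
the same synapse; at 0.2 mV the mEPP correction would be <0.5% and is
deliberately omitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "NlsParams",
    "QuantalSummary",
    "correct_nls",
    "saturate_nls",
    "quantal_content",
    "summarize_synapse",
]


@dataclass(frozen=True)
class NlsParams:
    """Non-linear summation constants: factor ``f`` and driving force ``E`` (mV)."""

    f: float = 0.8
    e_drive_mv: float = 50.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("f must be in [0, 1]")
        if self.e_drive_mv <= 0:
            raise ValueError("e_drive_mv must be positive")


@dataclass
class QuantalSummary:
    """Per-synapse quantal summary (one NMJ, one recording session)."""

    mean_mepp_mv: float
    mepp_freq_hz: float
    mean_epp_mv: float  # NLS-corrected
    qc: float
    n_mepps: int
    n_epps: int


def correct_nls(v_mv, params: NlsParams = NlsParams()):
    """Correct recorded amplitude(s) for non-linear summation.

    Returns ``v / (1 - f*v/E)``; strictly greater than ``v`` for positive
    amplitudes whenever f > 0.  Accepts scalars or arrays.

    Raises
    ------
    ValueError
        If ``f*v/E >= 1`` for any element (the correction is undefined there).
    """
    v = np.asarray(v_mv, dtype=float)
    x = params.f * v / params.e_drive_mv
    if np.any(x >= 1.0):
        raise ValueError("correction undefined: f*v/E >= 1")
    out = v / (1.0 - x)
    return out.item() if np.isscalar(v_mv) else out


def saturate_nls(v_lin_mv, params: NlsParams = NlsParams()):
    """Forward saturation model: the exact algebraic inverse of
    :func:`correct_nls`.

    Maps a linear (would-be) amplitude to the recorded one,
    ``v_lin / (1 + f*v_lin/E)``, so that ``correct_nls(saturate_nls(v)) == v``
    up to floating point.
    """
    v = np.asarray(v_lin_mv, dtype=float)
    if np.any(v < 0):
        raise ValueError("linear amplitude must be non-negative")
    out = v / (1.0 + params.f * v / params.e_drive_mv)
    return out.item() if np.isscalar(v_lin_mv) else out


def quantal_content(mean_epp_mv: float, mean_mepp_mv: float) -> float:
    """QC = mean (corrected) EPP amplitude / mean mEPP amplitude."""
    if not mean_mepp_mv > 0:
        raise ValueError("mean mEPP amplitude must be positive")
    return float(mean_epp_mv) / float(mean_mepp_mv)


def summarize_synapse(
    mepp_amplitudes_mv: Sequence[float],
    epp_amplitudes_mv: Sequence[float],
    duration_s: float,
    params: NlsParams = NlsParams(),
) -> QuantalSummary:
    """Summarise one synapse from its detected events.

    EPP amplitudes are NLS-corrected before averaging; mEPP amplitudes are
    not.  QC is computed from this synapse's own mEPP mean.
    """
    mepps = np.asarray(mepp_amplitudes_mv, dtype=float)
    epps = np.asarray(epp_amplitudes_mv, dtype=float)
    if mepps.size == 0 or epps.size == 0:
        raise ValueError("need at least one mEPP and one EPP")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    mean_mepp = float(mepps.mean())
    mean_epp = float(np.mean(correct_nls(epps, params)))
    return QuantalSummary(
        mean_mepp_mv=mean_mepp,
        mepp_freq_hz=mepps.size / duration_s,
        mean_epp_mv=mean_epp,
        qc=quantal_content(mean_epp, mean_mepp),
        n_mepps=int(mepps.size),
        n_epps=int(epps.size),
    )
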