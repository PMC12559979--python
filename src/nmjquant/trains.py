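"""High-frequency train analysis: plasticity, cumulative QC, RRP and VRR.

During a 100 Hz, 0.5 s (50-stimulus) train the cumulative quantal content
plotted against stimulus number approaches a line once the readily
releasable pool (RRP) is depleted and release is sustained by
replenishment.  An ordinary least-squares line through the trailing 20
points estimates the vesicle replenishment rate (VRR, the slope, in
quanta/stimulus — also reported per second) and the RRP (the y-intercept at
stimulus number 0).  Synapses are stratified by quantal content into
low (< 65), medium (65-85, boundaries inclusive) and high (> 85) strata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "TrainRecording",
    "PlasticityProfile",
    "PoolEstimate",
    "PoolEstimator",
    "normalize_train",
    "stratify_qc",
    "cumulative_qc",
    "estimate_pool",
]


@dataclass
class TrainRecording:
    """Per-stimulus corrected EPP amplitudes and QC for one train."""

    freq_hz: float
    amplitudes_mv: np.ndarray
    qc_per_stimulus: np.ndarray | None = None
    synapse_id: str = ""
    age_group: str = ""

    def __post_init__(self) -> None:
        self.amplitudes_mv = np.asarray(self.amplitudes_mv, dtype=float)
        if self.freq_hz <= 0:
            raise ValueError("freq_hz must be positive")
        if self.qc_per_stimulus is not None:
            self.qc_per_stimulus = np.asarray(self.qc_per_stimulus, dtype=float)
            if self.qc_per_stimulus.size != self.amplitudes_mv.size:
                raise ValueError("qc_per_stimulus length must match amplitudes")
            if np.any(self.qc_per_stimulus < 0):
                raise ValueError("qc_per_stimulus must be non-negative")

    @property
    def n_stimuli(self) -> int:
        return self.amplitudes_mv.size

    def assign_qc(self, mean_mepp_mv: float) -> "TrainRecording":
        """Fill ``qc_per_stimulus`` from the synapse's mean mEPP amplitude."""
        if mean_mepp_mv <= 0:
            raise ValueError("mean mEPP amplitude must be positive")
        self.qc_per_stimulus = self.amplitudes_mv / mean_mepp_mv
        return self


@dataclass
class PlasticityProfile:
    """Short-term plasticity profile: amplitudes normalised to the first."""

    normalized: np.ndarray
    stimulus_index: np.ndarray  # 1-based


@dataclass
class PoolEstimate:
    """RRP/VRR estimate from the cumulative-QC linear extrapolation."""

    rrp_quanta: float
    vrr_quanta_per_stim: float
    vrr_quanta_per_s: float
    fit_r2: float
    fit_window: tuple[int, int]  # 1-based inclusive stimulus range used
    negative_intercept: bool = False


def normalize_train(amplitudes_mv: Sequence[float]) -> PlasticityProfile:
    """Divide every amplitude by the first; the first element is exactly 1."""
    a = np.asarray(amplitudes_mv, dtype=float)
    if a.size == 0:
        raise ValueError("amplitudes must be non-empty")
    if a[0] <= 0:
        raise ValueError("first amplitude must be positive")
    return PlasticityProfile(
        normalized=a / a[0], stimulus_index=np.arange(1, a.size + 1)
    )


def stratify_qc(qc: float, low_hi: float = 65.0, high_lo: float = 85.0) -> str:
    """Assign a QC value to the low / medium / high stratum.

    Medium is the closed interval [low_hi, high_lo] (65-85 by default, i.e.
    75 +/- 10); boundaries belong to medium.
    """
    if qc < 0:
        raise ValueError("qc must be non-negative")
    if low_hi > high_lo:
        raise ValueError("low_hi must not exceed high_lo")
    if qc < low_hi:
        return "low"
    if qc <= high_lo:
        return "medium"
    return "high"


def cumulative_qc(qc_per_stimulus: Sequence[float]) -> np.ndarray:
    """Running sum of per-stimulus QC (non-decreasing, same length)."""
    q = np.asarray(qc_per_stimulus, dtype=float)
    if np.any(q < 0):
        raise ValueError("qc_per_stimulus must be non-negative")
    return np.cumsum(q)


class PoolEstimator(RegressorMixin, BaseEstimator):
    """OLS line through the trailing cumulative-QC points.

    Fit ``cumulative QC ~ stimulus number`` (1-based) over the last
    ``fit_last_n`` stimuli.  Fitted attributes: ``rrp_quanta_`` (intercept at
    stimulus 0), ``vrr_quanta_per_stim_`` (slope), ``vrr_quanta_per_s_``
    (slope x frequency), ``fit_r2_``, ``fit_window_``.  Negative intercepts
    are reported as-is with ``negative_intercept_ = True``, never clipped.
    """

    def __init__(self, fit_last_n: int = 20, freq_hz: float = 100.0):
        self.fit_last_n = fit_last_n
        self.freq_hz = freq_hz

    def fit(self, X, y=None):
        """``X`` is a TrainRecording (with qc filled) or a per-stimulus QC array."""
        if isinstance(X, TrainRecording):
            if X.qc_per_stimulus is None:
                raise ValueError("TrainRecording has no qc_per_stimulus; call assign_qc")
            q = X.qc_per_stimulus
            freq = X.freq_hz
        else:
            q = np.asarray(X, dtype=float)
            freq = self.freq_hz
        if self.fit_last_n < 2:
            raise ValueError("fit_last_n must be >= 2")
        if q.size < self.fit_last_n + 1:
            raise ValueError(
                f"need at least fit_last_n+1={self.fit_last_n + 1} stimuli, got {q.size}"
            )
        cum = cumulative_qc(q)
        k = np.arange(1, q.size + 1, dtype=float)
        kw, cw = k[-self.fit_last_n :], cum[-self.fit_last_n :]
        # closed-form OLS (the independent oracle in tests re-derives this
        # from the normal equations)
        kbar, cbar = kw.mean(), cw.mean()
        sxx = float(np.sum((kw - kbar) ** 2))
        slope = float(np.sum((kw - kbar) * (cw - cbar)) / sxx)
        intercept = float(cbar - slope * kbar)
        pred = intercept + slope * kw
        ss_res = float(np.sum((cw - pred) ** 2))
        ss_tot = float(np.sum((cw - cbar) ** 2))
        self.vrr_quanta_per_stim_ = slope
        self.vrr_quanta_per_s_ = slope * freq
        self.rrp_quanta_ = intercept
        self.fit_r2_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        self.fit_window_ = (q.size - self.fit_last_n + 1, q.size)
        # tolerance keeps exact lines through the origin from being flagged
        # by rounding error
        self.negative_intercept_ = intercept < -1e-8 * max(1.0, float(np.abs(cw).max()))
        self.cumulative_ = cum
        return self

    def predict(self, stimulus_numbers) -> np.ndarray:
        """Fitted line evaluated at (1-based) stimulus numbers."""
        k = np.asarray(stimulus_numbers, dtype=float)
        return self.rrp_quanta_ + self.vrr_quanta_per_stim_ * k

    def to_estimate(self) -> PoolEstimate:
        return PoolEstimate(
            rrp_quanta=self.rrp_quanta_,
            vrr_quanta_per_stim=self.vrr_quanta_per_stim_,
            vrr_quanta_per_s=self.vrr_quanta_per_s_,
            fit_r2=self.fit_r2_,
            fit_window=self.fit_window_,
            negative_intercept=self.negative_intercept_,
        )


def estimate_pool(train: TrainRecording, fit_last_n: int = 20) -> PoolEstimate:
    """Functional wrapper over :class:`PoolEstimator`."""
    import warnings

    est = PoolEstimator(fit_last_n=fit_last_n).fit(train)
    if est.negative_intercept_:
        warnings.warn("fitted RRP intercept is negative; reported unclipped")
    return est.to_estimate()
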