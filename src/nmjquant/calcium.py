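"""Line-scan calcium-transient analysis (ΔF/F).

An XT line scan records one spatial line repeatedly; averaging each line
over the ROI columns gives a fluorescence time series F(t).  Baseline
fluorescence F0 is the mean of the 100 lines immediately preceding the
stimulus (configurable: the first 100 lines of the record are also
supported), ΔF/F(t) = 100*(F(t) - F0)/F0 in percent, and the reported peak
is the mean of ΔF/F over a fixed 20-line window starting at the first line
strictly after the stimulus — a windowed mean, not a maximum search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import tifffile
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "LineScanImage",
    "CalciumTransient",
    "DeltaFOverF",
    "roi_profile",
    "compute_dff",
    "analyze_linescan",
    "average_transients",
    "read_linescan_tiff",
    "write_linescan_tiff",
]


@dataclass
class LineScanImage:
    """Lines (time) x pixels (space) fluorescence record."""

    intensity: np.ndarray
    line_period_s: float
    stim_line: int
    roi_pixels: tuple[int, int]  # half-open column range covering the terminal
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("intensity must be 2-D (lines x pixels)")
        if self.line_period_s <= 0:
            raise ValueError("line_period_s must be positive")
        if not 0 <= self.stim_line < self.intensity.shape[0]:
            raise ValueError("stim_line outside the record")
        lo, hi = self.roi_pixels
        if not (0 <= lo < hi <= self.intensity.shape[1]):
            raise ValueError("roi_pixels outside the pixel range")

    @property
    def n_lines(self) -> int:
        return self.intensity.shape[0]


@dataclass
class CalciumTransient:
    """Normalised ΔF/F time course and its windowed peak (percent)."""

    dff_pct: np.ndarray
    baseline_f: float
    peak_dff_pct: float
    stim_line: int
    line_period_s: float


def roi_profile(image: LineScanImage) -> np.ndarray:
    """Per-line arithmetic mean over the ROI columns."""
    lo, hi = image.roi_pixels
    if hi <= lo:
        raise ValueError("empty ROI")
    return image.intensity[:, lo:hi].mean(axis=1)


class DeltaFOverF(TransformerMixin, BaseEstimator):
    """ΔF/F transformer for line-scan intensity series.

    Parameters
    ----------
    baseline_n, peak_n : int
        Baseline and peak window lengths in lines.
    baseline_mode : "adjacent" or "start"
        Baseline window immediately before the stimulus (default) or the
        first ``baseline_n`` lines of the record.

    Fitted attributes: ``baseline_f_``, ``peak_dff_pct_``, ``dff_pct_``.
    """

    def __init__(
        self,
        baseline_n: int = 100,
        peak_n: int = 20,
        baseline_mode: Literal["adjacent", "start"] = "adjacent",
    ):
        self.baseline_n = baseline_n
        self.peak_n = peak_n
        self.baseline_mode = baseline_mode

    def fit(self, series: np.ndarray, stim_line: int | None = None):
        f = np.asarray(series, dtype=float)
        if stim_line is None:
            raise ValueError("stim_line is required")
        if stim_line < self.baseline_n:
            raise ValueError("insufficient baseline lines before the stimulus")
        if f.size - stim_line - 1 < self.peak_n:
            raise ValueError("insufficient post-stimulus lines for the peak window")
        if self.baseline_mode == "adjacent":
            base = f[stim_line - self.baseline_n : stim_line]
        elif self.baseline_mode == "start":
            base = f[: self.baseline_n]
        else:
            raise ValueError("baseline_mode must be 'adjacent' or 'start'")
        f0 = float(base.mean())
        if f0 <= 0:
            raise ValueError("non-positive baseline fluorescence")
        dff = 100.0 * (f - f0) / f0
        self.baseline_f_ = f0
        self.dff_pct_ = dff
        self.peak_dff_pct_ = float(dff[stim_line + 1 : stim_line + 1 + self.peak_n].mean())
        return self

    def transform(self, series: np.ndarray, stim_line: int | None = None) -> np.ndarray:
        return self.fit(series, stim_line=stim_line).dff_pct_


def compute_dff(
    series: np.ndarray,
    stim_line: int,
    baseline_n: int = 100,
    peak_n: int = 20,
    baseline_mode: Literal["adjacent", "start"] = "adjacent",
    line_period_s: float = float("nan"),
) -> CalciumTransient:
    """ΔF/F (%) time course and windowed peak for one intensity series."""
    est = DeltaFOverF(baseline_n, peak_n, baseline_mode).fit(series, stim_line=stim_line)
    return CalciumTransient(
        dff_pct=est.dff_pct_,
        baseline_f=est.baseline_f_,
        peak_dff_pct=est.peak_dff_pct_,
        stim_line=stim_line,
        line_period_s=line_period_s,
    )


def analyze_linescan(
    image: LineScanImage,
    baseline_n: int = 100,
    peak_n: int = 20,
    baseline_mode: Literal["adjacent", "start"] = "adjacent",
) -> CalciumTransient:
    """ROI profile + ΔF/F in one call."""
    return compute_dff(
        roi_profile(image),
        image.stim_line,
        baseline_n=baseline_n,
        peak_n=peak_n,
        baseline_mode=baseline_mode,
        line_period_s=image.line_period_s,
    )


def average_transients(
    transients: Sequence[CalciumTransient], peak_n: int = 20
) -> CalciumTransient:
    """Element-wise mean of aligned ΔF/F series; the peak is recomputed from
    the averaged series over the same post-stimulus window."""
    if not transients:
        raise ValueError("need at least one transient")
    n = transients[0].dff_pct.size
    stim = transients[0].stim_line
    for tr in transients:
        if tr.dff_pct.size != n or tr.stim_line != stim:
            raise ValueError("transients must have equal length and aligned stim_line")
    mean_dff = np.mean([tr.dff_pct for tr in transients], axis=0)
    peak = float(mean_dff[stim + 1 : stim + 1 + peak_n].mean())
    return CalciumTransient(
        dff_pct=mean_dff,
        baseline_f=float(np.mean([tr.baseline_f for tr in transients])),
        peak_dff_pct=peak,
        stim_line=stim,
        line_period_s=transients[0].line_period_s,
    )


# ---------------------------------------------------------------------------
# TIFF I/O


def write_linescan_tiff(image: LineScanImage, path: str | Path) -> None:
    tifffile.imwrite(
        path,
        image.intensity.astype(np.float32),
        metadata={
            "line_period_s": image.line_period_s,
            "stim_line": image.stim_line,
            "roi_pixels": list(image.roi_pixels),
        },
    )


def read_linescan_tiff(
    path: str | Path,
    line_period_s: float | None = None,
    stim_line: int | None = None,
    roi_pixels: tuple[int, int] | None = None,
) -> LineScanImage:
    """Read a line-scan TIFF; acquisition metadata may come from the file's
    ImageJ/ShapedMetadata or be supplied explicitly."""
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    line_period_s = line_period_s if line_period_s is not None else meta.get("line_period_s")
    stim_line = stim_line if stim_line is not None else meta.get("stim_line")
    roi = roi_pixels if roi_pixels is not None else meta.get("roi_pixels")
    if line_period_s is None or stim_line is None:
        raise ValueError("line_period_s and stim_line must be in metadata or arguments")
    if roi is None:
        roi = (0, arr.shape[1])
    return LineScanImage(arr, float(line_period_s), int(stim_line), tuple(roi))
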