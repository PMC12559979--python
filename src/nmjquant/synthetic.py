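"""Synthetic quantal-release and imaging data with known ground truth.

Four generators emulate the statistical structure the analysis chain
assumes, so every downstream stage is testable without raw recordings:

* :func:`simulate_spontaneous` — Poisson-timed mEPPs on a noisy baseline.
* :func:`simulate_evoked` — well-separated EPPs (the 10-at-0.2 Hz protocol).
* :func:`simulate_train` — evoked amplitudes from a binomial
  depletion-replenishment pool model under high-frequency stimulation.
* :func:`simulate_linescan` / :func:`simulate_puncta_image` — a single
  stimulus-evoked fluorescence transient in XT line-scan geometry, and
  confocal-like puncta fields for density analysis.

Every generator takes an integer seed, is bit-reproducible for a fixed
seed, and returns a :class:`SimulationTruth` (or annotation) carrying the
ground truth for recovery tests.

The release model: before stimulus k the pool holds ``pool_k`` quanta; the
stimulus releases ``r_k ~ Binomial(pool_k, p_release)`` quanta whose linear
summed amplitude is ``v_lin``; the recorded amplitude saturates as
``v_obs = v_lin / (1 + f*v_lin/E)`` — the exact algebraic inverse of the
non-linear summation correction, so the correction round-trip is exact by
construction.  Between stimuli the pool refills at ``replenish_per_s``
(deterministic with fractional carry-over by default, optionally Poisson),
capped at ``pool_cap``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .calcium import LineScanImage
from .config import ReleaseModelConfig
from .density import PunctaAnnotation
from .quantal import NlsParams, correct_nls, saturate_nls
from .traces import VoltageTrace
from .trains import TrainRecording
from .waveforms import biexp_waveform

__all__ = [
    "SimulationTruth",
    "simulate_spontaneous",
    "simulate_evoked",
    "simulate_train",
    "simulate_linescan",
    "simulate_puncta_image",
]


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside each simulated recording."""

    event_times_s: list = field(default_factory=list)
    event_amplitudes_mv: list = field(default_factory=list)
    quanta_per_stimulus: list = field(default_factory=list)
    pool_trajectory: list = field(default_factory=list)  # pool before each stimulus
    linear_amplitudes_mv: list = field(default_factory=list)
    observed_amplitudes_mv: list = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SimulationTruth":
        return cls(**json.loads(Path(path).read_text()))


def _draw_quantal_amplitudes(rng, n, q_mv, q_cv):
    """Truncated-at-zero normal amplitudes (mean q_mv before truncation)."""
    if q_cv == 0:
        return np.full(n, q_mv, dtype=float)
    return np.clip(rng.normal(q_mv, q_cv * q_mv, n), 0.0, None)


def _render_events(
    n_samples: int,
    fs: float,
    times_s: np.ndarray,
    amps_mv: np.ndarray,
    rise_tau_ms: float,
    decay_tau_ms: float,
) -> np.ndarray:
    """Superimpose unit-peak waveforms scaled by per-event amplitudes."""
    v = np.zeros(n_samples)
    # render to 10 decay constants; tails below 5e-5 of peak are dropped
    tmpl_len = int(round(10.0 * decay_tau_ms * 1e-3 * fs))
    t_ms = np.arange(tmpl_len) / fs * 1e3
    tmpl = biexp_waveform(t_ms, rise_tau_ms, decay_tau_ms)
    for t0, a in zip(times_s, amps_mv):
        i0 = int(round(t0 * fs))
        seg = tmpl[: max(n_samples - i0, 0)]
        v[i0 : i0 + seg.size] += a * seg
    return v


def simulate_spontaneous(
    config: ReleaseModelConfig,
    duration_s: float,
    seed: int,
) -> tuple[VoltageTrace, SimulationTruth]:
    """Simulate a spontaneous recording of Poisson-timed mEPPs.

    Event times are homogeneous Poisson at ``mepp_rate_hz``; amplitudes are
    truncated-normal with mean ``q_mv`` and CV ``q_cv``; each event is a
    unit-peak difference-of-exponentials waveform; Gaussian noise of SD
    ``noise_sd_mv`` is added and the baseline sits at ``v_rest_mv``.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    fs = config.sample_rate_hz
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    n_events = rng.poisson(config.mepp_rate_hz * duration_s)
    # keep events fully inside the record so truth amplitudes are recoverable
    margin = min(10.0 * config.decay_tau_ms * 1e-3, duration_s)
    times = np.sort(rng.uniform(0.0, max(duration_s - margin, 0.0), n_events))
    amps = _draw_quantal_amplitudes(rng, n_events, config.q_mv, config.q_cv)
    v = _render_events(n, fs, times, amps, config.rise_tau_ms, config.decay_tau_ms)
    if config.noise_sd_mv > 0:
        v += rng.normal(0.0, config.noise_sd_mv, n)
    trace = VoltageTrace(
        v + config.v_rest_mv, fs, meta={"kind": "spontaneous", "seed": seed}
    )
    truth = SimulationTruth(
        event_times_s=times.tolist(),
        event_amplitudes_mv=amps.tolist(),
        config=config.to_dict(),
    )
    return trace, truth


def simulate_evoked(
    config: ReleaseModelConfig,
    n_stimuli: int = 10,
    freq_hz: float = 0.2,
    seed: int = 0,
    pre_s: float = 0.1,
) -> tuple[VoltageTrace, SimulationTruth]:
    """Simulate well-separated evoked EPPs (default: 10 at 0.2 Hz).

    Each stimulus releases a binomial draw from a full pool (no cumulative
    depletion: inter-stimulus intervals at 0.2 Hz dwarf the replenishment
    time).  Observed amplitudes pass through the forward saturation model.
    """
    if n_stimuli < 1 or freq_hz <= 0:
        raise ValueError("need n_stimuli >= 1 and positive freq_hz")
    fs = config.sample_rate_hz
    rng = np.random.default_rng(seed)
    isi = 1.0 / freq_hz
    stim_times = pre_s + np.arange(n_stimuli) * isi
    duration = stim_times[-1] + isi
    n = int(round(duration * fs))
    nls = NlsParams(config.f_nls, config.e_drive_mv)
    r = rng.binomial(config.n0, config.p_release, n_stimuli)
    v_lin = np.array(
        [
            _draw_quantal_amplitudes(rng, rk, config.q_mv, config.q_cv).sum()
            for rk in r
        ]
    )
    v_obs = saturate_nls(v_lin, nls)
    v = _render_events(
        n, fs, stim_times, v_obs, config.rise_tau_ms, config.decay_tau_ms
    )
    if config.noise_sd_mv > 0:
        v += rng.normal(0.0, config.noise_sd_mv, n)
    trace = VoltageTrace(
        v + config.v_rest_mv,
        fs,
        stimulus_times_s=stim_times,
        meta={"kind": "evoked", "seed": seed},
    )
    truth = SimulationTruth(
        event_times_s=stim_times.tolist(),
        quanta_per_stimulus=r.tolist(),
        linear_amplitudes_mv=v_lin.tolist(),
        observed_amplitudes_mv=np.asarray(v_obs).tolist(),
        config=config.to_dict(),
    )
    return trace, truth


def simulate_train(
    config: ReleaseModelConfig,
    n_stimuli: int = 50,
    freq_hz: float = 100.0,
    seed: int = 0,
    p_schedule=None,
) -> tuple[TrainRecording, SimulationTruth]:
    """Simulate per-stimulus EPP amplitudes for a high-frequency train.

    Implements the binomial depletion-replenishment recursion described in
    the module docstring.  Replenishment per inter-stimulus interval is
    ``replenish_per_s / freq_hz`` quanta, accumulated deterministically with
    fractional carry-over (or drawn Poisson when ``config.replenish_poisson``).
    The pool never goes negative and never exceeds ``pool_cap``.

    ``p_schedule`` is an optional per-stimulus multiplier on ``p_release``
    (facilitation hook); the product is clipped to [0, 1].

    Returns a :class:`TrainRecording` whose ``amplitudes_mv`` are the
    NLS-corrected observed amplitudes and ``qc_per_stimulus`` their ratio to
    the true mean quantal amplitude ``q_mv``, plus the full truth.
    """
    if n_stimuli < 1:
        raise ValueError("n_stimuli must be >= 1")
    if freq_hz <= 0:
        raise ValueError("freq_hz must be positive")
    if not 0.0 <= config.p_release <= 1.0:
        raise ValueError("p_release must be in [0, 1]")
    rng = np.random.default_rng(seed)
    nls = NlsParams(config.f_nls, config.e_drive_mv)
    repl_per_isi = config.replenish_per_s / freq_hz

    pool = int(config.n0)
    carry = 0.0
    r_list, pool_list, v_lin_list, v_obs_list = [], [], [], []
    for k in range(n_stimuli):
        pool_list.append(pool)
        p = config.p_release
        if p_schedule is not None:
            p = min(max(p * float(p_schedule[k]), 0.0), 1.0)
        r = int(rng.binomial(pool, p))
        v_lin = float(
            _draw_quantal_amplitudes(rng, r, config.q_mv, config.q_cv).sum()
        )
        v_obs = float(saturate_nls(v_lin, nls))
        if config.noise_sd_mv > 0:
            v_obs = max(v_obs + float(rng.normal(0.0, config.noise_sd_mv)), 0.0)
        r_list.append(r)
        v_lin_list.append(v_lin)
        v_obs_list.append(v_obs)
        pool -= r
        if config.replenish_poisson:
            add = int(rng.poisson(repl_per_isi))
        else:
            carry += repl_per_isi
            add = int(np.floor(carry + 1e-12))
            carry -= add
        pool = min(pool + add, int(config.pool_cap))
        assert pool >= 0

    corrected = correct_nls(np.array(v_obs_list), nls)
    recording = TrainRecording(
        freq_hz=freq_hz,
        amplitudes_mv=corrected,
        qc_per_stimulus=corrected / config.q_mv,
        synapse_id=f"sim-{seed}",
        age_group="synthetic",
    )
    truth = SimulationTruth(
        quanta_per_stimulus=r_list,
        pool_trajectory=pool_list,
        linear_amplitudes_mv=v_lin_list,
        observed_amplitudes_mv=v_obs_list,
        config=config.to_dict(),
    )
    return recording, truth


def simulate_linescan(
    baseline_f: float = 100.0,
    peak_dff_pct: float = 50.0,
    rise_tau_ms: float = 2.0,
    decay_tau_ms: float = 150.0,
    n_lines: int = 400,
    stim_line: int = 150,
    n_pixels: int = 64,
    line_period_s: float = 1.43e-3,
    noise_model: str = "none",
    noise_sd: float = 2.0,
    seed: int = 0,
) -> LineScanImage:
    """Simulate an XT line scan with one stimulus-evoked fluorescence transient.

    Per-line ROI-mean intensity is ``baseline_f * (1 + (peak_dff_pct/100) * g(t))``
    where g is a unit-peak difference of exponentials starting at the line
    after ``stim_line``.  ``noise_model`` is one of none / gaussian / poisson,
    applied per pixel.
    """
    if not 0 < stim_line < n_lines:
        raise ValueError("stim_line must lie strictly inside the record")
    if baseline_f <= 0:
        raise ValueError("baseline_f must be positive")
    if noise_model not in {"none", "gaussian", "poisson"}:
        raise ValueError("noise_model must be none, gaussian or poisson")
    rng = np.random.default_rng(seed)
    t_ms = (np.arange(n_lines) - (stim_line + 1)) * line_period_s * 1e3
    g = biexp_waveform(t_ms, rise_tau_ms, decay_tau_ms)
    profile = baseline_f * (1.0 + (peak_dff_pct / 100.0) * g)
    img = np.tile(profile[:, None], (1, n_pixels))
    if noise_model == "gaussian":
        img = img + rng.normal(0.0, noise_sd, img.shape)
    elif noise_model == "poisson":
        img = rng.poisson(img).astype(float)
    return LineScanImage(
        intensity=img,
        line_period_s=line_period_s,
        stim_line=stim_line,
        roi_pixels=(0, n_pixels),
        meta={"peak_dff_pct": peak_dff_pct, "seed": seed,
              "rise_tau_ms": rise_tau_ms, "decay_tau_ms": decay_tau_ms},
    )


def simulate_puncta_image(
    density_per_um2: float = 2.04,
    roi_area_um2: float = 100.0,
    pixel_um: float = 0.04,
    psf_sigma_um: float = 0.05,
    amplitude: float = 1.0,
    background: float = 0.1,
    noise_sd: float = 0.0,
    seed: int = 0,
    exact_count: bool = True,
    marker: str = "synthetic",
) -> tuple[np.ndarray, PunctaAnnotation]:
    """Simulate a confocal-like active-zone puncta field (square ROI).

    Places ``round(density*area)`` puncta (``exact_count``) or a Poisson draw
    uniformly in the ROI as Gaussian spots of SD ``psf_sigma_um`` and peak
    ``amplitude`` on a constant ``background``, plus optional Gaussian noise.
    Spot scales represent deconvolved confocal data.  The default density is
    the young-adult active-zone value (2.04 puncta/um^2).
    """
    if density_per_um2 < 0:
        raise ValueError("density must be non-negative")
    if roi_area_um2 <= 0 or pixel_um <= 0 or psf_sigma_um <= 0:
        raise ValueError("area, pixel size and PSF sigma must be positive")
    side_um = float(np.sqrt(roi_area_um2))
    n_px = int(round(side_um / pixel_um))
    if n_px < 1:
        raise ValueError("ROI smaller than one pixel")
    rng = np.random.default_rng(seed)
    n_true = (
        int(round(density_per_um2 * roi_area_um2))
        if exact_count
        else int(rng.poisson(density_per_um2 * roi_area_um2))
    )
    xy_um = rng.uniform(0.0, side_um, size=(n_true, 2))
    img = np.full((n_px, n_px), float(background))
    if n_true:
        yy, xx = np.mgrid[0:n_px, 0:n_px]
        sig_px = psf_sigma_um / pixel_um
        for x_um, y_um in xy_um:
            cx, cy = x_um / pixel_um, y_um / pixel_um
            # render each spot only within a local window for speed
            r = int(np.ceil(4 * sig_px)) + 1
            x0, x1 = max(int(cx) - r, 0), min(int(cx) + r + 1, n_px)
            y0, y1 = max(int(cy) - r, 0), min(int(cy) + r + 1, n_px)
            sub_y, sub_x = yy[y0:y1, x0:x1], xx[y0:y1, x0:x1]
            img[y0:y1, x0:x1] += amplitude * np.exp(
                -((sub_x - cx) ** 2 + (sub_y - cy) ** 2) / (2 * sig_px**2)
            )
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    ann = PunctaAnnotation(
        marker=marker,
        coordinates_um=xy_um,
        roi_area_um2=float(roi_area_um2),
        pixel_um=pixel_um,
    )
    return img, ann
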