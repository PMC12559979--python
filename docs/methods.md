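# Methods

This note documents the models, algorithms, defaults and numerical choices
behind `nmjquant`, and what the synthetic benchmarks do and do not
establish about real recordings.

## The release model

Evoked transmission is simulated as a binomial depletion–replenishment
process.  Before stimulus k the releasable pool holds `pool_k` quanta; the
stimulus releases `r_k ~ Binomial(pool_k, p_release)`.  Each released
quantum contributes an amplitude drawn from a normal distribution with
mean `q_mv` and CV `q_cv`, truncated at zero (truncation prevents negative
quanta while matching a mean ± SD parameterisation; at the default CV of
0.39 the truncated mass is ≈ 0.5%).  The linear sum v_lin then passes
through the saturation model

    v_obs = v_lin / (1 + f·v_lin/E),

the exact algebraic inverse of the non-linear summation correction
(below), so the correction round trip is exact by construction rather than
approximately calibrated.  Between stimuli the pool refills at
`replenish_per_s` quanta/s, applied per inter-stimulus interval as an
integer with deterministic carry-over of the fractional remainder (an
optional Poisson-replenishment flag exists, default off).  The carry-over
scheme makes the expectation recursion

    E[pool_{k+1}] = E[pool_k](1 − p) + R/freq

exact, which in turn makes the deterministic oracle used in the tests
exact.  The pool is clamped to `[0, pool_cap]`, with `pool_cap = n0` by
default.

Spontaneous activity is a homogeneous Poisson train of single quanta at
`mepp_rate_hz`.  Every event, spontaneous or evoked, has the canonical
difference-of-exponentials shape

    w(t) ∝ exp(−t/τ_d) − exp(−t/τ_r),

normalised to unit peak; its peak time and fractional rise times have
closed forms / one-dimensional root-finding solutions, which supply the
kinetics oracles.

### Default parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| `n0` | 1000 | quanta | with p = 0.08 gives first-stimulus QC ≈ 80, the young-adult value |
| `p_release` | 0.08 | – | see above |
| `q_mv` | 0.23 | mV | young-adult mEPP amplitude |
| `q_cv` | 0.39 | – | matches the reported mEPP SD/mean (0.09/0.23) |
| `mepp_rate_hz` | 5.33 | s⁻¹ | young-adult mEPP frequency |
| `rise_tau_ms` / `decay_tau_ms` | 0.8 / 3.5 | ms | give a 10–90% rise of ≈ 0.86 ms and fitted decay τ ≈ 3.5 ms, the young-adult kinetics |
| `replenish_per_s` | 1000 | quanta/s | 10 quanta per 100 Hz interval; sustains a steady-state release of 10 quanta/stimulus |
| `noise_sd_mv` | 0.02 | mV | a declared choice for a quiet sharp-electrode baseline; no measured value exists to infer it from |
| `v_rest_mv` | −70 | mV | typical curarised fibre resting potential |
| `f_nls` / `e_drive_mv` | 0.8 / 50 | – / mV | the classical correction constants (below) |
| `sample_rate_hz` | 10 000 | Hz | standard digitisation rate |

One integer seed governs each generator call through an independent
`numpy` Generator; all generators are bit-reproducible for a fixed seed.

## Filtering

Traces are low-pass filtered with a Gaussian filter whose −3 dB point is
at `cutoff_hz` (default 2000 Hz): H(f) = exp(−2π²σ_t²f²) with
σ_t = √(ln 2)/(2π·f_c).  At 2 kHz and 10 kHz sampling σ_t is only 0.66
samples, so a directly sampled kernel would alias (≈ 3% response error at
3 kHz).  The kernel is therefore designed in the frequency domain (4096
bins), truncated to ±256 samples and renormalised so the DC gain is
exactly 1; edges are handled by reflection.  The filter preserves the
trace mean to < 1e−9 mV and matches the analytic transfer function at
3 kHz to < 1%.

## Event detection

Baseline noise is estimated robustly from the first-difference (high-pass)
residual of the **raw** trace: σ̂ = MAD(Δv)/(0.6745·√2).  Sparse, smooth
synaptic events barely move this statistic.  Candidate events are
contiguous excursions of the filtered trace above
`median + threshold_sd·σ̂` (default 3.5); one event per excursion (this is
what prevents noise wiggles on a decay tail from double-counting), with
excursions whose onsets fall within `min_interval_ms` (default 5 ms) of
the previous onset merged into the earlier event.  Because the threshold
references the raw noise while the search runs on the filtered trace
(whose noise SD is ≈ 0.65× the raw SD at these settings), the effective
threshold in filtered-noise units is ≈ 5.4 SD and the Gaussian upcrossing
false-positive rate is negligible.  Each candidate must finally rise a
full threshold above its local pre-onset baseline (mean of the preceding
1 ms); re-crossings of a decaying tail fail this criterion and are
rejected.  Amplitude is reported baseline-to-peak against that local
baseline.  A 0.1 µV absolute threshold floor keeps noiseless traces free
of rounding-level detections.

On 60 s synthetic recordings with amplitude/noise-SD = 5 this detector
achieves ≈ 0.96 sensitivity at a false discovery rate < 0.01 (the
residual misses are dominated by genuinely overlapping Poisson events
closer than the 5 ms merge interval); on noiseless, well-separated events
recovery is exact.

## Kinetics

Rise time is the 10–90% interval (fractions configurable), with crossing
times linearly interpolated between samples; the search window starts 1 ms
before the event onset because a detector's onset is its threshold
crossing, which already sits above the 10% level.  Decay is the time
constant of a single-exponential least-squares fit.  The default fit
window runs from the 90% point after the peak down to the 10% point
("90-10"); fitting from the peak itself is available but biases τ upward
by ≈ 1.5% on the biexponential shape because the fast rise component has
not fully decayed at the peak.  The window is located on a lightly
smoothed (0.5 ms boxcar) copy of the decay so a single downward noise
excursion cannot truncate the segment at a local dip — without this the
fitted τ is biased low by tens of percent at realistic noise.  The fit
itself uses the raw samples, initialised log-linearly from the positive
samples.  Both measures are invariant to amplitude scaling and DC offsets.
Events whose rise fractions cannot be bracketed are flagged unmeasurable,
never silently dropped.  Note that 2 kHz filtering broadens the decay
slightly: the fitted τ of the default template measured through the full
filter-and-detect chain is ≈ 3.75 ms for a generating τ_d of 3.5 ms.

## Non-linear summation and quantal content

Recorded EPP amplitudes are corrected as v' = v/(1 − f·v/E).  The source
constants are not published for this workflow, so the classical defaults
f = 0.8, E = 50 mV are used and both are exposed in `NlsParams`.  mEPPs
are not corrected: at 0.2 mV the correction is < 0.5%.  QC is the mean
corrected EPP divided by the same synapse's mean mEPP.  Synapses are
stratified by QC into low (< 65), medium (65–85, boundaries inclusive —
the printed ranges leave exact boundary membership open, and the closed
medium interval is the declared choice) and high (> 85).

## Train analysis: RRP and VRR

Per-stimulus QC values are cumulated and an OLS line is fitted to the last
`fit_last_n` (default 20) points of cumulative QC vs. 1-based stimulus
number.  The slope is the VRR (quanta/stimulus; also reported ×frequency
as quanta/s because the literature is inconsistent about the unit), and
the intercept — evaluated at stimulus number 0 — is the RRP.  Negative
intercepts are reported as-is with a warning flag, never clipped.  The
default train is 50 stimuli at 100 Hz (0.5 s); train length is
configurable.

A known property of this estimator, reproduced exactly by the
expectation-recursion oracle in the tests: at the default operating point
(n0 = 1000, p = 0.08, 10 quanta/stimulus replenishment) the depletion
transient decays with a time constant of 1/p = 12.5 stimuli, so at 50
stimuli the 31–50 fit window still contains transient release and the
expected fitted slope is ≈ 12.7 quanta/stimulus with intercept ≈ 730 —
not the steady-state 10 and n0 = 1000.  Simulated recovery converges to
the recursion's prediction, and approaches the asymptotic values
(slope → 10, intercept → n0 − steady-state pool = 875) only for trains of
≳ 75 stimuli.  Users comparing ages should therefore hold the train
length fixed across groups, as the underlying protocol does.

## Line-scan ΔF/F

The ROI (a column range; line scans are one-dimensional in space) is
averaged per line to give F(t).  Baseline F₀ is the mean of the
`baseline_n` = 100 lines immediately preceding the stimulus line; a
"first 100 lines of the record" mode is provided, with the adjacent
window as the default reading.  ΔF/F(t) = 100·(F(t) − F₀)/F₀.  The
reported peak is the mean over the fixed `peak_n` = 20 lines starting at
the first line strictly after the stimulus — a windowed mean by
definition, not a maximum search, so for fast-rising transients the
reported peak is the window average of the underlying transient (≈ 88% of
the programmed peak for the default 2 ms rise / 150 ms decay / 1.43 ms
line period), which the closed-form window-average oracle in the tests
computes exactly.  ΔF/F is exactly invariant to multiplicative gain;
additive offsets shift it by the analytic amount tested numerically.
Averaging across images is element-wise on aligned ΔF/F series with the
peak recomputed from the averaged series.

## Puncta detection and density

Spot detection is Gaussian smoothing (default σ 0.02 µm at 0.04 µm
pixels — half a typical deconvolved-spot σ, suppressing pixel noise while
merging as few neighbouring spots as possible) followed by strict 3×3
local maxima above `median + 4·robust-SD` of the smoothed image, then a
brightness-ordered Euclidean collapse of maxima closer than
`min_separation_um` (default 0.06 µm; ties resolve to the smaller
row-major index).  The collapse is done explicitly rather than through a
square suppression footprint, which would over-suppress diagonal
neighbours.  On noiseless well-separated spots recovery is exact to one
pixel; at spot SNR 5 and 2 puncta/µm² mean recall is ≈ 0.96 — the
irreducible losses are point pairs closer than the ≈ 2σ resolution limit
of the blurred image, which no local-maxima detector can split.  Density
is count/ROI-area per marker, averaged across markers (with a shared ROI,
count-level and density-level averaging coincide).  Manual counts can be
supplied directly, bypassing detection, and dual-observer counts are
averaged arithmetically.

## Group statistics

Deliberately standard procedures, delegated to scipy/statsmodels: one-way
ANOVA + Tukey HSD (studentized range; unadjusted pairwise p values use the
pooled-MSE t on N−k df, and the Tukey-adjusted p is never smaller), a
type-II two-way ANOVA with interaction, the pooled-variance unpaired t
test (Welch optional), and simple linear regression with a two-sided slope
t test.  Tests validate them against algebraic identities (two-group
F = t²), brute-force sums of squares, normal-equation solutions, and
vectorised permutation oracles (50 000 label shuffles for the t test;
max-studentized-range shuffles for Tukey).

## What the synthetic benchmarks do not show

The generator reproduces the statistical structure the analyses assume —
Poisson event timing, binomial release with saturation, stationary
Gaussian noise, a single clean fluorescence transient, isotropic Gaussian
spots on uniform background.  Real recordings add baseline drift, seal
and electrode instability, stimulus artifacts with ringing, fibre-to-fibre
input-resistance differences, dye bleaching and motion, and non-uniform
labelling; performance figures (detection sensitivity/FDR, spot recall)
are therefore upper bounds for field data, while the arithmetic stages
(correction, QC, cumulative fits, ΔF/F, density) are exact regardless.
Animal-level nesting is deliberately not modelled: synapses are treated as
independent units, mirroring the underlying design.

## Problem sizes and runtime

The shipped benchmarks use 60 s recordings at 10 kHz (20 seeds for
detection), 100-seed train and ΔF/F ensembles, 100 µm² puncta fields at
0.04 µm pixels (20 seeds), and 20 000–50 000-shuffle permutation oracles —
sizes chosen so the whole suite runs in well under a minute on one CPU
while keeping Monte-Carlo errors small relative to the tolerances tested.
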