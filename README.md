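# nmjquant

Quantal analysis of neurotransmission at the ageing mouse neuromuscular
junction (NMJ): miniature/evoked endplate-potential detection and kinetics,
quantal content with non-linear summation correction, short-term plasticity
and readily-releasable-pool estimation from 100 Hz stimulus trains,
line-scan calcium ΔF/F analysis, active-zone puncta density, and the group
statistics used to compare age groups.  A synthetic quantal-release and
imaging generator with known ground truth drives the test suite, so every
stage is verifiable without raw recordings.

## Who it is for

Electrophysiologists and synapse biologists who record intracellular
endplate potentials, line-scan calcium transients or confocal active-zone
images and want a scripted, reproducible version of the standard desk
analyses (pClamp + ImageJ + spreadsheet workflows).

## The quantities it computes

* **Quantal content** QC = mean corrected EPP / mean mEPP of the same
  synapse.  Recorded EPP amplitudes v are first corrected for non-linear
  summation, v' = v / (1 − f·v/E), with f = 0.8 and driving force
  E = 50 mV by default.
* **RRP and VRR.**  During a 100 Hz, 0.5 s train the cumulative QC vs.
  stimulus number approaches a line; ordinary least squares over the last
  20 stimuli gives the vesicle replenishment rate (slope, quanta/stimulus)
  and the readily releasable pool (y-intercept at stimulus 0, quanta).
* **Event kinetics.**  10–90% rise time and single-exponential decay τ of
  detected events; both amplitude- and offset-invariant.
* **ΔF/F (%).**  (raw F − baseline F)/baseline F × 100 per line of an XT
  line scan; baseline = mean of the 100 lines before the stimulus, peak =
  mean of the 20 lines after it.
* **Active-zone density.**  Marker puncta (e.g. piccolo, RIMBP2) counted
  inside the AChR-defined ROI, divided by ROI area (puncta/µm²), averaged
  across markers.
* **Group statistics.**  One-way ANOVA with Tukey's HSD, two-way ANOVA
  (type-II), unpaired t test, simple linear regression; mean ± SD reports.

## Worked example

Simulate one young-adult synapse (mEPP ≈ 0.23 mV at ≈ 5.3 /s, pool of 1000
quanta released with p = 0.08), run the full protocol — 1 min of
spontaneous recording, 10 EPPs at 0.2 Hz, one 50-stimulus 100 Hz train —
and recover its quantal parameters:

```python
from nmjquant import (ReleaseModelConfig, NlsParams, detect_mepps, extract_evoked,
                      simulate_spontaneous, simulate_evoked, simulate_train,
                      summarize_synapse, estimate_pool, stratify_qc)

cfg = ReleaseModelConfig()          # young-adult NMJ phenotype
sp, _ = simulate_spontaneous(cfg, 60.0, seed=7)
mepps = detect_mepps(sp)
ev, _ = simulate_evoked(cfg, n_stimuli=10, seed=8)
epps = extract_evoked(ev, window_ms=25.0)
s = summarize_synapse([m.amplitude_mv for m in mepps],
                      [e.amplitude_mv for e in epps],
                      60.0, NlsParams(cfg.f_nls, cfg.e_drive_mv))
print(f"mEPP: {s.mean_mepp_mv:.3f} mV at {s.mepp_freq_hz:.2f} /s  (n={s.n_mepps})")
print(f"EPP (NLS-corrected): {s.mean_epp_mv:.2f} mV  ->  QC = {s.qc:.1f} ({stratify_qc(s.qc)})")

train, _ = simulate_train(cfg, n_stimuli=50, freq_hz=100.0, seed=9)
pool = estimate_pool(train, fit_last_n=20)
print(f"RRP = {pool.rrp_quanta:.0f} quanta, VRR = {pool.vrr_quanta_per_stim:.1f} quanta/stimulus"
      f" ({pool.vrr_quanta_per_s:.0f} quanta/s), r^2 = {pool.fit_r2:.4f}")
```

Output:

```
mEPP: 0.240 mV at 4.88 /s  (n=293)
EPP (NLS-corrected): 18.79 mV  ->  QC = 78.2 (medium)
RRP = 693 quanta, VRR = 13.9 quanta/stimulus (1394 quanta/s), r^2 = 0.9917
```

The detected mEPP amplitude and frequency recover the generator's settings
within sampling error, the corrected EPP mean implies a quantal content of
≈ 78 ≈ n0·p = 80 (a "medium" synapse in the 65–85 stratum), and the
cumulative-QC line is nearly perfect (r² = 0.99).  The fitted slope sits
above the programmed replenishment rate of 10 quanta/stimulus because a
50-stimulus train ends before the depletion transient (time constant
1/p = 12.5 stimuli) has decayed inside the fit window — an inherent
property of the last-20-stimuli extrapolation at this train length that
`docs/methods.md` quantifies.

A command-line interface mirrors these stages
(`nmjquant simulate|detect|quantal|train|calcium|density|stats`; see
`nmjquant --help`).

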