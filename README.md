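# xentrain

Analysis toolkit for **cross-modal entrainment**: does a continuous,
rhythmic *sound* pace visual perception and visual cortical activity?

The experimental paradigm this package analyzes presents a 2-s narrow-band
noise whose pitch is frequency-modulated at 3 Hz (constant energy, clear
rhythm) while observers discriminate the orientation (45°/135°) of a brief,
masked Gabor grating presented at one of 20 phases of the FM cycle, with EEG
recorded throughout. The package provides:

- **Stimulus synthesis** — the 3-Hz FM narrow-band noise (37.5 % depth,
  30-component carrier, 333-ms Hann ramps, four onset phases), the 20-phase
  target grid (8° + 18°·k), and Gabor/mask rendering.
- **Synthetic cohort generation** — behavioral sessions with
  `d′(φ) = b + A·cos(φ − φ_pref)`, 3-down-1-up staircase simulation, and EEG
  epochs with a von Mises phase-locked 3-Hz component in 1/f noise, with
  full ground truth retained.
- **Behavioral entrainment** — trial filtering, phase-binned
  `d′ = z(H) − z(FA)` with the log-linear correction, ±2-bin circular
  smoothing, Johnson–Wehrly–Mardia circular-linear correlation with a
  bin-shuffle permutation null (`z = (r − μ)/σ`), single-cycle sine fitting
  and preferred-phase extraction, Rayleigh and one-sample t group tests.
- **Neural entrainment** — epoch realignment to FM phase 0, spherical-spline
  surface Laplacian (CSD), inter-trial phase coherence (ITPC) from six-cycle
  Hanning-tapered windows (1–10 Hz × 100-ms steps), band extraction
  (2.5–3.5 Hz × 500–1000 ms vs. −800…−300 ms baseline), arcsine-transformed
  paired t tests, first/second-cycle splits.
- **Group linkage** — k-means (k = 3) grouping on behavioral entrainment,
  linear-trend contrast of visual ITPC across groups (df (1, N−3)), and
  Spearman correlation between neural and behavioral entrainment.

## Worked example

```python
import numpy as np
import xentrain as xt

# a strongly entrained observer: d'(phi) = 1.57 + 0.8 cos(phi - 98.4 deg)
obs = xt.ObserverModel(mod_amplitude=0.8, preferred_phase_rad=np.deg2rad(98.4))
trials = xt.simulate_behavior(obs, seed=7)           # one 640-trial session
res, prof, rep = xt.analyze_subject(trials, n_perm=1000, seed=7)

print("retained", rep["n_retained"], "of", rep["n_total"])
print(f"mean d' = {prof.dprime_raw.mean():.2f}")
print(f"circular-linear r = {res.circ_linear_r:.3f}")
print(f"permutation z = {res.perm_z:.2f}, p = {res.perm_p:.4f}")
print(f"preferred phase = {np.rad2deg(res.peak_phase_rad):.1f} deg (truth 98.4)")
```

prints

```
retained 577 of 640
mean d' = 1.53
circular-linear r = 0.974
permutation z = 1.48, p = 0.0030
preferred phase = 94.0 deg (truth 98.4)
```

63 trials fall to the response-window/blink filters (the generator plants
realistic exclusion rates); the phase-binned d′ profile tracks the planted
cosine, the permutation test rejects the no-modulation null (p ≈ 0.003), and
the sine fit recovers the planted preferred phase to within ~4°.

The same flows are available from the shell:

```bash
xentrain run-all --seed 1 --out-dir out/          # simulate + analyze cohort
xentrain analyze-behavior --trials out/subjects/S01_trials.csv --n-perm 1000 --seed 1
xentrain analyze-eeg --epochs out/subjects/S01_epochs.h5 --band 2.5:3.5 --window 500:1000
xentrain group --summary out/subject_summary.csv --seed 1
```

`run-all` writes per-subject trial CSVs and epoch HDF5 files, per-stage
result tables, and a `group_report.json` with the cluster centers, the
visual-ITPC linear-trend F and its p-value, and the Spearman ρ between
neural and behavioral entrainment.

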