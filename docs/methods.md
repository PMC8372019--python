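# Methods

`xentrain` implements a complete analysis chain for cross-modal entrainment
experiments in which a continuous frequency-modulated (FM) sound rhythmically
modulates visual discrimination and entrains EEG activity. This note records
the models, the numerical conventions, and the design choices made where the
procedure admitted more than one reasonable reading.

## Stimulus model

The auditory driver is a 2-s narrow-band noise whose *frequency* is modulated
sinusoidally at `f_m = 3 Hz` while its amplitude stays constant — perceptual
rhythm without rhythmic energy. The carrier is a sum of 30 components with
base frequencies drawn uniformly from a 500-Hz band centered on `f_0 ∈ {800,
1000, 1200} Hz`, each with an independent uniform starting phase. All
components share one modulator: component `c` follows

    dθ_c/dt = 2π f_c (1 + m · sin(2π f_m t + φ_0)),

with modulation depth `m = 0.375` interpreted as the peak fractional
excursion of instantaneous frequency relative to the component's own base
frequency (a single 1000-Hz component sweeps 625–1375 Hz). The depth
reference is not uniquely determined by a verbal description ("37.5 %
depth"); this convention keeps the frequency trajectory sinusoidal and the
excursion proportional to carrier frequency. The waveform is RMS-normalized
and faded in/out with raised-cosine half-windows of exactly one modulation
cycle (333.3 ms). WAV export is 16-bit PCM at 48 kHz, peak-normalized to
−3 dBFS after RMS equalization.

Phase 0 of the modulator is its rising zero-crossing; the trial-wise onset
phase takes one of four values (0, π/2, π, 3π/2). Visual targets occupy 20
phases, 8° + 18°·k (k = 0…19), realized as onset times inside a 1000–1666-ms
window; each phase has two eligible modulation cycles and the cycle is chosen
uniformly at random per trial (reducing temporal predictability). Because the
stochastic carrier beats on ~10-ms timescales, short-window RMS fluctuates by
design ~±15 % even without modulation; the meaningful invariant — verified in
the tests — is the absence of any systematic energy modulation at 3 Hz
(compared against a matched amplitude-modulated control).

The Gabor target (2.5 cycles/degree, 45° or 135°, 2° aperture) and its
10-cpd mask use a radial windowing kernel
`f(x, y) = 2·exp(−((x² + y²)/(2σ) − μ)²) − 1` with σ = 0.30, μ = 0. This
kernel circulates in a typographically ambiguous form; the reading adopted
here is the one that yields 1 at the center, −1 in the far field, and a ≈2°
aperture at σ = 0.30, consistent with its purpose as a soft aperture.

## Behavioral model and analysis

The synthetic observer inverts the analysis: sensitivity follows
`d′(φ) = b + A·cos(φ − φ_pref)` with baseline `b = 1.57` (the empirical group
mean) and equal-variance SDT responses — hit probability `Φ(d′/2 − c)` for
45° (signal) targets, false-alarm probability `Φ(−d′/2 − c)` for 135° (noise)
targets, criterion `c = 0`, lapse rate 2 %. Sessions hold 640 trials: 32 per
phase, 16 per orientation. A configurable 8.9 % of trials get responses
outside the 100–1000-ms window (or none) and 1.46 % carry blink flags,
mirroring reported exclusion rates so the filter bookkeeping is exercised.

Analysis per subject:

1. **Filtering.** Keep trials with a response at RT ∈ [100, 1000] ms (closed
   interval — inclusivity is not specified verbally, so the boundary is fixed
   here) and no blink in the −500…+100-ms window around the target.
2. **d′ per phase** with the log-linear correction
   `H = (hits + 0.5)/(n₄₅ + 1)`, `FA = (fa + 0.5)/(n₁₃₅ + 1)`,
   `d′ = probit(H) − probit(FA)` — finite for every count table.
3. **Circular smoothing**: unweighted ±2-bin moving average with wrap-around;
   preserves the profile mean. The 20 phases span one phase cycle (laid out
   over two temporal cycles); all circular operations work on the single
   phase circle.
4. **Circular-linear correlation** (Johnson–Wehrly–Mardia):
   `r² = (r_xc² + r_xs² − 2 r_xc r_xs r_cs)/(1 − r_cs²)`. We report `r`
   (values in [0, 1]); whether `r` or `r²` is the conventional report is
   ambiguous, and `r` is documented here as the package's convention.
5. **Permutation inference**: shuffle the 20 *raw* d′ values across phase
   bins, re-smooth, recompute r, 1000 iterations;
   `z = (r_obs − μ_perm)/σ_perm`, add-one p-value. Shuffling is bin-level,
   not trial-level, and the observed statistic is computed on the smoothed
   profile exactly as each permutation is.
6. **Single-cycle sine fit** `y = A·sin(2π f_m x + φ) + b` with
   `x = phase/(360 f_m)` seconds. The model is linear in
   `(A cos φ, A sin φ, b)`, so the fit is solved by exact linear least
   squares — the same 3-parameter optimum a Levenberg–Marquardt search
   converges to, without initialization or convergence concerns. Output is
   canonicalized to `A ≥ 0`, `φ ∈ [0, 2π)`. The preferred (peak) phase is
   `(π/2 − φ) mod 2π = 2π f_m · argmax`.
7. **Group level**: one-sample t of permutation z-scores against 0 (Cohen's
   d = mean/sd); Rayleigh test (`z = nR²`, standard series approximation) of
   preferred phases across subjects.

## Staircase simulation

Contrast calibration uses a 3-down-1-up rule on a log₁₀ contrast grid (step
0.05), three blocks of 12 reversals, block threshold = mean contrast of the
last eight reversals, final threshold = mean of blocks. The simulated
psychometric function is `p(c) = 0.5 + (0.5 − λ)·Φ(s·(log₁₀ c − log₁₀ c*))`
with slope `s = 3` per decade. The rule's stationary accuracy is the
analytic balance point `p³ = ½` (≈ 79.4 %), which the tests verify on long
staircases; note that the *12-reversal protocol estimate* sits systematically
above it (~86 % accuracy here) because blocks start well above threshold and
reversal averages are taken in linear contrast units. (The protocol is
sometimes described as targeting ~70 % accuracy; that figure is inconsistent
with the 3-down-1-up asymptote, and it is the rule itself that is simulated.)

## EEG model and analysis

Synthetic epochs are anchored to sound onset, sampled at 500 samples/s
(250 in the reduced test configurations), and span −2000…+4350 ms so that
realignment can consume up to one modulation cycle. During stimulation
(0–2000 ms, Hann-ramped like the sound) every channel receives a 3-Hz
sinusoid with trial phase = FM onset phase + a fixed subject lag + von Mises
jitter of concentration `κ_lock` (κ → ∞ is implemented as zero jitter; κ = 0
as uniform phase). Channel gains: 1.0 on the eight auditory electrodes (FC3,
FC5, FC4, FC6, TP7, P7, TP8, P8), 0.5 on the three visual electrodes (O1,
Oz, O2), 0.15 elsewhere, all scaled by an SNR of 0.4 relative to unit-RMS
1/f background noise (power exponent α = 1 plus a white floor — a generic
EEG spectrum; the real recordings' noise is of course richer). An optional
Gaussian target-evoked transient can be added on visual channels. Expected
ITPC under this model is ≈ I₁(κ)/I₀(κ) of the von Mises jitter at high SNR,
which the generator reproduces (κ = 2 → ≈ 0.70).

Analysis:

- **Realignment.** Trials are shifted so t = 0 is the modulator's first
  rising phase-0: shift = ((2π − φ_onset) mod 2π)/(2π·3) s, rounded to the
  nearest sample (at 500 Hz the π and 3π/2 onsets imply non-integer shifts;
  the ≤1-ms rounding costs ≤1.1° of 3-Hz phase). Epochs are cropped to
  −2000…+4000 ms and baseline-corrected over −150…0 ms.
- **Surface Laplacian.** Spherical-spline current-source density via MNE
  (stiffness m = 4, regularization λ = 1e-5, standard 10-05 electrode
  positions). Refused below 16 channels, where the spline is
  ill-conditioned. Because the Laplacian is reference-free, the synthetic
  pipeline ignores mastoid re-referencing entirely.
- **ITPC.** For each frequency (1–10 Hz in 0.1-Hz steps by default) a
  six-cycle window is centered on each 100-ms-step time point (center
  convention), Hanning-tapered, and zero-padded to the next power of two ≥ 4×
  the window; the coefficient at the padded-grid bin nearest the target
  frequency is normalized to unit magnitude and ITPC is the magnitude of the
  trial average. Cells whose window exceeds the epoch are *missing* (NaN),
  never zero-filled. Entrainment strength is the mean over 2.5–3.5 Hz ×
  500–1000 ms; baseline uses −800…−300 ms. With six-cycle windows the
  low-frequency baseline cells necessarily draw some support from the
  stimulation period (backward smearing); the baseline window is the one
  furthest from both the realignment point and the stimulation window that
  the epoch supports.
- **Statistics.** ITPC values are arcsine-transformed (`asin(√x)`, the
  standard stabilizer for [0, 1] proportions — "arcsine transform" is not
  otherwise specified) before paired t tests of stimulation vs. baseline.
  The transform is monotone, so orderings are unaffected.
- **Cycle split.** ITPC is recomputed separately for trials whose target fell
  in the first (≈1000–1333 ms) or second (≈1333–1667 ms) cycle of the target
  window; subsets below 20 trials raise a warning.
- The joint-probability rejection of high-variance epochs used on real
  recordings is a declared no-op here: synthetic epochs contain no
  non-stereotypical artifacts, and the hook exists only for interface parity.

## Group linkage

Subjects are clustered on their circular-linear correlations by 1-D k-means
(k = 3, 50 restarts, seeded; labels low/medium/high by ascending center —
group sizes are emergent, not preset). A linear-trend contrast with weights
(−1, 0, +1) on the group means of (arcsine-transformed, by default) visual
ITPC uses the pooled within-group mean square: F with df (1, N − 3) — for
N = 28 that is (1, 25). A tie-aware Spearman correlation between visual ITPC
and behavioral r probes the same linkage continuously. Cluster labels depend
only on behavior, never on ITPC.

## Cohort defaults

28 subjects in low/medium/high groups of 7/11/10. Behavioral modulation
amplitudes per group: 0.05/0.4/0.8 (±0.05 between-subject spread); EEG
phase-locking κ per group: 0.2/0.8/2.0. When `coupled=True` the two run in
lockstep (the hypothesis under study: neural entrainment mediates behavioral
entrainment); `coupled=False` shuffles the κ assignment across subjects,
severing the linkage while preserving marginals — the null configuration for
calibration checks. Preferred phases are von Mises around 98.4° (the
empirical mean direction) with κ = 1.2, acknowledging the large
between-subject phase spread. Ground truth (observer parameters, κ, group)
is serialized into every epoch file so recovery tests are self-contained.

## Problem sizes in the validation suite

The suite verifies inference calibration on 1000 null subjects (permutation
count 200), Rayleigh uniformity on 10,000 replicates, phase recovery on 60
subjects at 640 trials, and the group linkage on 50 coupled + 50 decoupled
28-subject cohorts simulated at 250 samples/s with 240 trials and the 11
analysis electrodes — sizes chosen so the full suite runs on a single CPU in
minutes while keeping Monte-Carlo error well below every asserted margin.

## What the generator does and does not emulate

It reproduces the statistical structure the analysis assumes: cosine phase
dependence of d′, balanced designs with realistic exclusion rates, von Mises
phase locking with auditory/visual gain topography in 1/f noise, and a
behavioral–neural coupling across groups. It does not model volume
conduction or head geometry (channel gains are assigned, not forward
modeled), ocular or muscular artifacts, evoked responses beyond an optional
Gaussian transient, non-stationary noise, or drifting attention. Passing
tests therefore certify the *analysis chain* — its statistics, calibration,
and invariances — not the physiological realism of the simulated EEG.

## Known limitations

- The surface Laplacian presumes the standard 10-05 position for every
  channel label; custom montages with non-standard labels are not supported.
- ITPC cells near epoch edges are missing by construction; analyses
  requesting unsupported band/window combinations fail loudly rather than
  extrapolate.
- The permutation z-score is computed from 1000 (default) permutations of
  only 20 bins; ties in the null distribution make p-values slightly
  conservative, which the calibration tests bound.
- Realignment shifts are rounded to whole samples (≤1.1° of 3-Hz phase at
  500 Hz).
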