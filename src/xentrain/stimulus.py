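"""Frequency-modulated sound synthesis and visual-target geometry.

The auditory driver is a 2-s narrow-band noise whose *frequency* (not
amplitude) is modulated sinusoidally at 3 Hz, so the stimulus carries a clear
perceptual rhythm while its energy stays flat over time.  Visual Gabor targets
are placed at 20 phases of that 3-Hz cycle, spread over two modulation cycles
inside a 1000-1666 ms window after sound onset.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal.windows import hann

__all__ = [
    "ONSET_PHASES",
    "FMStimulusSpec",
    "TargetPhaseGrid",
    "GaborMaskSpec",
    "synthesize_fm_waveform",
    "fm_phase_at_time",
    "build_target_grid",
    "mask_kernel",
    "render_gabor",
]

#: Allowed trial-wise onset phases of the frequency modulator (radians).
ONSET_PHASES = (0.0, np.pi / 2, np.pi, 3 * np.pi / 2)

#: Allowed carrier center frequencies (Hz).
CARRIER_CENTERS = (800.0, 1000.0, 1200.0)


@dataclass(frozen=True)
class FMStimulusSpec:
    """Parameters of one frequency-modulated narrow-band noise stimulus.

    ``mod_depth`` is the peak fractional excursion of instantaneous frequency
    relative to each component's base frequency, so a single component at
    ``f0`` sweeps between ``f0*(1 - depth)`` and ``f0*(1 + depth)``.
    """

    carrier_center_hz: float = 1000.0
    n_components: int = 30
    component_band_hz: float = 500.0  # total width, uniform around the center
    mod_rate_hz: float = 3.0
    mod_depth: float = 0.375
    duration_s: float = 2.0
    sample_rate_hz: float = 48_000.0
    ramp_s: float = 1.0 / 3.0  # one modulation cycle
    onset_phase_rad: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.mod_depth < 1.0):
            raise ValueError(
                f"mod_depth must be in [0, 1); got {self.mod_depth} "
                "(>= 1 would drive instantaneous frequency through zero)"
            )
        if self.ramp_s > self.duration_s / 2:
            raise ValueError("ramp_s must not exceed half the stimulus duration")
        if not any(np.isclose(self.onset_phase_rad, p) for p in ONSET_PHASES):
            raise ValueError(
                f"onset_phase_rad must be one of {ONSET_PHASES}; got {self.onset_phase_rad}"
            )
        if self.carrier_center_hz - self.component_band_hz / 2 <= 0:
            raise ValueError("component band extends to non-positive frequencies")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")

    def with_onset(self, onset_phase_rad: float) -> "FMStimulusSpec":
        return replace(self, onset_phase_rad=onset_phase_rad)


def synthesize_fm_waveform(spec: FMStimulusSpec) -> np.ndarray:
    """Synthesize the FM narrow-band noise as mono float samples.

    Each of the ``n_components`` carrier components, with base frequency
    ``f_c`` drawn uniformly from the 500-Hz band around the center, follows
    the common phase trajectory

        dtheta/dt = 2*pi*f_c*(1 + depth*sin(2*pi*f_m*t + onset_phase))

    i.e. all components are frequency-modulated coherently by one 3-Hz
    modulator.  The sum is RMS-normalized (unit RMS on the plateau is fixed at
    export time; here the full waveform has RMS 1 before ramping) and faded
    in/out with raised-cosine half-windows of one modulation cycle.
    """
    fs = spec.sample_rate_hz
    n = round(spec.duration_s * fs)
    t = np.arange(n) / fs
    rng = np.random.default_rng(spec.rng_seed)

    half_band = spec.component_band_hz / 2
    f_c = rng.uniform(
        spec.carrier_center_hz - half_band,
        spec.carrier_center_hz + half_band,
        spec.n_components,
    )
    start_phase = rng.uniform(0.0, 2 * np.pi, spec.n_components)

    # integral of (1 + depth*sin(2*pi*fm*t + phi0)) dt, zero at t = 0
    fm = spec.mod_rate_hz
    phi0 = spec.onset_phase_rad
    if spec.mod_depth > 0:
        warp = t - spec.mod_depth * (
            np.cos(2 * np.pi * fm * t + phi0) - np.cos(phi0)
        ) / (2 * np.pi * fm)
    else:
        warp = t

    wave = np.sin(
        2 * np.pi * f_c[:, None] * warp[None, :] + start_phase[:, None]
    ).sum(axis=0)

    wave /= np.sqrt(np.mean(wave**2))

    n_ramp = round(spec.ramp_s * fs)
    if n_ramp > 0:
        w = hann(2 * n_ramp)
        wave[:n_ramp] *= w[:n_ramp]
        wave[-n_ramp:] *= w[n_ramp:]
    return wave


def fm_phase_at_time(spec: FMStimulusSpec, t_s: float) -> float:
    """Phase of the 3-Hz frequency modulator at time ``t_s`` after sound onset.

    Phase 0 is the rising zero-crossing of the modulator sinusoid — the same
    anchor used to re-align EEG epochs.
    """
    t_s = float(t_s)
    if not (0.0 <= t_s <= spec.duration_s):
        raise ValueError(f"t_s={t_s} outside the stimulus [0, {spec.duration_s}] s")
    return float(
        (spec.onset_phase_rad + 2 * np.pi * spec.mod_rate_hz * t_s) % (2 * np.pi)
    )


@dataclass(frozen=True)
class TargetPhaseGrid:
    """The 20 target phases (8 deg + 18 deg steps) and their onset-time map.

    Targets appear after at least 1 s of stimulation; each phase has two
    eligible onsets (first/second modulation cycle) inside the 1000-1666 ms
    window, which cycle is used being a per-trial choice.
    """

    phases_deg: np.ndarray
    window_ms: tuple[float, float] = (1000.0, 1666.0)
    mod_rate_hz: float = 3.0

    @property
    def n_phases(self) -> int:
        return len(self.phases_deg)

    def target_time_s(
        self, phase_deg: float, onset_phase_rad: float, cycle: int
    ) -> float:
        """Onset time (s after sound onset) realizing ``phase_deg`` in the
        first (``cycle=1``) or second (``cycle=2``) eligible modulation cycle."""
        if cycle not in (1, 2):
            raise ValueError("cycle must be 1 or 2")
        phase_rad = np.deg2rad(phase_deg)
        period = 1.0 / self.mod_rate_hz
        # first time >= window start with modulator phase == phase_rad
        delta = (phase_rad - onset_phase_rad) % (2 * np.pi)
        t = delta / (2 * np.pi * self.mod_rate_hz)
        t_min = self.window_ms[0] / 1000.0
        while t < t_min:
            t += period
        t += (cycle - 1) * period
        if t * 1000.0 > self.window_ms[1]:
            raise ValueError(
                f"phase {phase_deg} deg, cycle {cycle} falls outside the "
                f"{self.window_ms} ms target window"
            )
        return float(t)


def build_target_grid(
    n_phases: int = 20,
    first_phase_deg: float = 8.0,
    step_deg: float = 18.0,
    window_ms: tuple[float, float] = (1000.0, 1666.0),
    mod_rate_hz: float = 3.0,
) -> TargetPhaseGrid:
    """Build the target-phase grid: 20 phases {8, 26, ..., 350} degrees."""
    phases = (first_phase_deg + step_deg * np.arange(n_phases)) % 360.0
    return TargetPhaseGrid(
        phases_deg=phases, window_ms=window_ms, mod_rate_hz=mod_rate_hz
    )


@dataclass(frozen=True)
class GaborMaskSpec:
    """Geometry of the Gabor target and its higher-frequency mask."""

    target_spatial_freq_cpd: float = 2.5
    mask_spatial_freq_cpd: float = 10.0
    orientation_deg: float = 45.0
    diameter_deg: float = 2.0
    kernel_sigma: float = 0.30
    kernel_mu: float = 0.0
    contrast: float = 1.0

    def __post_init__(self) -> None:
        if self.orientation_deg not in (45.0, 135.0):
            raise ValueError("orientation_deg must be 45 or 135")
        if not (0.0 <= self.contrast <= 1.0):
            raise ValueError("contrast must be in [0, 1]")


def mask_kernel(x, y, spec: GaborMaskSpec = GaborMaskSpec()):
    """Radial Gaussian-derived kernel used to window targets and masks.

    Implements ``f(x, y) = 2*exp(-((x^2 + y^2)/(2*sigma) - mu)^2) - 1`` with
    sigma = 0.30 and mu = 0, which is 1 at the center and approaches -1 with
    increasing radius.  (The kernel formula circulates in a typographically
    ambiguous form; this reading keeps the unit center value, the [-1, 1]
    range, and a ~2-degree aperture at sigma = 0.30.)
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r2 = x**2 + y**2
    val = 2.0 * np.exp(-((r2 / (2.0 * spec.kernel_sigma) - spec.kernel_mu) ** 2)) - 1.0
    return np.clip(val, -1.0, 1.0)


def render_gabor(spec: GaborMaskSpec, size_px: int) -> np.ndarray:
    """Render an oriented Gabor patch as a ``size_px`` x ``size_px`` array.

    Coordinates span the 2-degree aperture; the grating (cosine luminance
    profile at the requested cycles/degree and orientation) is windowed by the
    radial kernel rescaled to [0, 1] and scaled by ``contrast``.  Values lie
    in [-1, 1] around the mean-gray background.
    """
    if size_px <= 0:
        raise ValueError("size_px must be positive")
    deg_per_px = spec.diameter_deg / size_px
    coords = (np.arange(size_px) - (size_px - 1) / 2) * deg_per_px
    x, y = np.meshgrid(coords, coords)
    theta = np.deg2rad(spec.orientation_deg)
    carrier = np.cos(
        2 * np.pi * spec.target_spatial_freq_cpd * (x * np.cos(theta) + y * np.sin(theta))
    )
    window = (mask_kernel(x, y, spec) + 1.0) / 2.0
    return spec.contrast * carrier * window
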