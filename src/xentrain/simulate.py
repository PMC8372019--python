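"""Synthetic behavioral sessions and EEG epochs with known ground truth.

The generator inverts the analysis model: visual sensitivity follows
``d'(phi) = baseline + A*cos(phi - phi_pref)`` over the 20 target phases of
the 3-Hz FM sound, and EEG epochs carry a 3-Hz component whose trial-wise
phase locks to the FM phase with von Mises concentration ``kappa_lock``,
embedded in 1/f noise with separate auditory/visual channel gains.  A
simulated observer also runs the 3-down-1-up contrast staircase used to set
target contrast.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from scipy.fft import rfft, irfft, rfftfreq
from scipy.signal.windows import hann

from .eeg import AUDITORY_ELECTRODES, VISUAL_ELECTRODES, EpochSet
from .stimulus import ONSET_PHASES, TargetPhaseGrid, build_target_grid

__all__ = [
    "ObserverModel",
    "CohortConfig",
    "SyntheticSubject",
    "DEFAULT_SIM_CHANNELS",
    "simulate_behavior",
    "simulate_staircase",
    "simulate_eeg_epochs",
    "generate_cohort",
]

#: Default simulated montage: both analysis electrode sets plus central/parietal
#: context channels so the spherical-spline Laplacian is well-conditioned.
DEFAULT_SIM_CHANNELS = AUDITORY_ELECTRODES + VISUAL_ELECTRODES + (
    "Fz", "FCz", "Cz", "CPz", "Pz", "POz", "C3", "C4", "PO3", "PO4",
)


@dataclass
class ObserverModel:
    """Ground-truth observer for behavior and staircase simulation.

    ``baseline_dprime`` mirrors the empirical group mean sensitivity (1.57);
    ``mod_amplitude`` is the depth of the cosine modulation of d' over FM
    phase and must not drive d' negative.  ``contrast_slope`` is the probit
    slope of the 2AFC psychometric function per log10 contrast unit.
    """

    baseline_dprime: float = 1.57
    mod_amplitude: float = 0.0
    preferred_phase_rad: float = 0.0
    criterion: float = 0.0
    contrast_slope: float = 3.0
    threshold_contrast: float = 0.05
    lapse_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.baseline_dprime - abs(self.mod_amplitude) < 0:
            raise ValueError(
                "infeasible observer: d' would be negative at some phase "
                f"(baseline {self.baseline_dprime}, amplitude {self.mod_amplitude})"
            )
        if not (0.0 <= self.lapse_rate <= 0.1):
            raise ValueError("lapse_rate must lie in [0, 0.1]")

    def dprime_at(self, phase_rad) -> np.ndarray:
        return self.baseline_dprime + self.mod_amplitude * np.cos(
            np.asarray(phase_rad) - self.preferred_phase_rad
        )

    def p_correct_2afc(self, contrast) -> np.ndarray:
        """2AFC orientation-discrimination accuracy vs. contrast."""
        c = np.log10(np.asarray(contrast, dtype=float))
        c0 = np.log10(self.threshold_contrast)
        core = stats.norm.cdf(self.contrast_slope * (c - c0))
        return 0.5 + (0.5 - self.lapse_rate) * core


def simulate_behavior(
    observer: ObserverModel,
    design: TargetPhaseGrid | None = None,
    n_trials: int = 640,
    seed: int | np.random.Generator = 0,
    rt_outside_frac: float = 0.089,
    blink_frac: float = 0.0146,
    subject: str = "S01",
) -> pd.DataFrame:
    """Simulate one session of the cross-modal discrimination task.

    Trials are balanced: ``n_trials/20`` per target phase, half 45-degree and
    half 135-degree targets.  Responses follow equal-variance SDT with hit
    probability ``Phi(d'/2 - criterion)`` and false-alarm probability
    ``Phi(-d'/2 - criterion)``.  A configurable fraction of trials gets an RT
    outside the 100-1000 ms response window (or no response at all) and a
    configurable fraction carries a blink flag, to exercise trial filtering.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if design is None:
        design = build_target_grid()
    n_phases = design.n_phases
    if n_trials % (2 * n_phases):
        raise ValueError(
            f"n_trials must be divisible by 2*{n_phases} for balanced orientations"
        )
    per_phase = n_trials // n_phases

    phase_deg = np.repeat(design.phases_deg, per_phase)
    orientation = np.tile(
        np.repeat([45, 135], per_phase // 2), n_phases
    )
    order = rng.permutation(n_trials)
    phase_deg, orientation = phase_deg[order], orientation[order]

    onset_idx = rng.integers(0, len(ONSET_PHASES), size=n_trials)
    onset_phase = np.asarray(ONSET_PHASES)[onset_idx]
    cycle = rng.integers(1, 3, size=n_trials)
    # (phase, onset, cycle) -> onset time lookup table
    time_table = np.array(
        [
            [
                [design.target_time_s(p, o, c) * 1000.0 for c in (1, 2)]
                for o in ONSET_PHASES
            ]
            for p in design.phases_deg
        ]
    )
    phase_idx = np.searchsorted(design.phases_deg, phase_deg)
    target_time_ms = time_table[phase_idx, onset_idx, cycle - 1]

    dprime = observer.dprime_at(np.deg2rad(phase_deg))
    p45 = np.where(
        orientation == 45,
        stats.norm.cdf(dprime / 2 - observer.criterion),
        stats.norm.cdf(-dprime / 2 - observer.criterion),
    )
    p45 = (1 - observer.lapse_rate) * p45 + observer.lapse_rate * 0.5
    response = np.where(rng.random(n_trials) < p45, 45, 135)

    rt = 100.0 + rng.lognormal(mean=np.log(300.0), sigma=0.35, size=n_trials)
    rt = np.clip(rt, 105.0, 995.0)
    outside = rng.random(n_trials) < rt_outside_frac
    kind = rng.integers(0, 3, size=n_trials)
    no_resp = outside & (kind == 0)
    rt = np.where(outside & (kind == 1), rng.uniform(0.0, 99.0, n_trials), rt)
    rt = np.where(outside & (kind == 2), rng.uniform(1001.0, 1720.0, n_trials), rt)
    response = np.where(no_resp, 0, response)
    rt = np.where(no_resp, np.nan, rt)

    blink = rng.random(n_trials) < blink_frac

    return pd.DataFrame(
        {
            "subject": subject,
            "trial": np.arange(n_trials),
            "onset_phase_rad": onset_phase,
            "target_phase_deg": phase_deg,
            "target_time_ms": target_time_ms,
            "orientation": orientation,
            "response": response,
            "rt_ms": rt,
            "blink": blink,
        }
    )


def simulate_staircase(
    observer: ObserverModel,
    seed: int | np.random.Generator = 0,
    start_contrast: float = 0.5,
    step_log10: float = 0.05,
    n_blocks: int = 3,
    n_reversals: int = 12,
    n_average: int = 8,
    max_trials_per_block: int = 2000,
) -> tuple[float, list[dict]]:
    """Simulate the 3-down-1-up contrast staircase for Gabor calibration.

    Contrast moves on a log10 grid: down one step after three consecutive
    correct responses, up one step after any error.  A block ends after
    ``n_reversals`` direction reversals; its threshold is the mean contrast
    of the last ``n_average`` reversals, and the returned estimate is the
    arithmetic mean over ``n_blocks`` blocks.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    block_thresholds = []
    details = []
    for _ in range(n_blocks):
        log_c = np.log10(start_contrast)
        correct_streak = 0
        last_direction = 0
        reversal_contrasts: list[float] = []
        visited: list[float] = []
        n_trials = 0
        while len(reversal_contrasts) < n_reversals:
            n_trials += 1
            visited.append(10**log_c)
            if n_trials > max_trials_per_block:
                raise RuntimeError(
                    "staircase failed to converge within the trial cap"
                )
            correct = rng.random() < observer.p_correct_2afc(10**log_c)
            direction = 0
            if correct:
                correct_streak += 1
                if correct_streak == 3:
                    direction = -1
                    correct_streak = 0
            else:
                direction = +1
                correct_streak = 0
            if direction:
                if last_direction and direction != last_direction:
                    reversal_contrasts.append(10**log_c)
                last_direction = direction
                log_c += direction * step_log10
        threshold = float(np.mean(reversal_contrasts[-n_average:]))
        block_thresholds.append(threshold)
        details.append(
            {"threshold": threshold, "n_trials": n_trials,
             "reversals": reversal_contrasts, "visited_contrasts": visited}
        )
    return float(np.mean(block_thresholds)), details


def simulate_eeg_epochs(
    trials: pd.DataFrame,
    kappa_lock: float,
    subject_lag_rad: float = 0.0,
    eeg_snr: float = 0.4,
    visual_gain: float = 0.5,
    other_gain: float = 0.15,
    channels: tuple[str, ...] = DEFAULT_SIM_CHANNELS,
    sfreq: float = 500.0,
    epoch_window_ms: tuple[float, float] = (-2000.0, 4350.0),
    noise_alpha: float = 1.0,
    white_frac: float = 0.3,
    target_evoked_amp: float = 0.0,
    seed: int | np.random.Generator = 0,
    mod_rate_hz: float = 3.0,
) -> EpochSet:
    """Simulate epoched EEG phase-locked to the FM stimulus.

    Epochs are anchored to sound onset (t = 0) and span ``epoch_window_ms``
    (the extra 350 ms past +4000 leaves room for phase realignment).  During
    stimulation (0-2000 ms) every channel receives a 3-Hz sinusoid with
    trial-wise phase = FM onset phase + subject lag + von Mises jitter of
    concentration ``kappa_lock`` (``kappa_lock = inf`` means zero jitter),
    scaled by ``eeg_snr`` times a channel gain profile (auditory electrodes
    1.0, visual electrodes ``visual_gain``, remaining channels
    ``other_gain``) relative to unit-RMS 1/f background noise.  Optionally a
    target-evoked transient is added on visual channels at the target time.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    channels = list(channels)
    required = set(AUDITORY_ELECTRODES) | set(VISUAL_ELECTRODES)
    missing = sorted(required - set(channels))
    if missing:
        raise ValueError(f"montage lacks required electrodes: {missing}")

    n_tr = len(trials)
    dt_ms = 1000.0 / sfreq
    n_t = int(round((epoch_window_ms[1] - epoch_window_ms[0]) / dt_ms))
    times_ms = epoch_window_ms[0] + dt_ms * np.arange(n_t)
    n_ch = len(channels)

    # 1/f^alpha background with a white floor, unit RMS per channel/trial
    white = rng.standard_normal((n_ch, n_t, n_tr)).astype(np.float32)
    spec = rfft(white, axis=1)
    f = rfftfreq(n_t, d=1.0 / sfreq)
    shape = np.empty_like(f)
    shape[0] = 0.0
    shape[1:] = f[1:] ** (-noise_alpha / 2)
    shape[1:] = shape[1:] / shape[1:].max()
    shape = shape + white_frac
    noise = irfft(spec * shape[None, :, None], n=n_t, axis=1)
    noise /= noise.std(axis=1, keepdims=True)

    # entrained 3-Hz component during stimulation, Hann-ramped like the sound
    onset_phase = trials["onset_phase_rad"].to_numpy(dtype=float)
    if np.isinf(kappa_lock):
        jitter = np.zeros(n_tr)
    elif kappa_lock == 0:
        jitter = rng.uniform(-np.pi, np.pi, n_tr)
    else:
        jitter = rng.vonmises(0.0, kappa_lock, n_tr)
    phase = onset_phase + subject_lag_rad + jitter

    stim_sel = (times_ms >= 0.0) & (times_ms < 2000.0)
    t_stim = times_ms[stim_sel] / 1000.0
    carrier = np.sin(
        2 * np.pi * mod_rate_hz * t_stim[None, :] + phase[:, None]
    )  # trial x time
    n_ramp = int(round(sfreq / mod_rate_hz))
    envelope = np.ones(stim_sel.sum())
    w = hann(2 * n_ramp)
    envelope[:n_ramp] = w[:n_ramp]
    envelope[-n_ramp:] = w[n_ramp:]
    carrier *= envelope[None, :]

    gains = np.full(n_ch, other_gain)
    for i, ch in enumerate(channels):
        if ch in AUDITORY_ELECTRODES:
            gains[i] = 1.0
        elif ch in VISUAL_ELECTRODES:
            gains[i] = visual_gain

    data = noise.astype(np.float32)
    data[:, stim_sel, :] += (
        eeg_snr * gains[:, None, None] * carrier.T[None, :, :]
    ).astype(np.float32)

    if target_evoked_amp and "target_time_ms" in trials.columns:
        vis_idx = [i for i, ch in enumerate(channels) if ch in VISUAL_ELECTRODES]
        t_target = trials["target_time_ms"].to_numpy(dtype=float)
        for j in range(n_tr):
            resp = target_evoked_amp * np.exp(
                -0.5 * ((times_ms - t_target[j] - 120.0) / 40.0) ** 2
            )
            data[vis_idx, :, j] += resp.astype(np.float32)

    meta = trials.copy().reset_index(drop=True)
    if "target_cycle" not in meta.columns and "target_time_ms" in meta.columns:
        meta["target_cycle"] = np.where(meta["target_time_ms"] < 1333.0, 1, 2)
    return EpochSet(data, times_ms, channels, sfreq, meta)


@dataclass
class CohortConfig:
    """Study-level configuration for the synthetic cohort.

    Group sizes mirror the empirical low/medium/high cross-modal behavioral
    entrainment split (7/11/10).  Behavioral modulation amplitude and EEG
    phase-locking concentration co-vary across groups when ``coupled`` is
    True; with ``coupled=False`` the EEG locking levels are shuffled across
    subjects, severing the neuro-behavioral link while preserving the
    marginals.
    """

    group_sizes: dict = field(
        default_factory=lambda: {"low": 7, "medium": 11, "high": 10}
    )
    mod_amplitude: dict = field(
        default_factory=lambda: {"low": 0.05, "medium": 0.4, "high": 0.8}
    )
    kappa_lock: dict = field(
        default_factory=lambda: {"low": 0.2, "medium": 0.8, "high": 2.0}
    )
    baseline_dprime: float = 1.57
    preferred_phase_mu_rad: float = np.deg2rad(98.4)
    preferred_phase_kappa: float = 1.2
    eeg_snr: float = 0.4
    visual_gain: float = 0.5
    n_trials: int = 640
    rt_outside_frac: float = 0.089
    blink_frac: float = 0.0146
    channels: tuple[str, ...] = DEFAULT_SIM_CHANNELS
    sfreq: float = 500.0
    epoch_window_ms: tuple[float, float] = (-2000.0, 4350.0)
    coupled: bool = True
    include_eeg: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be positive")
        if any(k < 0 for k in self.kappa_lock.values()):
            raise ValueError("kappa_lock must be >= 0")
        if self.n_trials % 40:
            raise ValueError("n_trials must be divisible by 40 (20 phases x 2 orientations)")


@dataclass
class SyntheticSubject:
    """One simulated participant with full ground truth retained."""

    subject_id: str
    group: str
    observer: ObserverModel
    kappa_lock: float
    trials: pd.DataFrame
    epochs: EpochSet | None = None

    def ground_truth_json(self) -> str:
        truth = asdict(self.observer)
        truth.update({"kappa_lock": self.kappa_lock, "group": self.group})
        return json.dumps(truth)


def generate_cohort(config: CohortConfig | None = None) -> list[SyntheticSubject]:
    """Generate the synthetic cohort (default 28 subjects in groups 7/11/10)."""
    if config is None:
        config = CohortConfig()
    rng = np.random.default_rng(config.rng_seed)
    design = build_target_grid()

    groups = [g for g, n in config.group_sizes.items() for _ in range(n)]
    amps = [
        max(0.0, rng.normal(config.mod_amplitude[g], 0.05)) for g in groups
    ]
    kappas = [
        max(0.0, rng.normal(config.kappa_lock[g], 0.1 * max(config.kappa_lock[g], 0.5)))
        for g in groups
    ]
    if not config.coupled:
        kappas = list(rng.permutation(kappas))

    subjects = []
    for i, group in enumerate(groups):
        observer = ObserverModel(
            baseline_dprime=config.baseline_dprime,
            mod_amplitude=min(amps[i], config.baseline_dprime),
            preferred_phase_rad=float(
                rng.vonmises(config.preferred_phase_mu_rad, config.preferred_phase_kappa)
                % (2 * np.pi)
            ),
        )
        sid = f"S{i + 1:02d}"
        trials = simulate_behavior(
            observer,
            design,
            n_trials=config.n_trials,
            seed=rng,
            rt_outside_frac=config.rt_outside_frac,
            blink_frac=config.blink_frac,
            subject=sid,
        )
        epochs = None
        if config.include_eeg:
            epochs = simulate_eeg_epochs(
                trials,
                kappa_lock=kappas[i],
                subject_lag_rad=float(rng.uniform(0, 2 * np.pi)),
                eeg_snr=config.eeg_snr,
                visual_gain=config.visual_gain,
                channels=config.channels,
                sfreq=config.sfreq,
                epoch_window_ms=config.epoch_window_ms,
                seed=rng,
            )
        subjects.append(
            SyntheticSubject(
                subject_id=sid,
                group=group,
                observer=observer,
                kappa_lock=float(kappas[i]),
                trials=trials,
                epochs=epochs,
            )
        )
    return subjects
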