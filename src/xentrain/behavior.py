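"""Phase-resolved visual sensitivity and cross-modal behavioral entrainment.

Per subject: filter trials, bin responses by the 20 FM-stimulus phases,
compute d' with the log-linear correction, smooth circularly, quantify the
phase dependence with a circular-linear correlation against a bin-shuffle
permutation null, and summarize the preferred phase with a single-cycle sine
fit.  Group level: one-sample t on permutation z-scores and a Rayleigh test
on preferred phases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DPrimeProfile",
    "EntrainmentResult",
    "filter_trials",
    "dprime_by_phase",
    "circular_moving_average",
    "circ_linear_corr",
    "permutation_entrainment",
    "fit_single_cycle_sine",
    "peak_phase",
    "rayleigh_test",
    "group_z_test",
    "analyze_subject",
]

#: Response window for counting a trial (ms after target onset), closed interval.
RT_WINDOW_MS = (100.0, 1000.0)

TRIAL_COLUMNS = [
    "subject",
    "trial",
    "onset_phase_rad",
    "target_phase_deg",
    "target_time_ms",
    "orientation",
    "response",
    "rt_ms",
    "blink",
]


def filter_trials(trials: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Apply the behavioral retention rules.

    Keeps trials with a response whose RT lies in the closed [100, 1000] ms
    window and no blink around target presentation (-500 to +100 ms, carried
    as a precomputed flag).  Returns the retained table and a count report.
    """
    responded = trials["response"].isin([45, 135]) & trials["rt_ms"].notna()
    rt_ok = responded & trials["rt_ms"].between(*RT_WINDOW_MS, inclusive="both")
    no_blink = ~trials["blink"].astype(bool)
    keep = rt_ok & no_blink
    report = {
        "n_total": int(len(trials)),
        "n_no_response": int((~responded).sum()),
        "n_rt_outside": int((responded & ~rt_ok).sum()),
        "n_blink": int((~no_blink).sum()),
        "n_retained": int(keep.sum()),
    }
    return trials.loc[keep].copy(), report


@dataclass
class DPrimeProfile:
    """Phase-binned visual sensitivity (raw and circularly smoothed)."""

    phases_deg: np.ndarray
    dprime_raw: np.ndarray
    dprime_smoothed: np.ndarray
    n_trials_per_phase: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.phases_deg)
        for name in ("dprime_raw", "dprime_smoothed", "n_trials_per_phase"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != number of phases ({n})")

    @property
    def phases_rad(self) -> np.ndarray:
        return np.deg2rad(self.phases_deg)


def _dprime_loglinear(hits, n_signal, fas, n_noise):
    """d' with the log-linear correction: finite for all count tables."""
    h = (np.asarray(hits, float) + 0.5) / (np.asarray(n_signal, float) + 1.0)
    fa = (np.asarray(fas, float) + 0.5) / (np.asarray(n_noise, float) + 1.0)
    return stats.norm.ppf(h) - stats.norm.ppf(fa)


def dprime_by_phase(
    trials: pd.DataFrame,
    phases_deg: np.ndarray | None = None,
    smooth_halfwidth: int = 2,
) -> DPrimeProfile:
    """Signal-detection sensitivity per target phase.

    45-degree targets are the signal condition, 135-degree the noise
    condition; a 45 response is a hit on signal trials and a false alarm on
    noise trials.  The log-linear correction (hits+0.5, FAs+0.5, trial counts
    +1) keeps d' finite at 0% and 100% rates.
    """
    if phases_deg is None:
        phases_deg = np.sort(trials["target_phase_deg"].unique())
    phases_deg = np.asarray(phases_deg, dtype=float)

    n_bins = len(phases_deg)
    target = trials["target_phase_deg"].to_numpy(dtype=float)
    codes = np.searchsorted(phases_deg, target)
    codes = np.clip(codes, 0, n_bins - 1)
    # accept tiny float noise in the phase column, reject off-grid phases
    snapped = np.isclose(phases_deg[codes], target)
    low = np.clip(codes - 1, 0, n_bins - 1)
    codes = np.where(snapped, codes, low)
    if not np.isclose(phases_deg[codes], target).all():
        raise ValueError("trial target phases do not match the phase grid")

    orient = trials["orientation"].to_numpy()
    resp45 = (trials["response"].to_numpy() == 45)
    sig = orient == 45
    n45 = np.bincount(codes[sig], minlength=n_bins)
    n135 = np.bincount(codes[~sig], minlength=n_bins)
    hits = np.bincount(codes[sig & resp45], minlength=n_bins)
    fas = np.bincount(codes[~sig & resp45], minlength=n_bins)
    n_per = n45 + n135
    if (n45 == 0).any() or (n135 == 0).any():
        missing = phases_deg[(n45 == 0) | (n135 == 0)]
        raise ValueError(
            f"phase bins with no trials of one orientation: {missing.tolist()}"
        )
    raw = _dprime_loglinear(hits, n45, fas, n135)
    smoothed = circular_moving_average(raw, halfwidth=smooth_halfwidth)
    return DPrimeProfile(phases_deg, raw, smoothed, n_per)


def circular_moving_average(values: np.ndarray, halfwidth: int = 2) -> np.ndarray:
    """Unweighted moving average over angular bins with wrap-around.

    Each output bin is the mean of itself and ``halfwidth`` neighbors on each
    side (a 5-bin window at the default +/-2).  Preserves the profile mean.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if 2 * halfwidth + 1 > n:
        raise ValueError("window exceeds number of bins")
    out = np.zeros_like(values)
    for k in range(-halfwidth, halfwidth + 1):
        out += np.roll(values, k)
    return out / (2 * halfwidth + 1)


def _smoothing_matrix(n: int, halfwidth: int = 2) -> np.ndarray:
    s = np.zeros((n, n))
    for i in range(n):
        for k in range(-halfwidth, halfwidth + 1):
            s[i, (i + k) % n] = 1.0 / (2 * halfwidth + 1)
    return s


def circ_linear_corr(phases_rad: np.ndarray, values: np.ndarray) -> float:
    """Circular-linear correlation (Johnson-Wehrly-Mardia coefficient).

    r^2 = (r_xc^2 + r_xs^2 - 2 r_xc r_xs r_cs) / (1 - r_cs^2) with r_xc, r_xs
    the Pearson correlations of the values with cos(phase) and sin(phase) and
    r_cs the correlation between cos and sin.  Returns r in [0, 1].
    """
    phases_rad = np.asarray(phases_rad, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(phases_rad) != len(values) or len(values) < 4:
        raise ValueError("need equal-length inputs with n >= 4")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    if np.std(values) == 0:
        raise ValueError("zero-variance values: circular-linear r undefined")
    c, s = np.cos(phases_rad), np.sin(phases_rad)
    r_xc = np.corrcoef(values, c)[0, 1]
    r_xs = np.corrcoef(values, s)[0, 1]
    r_cs = np.corrcoef(c, s)[0, 1]
    r2 = (r_xc**2 + r_xs**2 - 2 * r_xc * r_xs * r_cs) / (1 - r_cs**2)
    return float(np.sqrt(np.clip(r2, 0.0, 1.0)))


def _circ_linear_corr_rows(phases_rad: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Row-wise circular-linear correlation for a (m, n) matrix of values."""
    c, s = np.cos(phases_rad), np.sin(phases_rad)
    cz = (c - c.mean()) / c.std()
    sz = (s - s.mean()) / s.std()
    r_cs = float(np.mean(cz * sz))
    x = rows - rows.mean(axis=1, keepdims=True)
    sd = x.std(axis=1)
    sd[sd == 0] = np.nan
    xz = x / sd[:, None]
    n = rows.shape[1]
    r_xc = xz @ cz / n
    r_xs = xz @ sz / n
    r2 = (r_xc**2 + r_xs**2 - 2 * r_xc * r_xs * r_cs) / (1 - r_cs**2)
    return np.sqrt(np.clip(r2, 0.0, 1.0))


@dataclass
class EntrainmentResult:
    """Per-subject behavioral-entrainment summary."""

    circ_linear_r: float
    perm_z: float
    perm_p: float
    n_permutations: int
    sine_amplitude: float = np.nan
    sine_phase_lag: float = np.nan
    sine_intercept: float = np.nan
    peak_phase_rad: float = np.nan


def permutation_entrainment(
    profile: DPrimeProfile,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    smooth_halfwidth: int = 2,
) -> EntrainmentResult:
    """Bin-shuffle permutation test of the circular-linear correlation.

    The observed r is computed on the smoothed profile; each permutation
    shuffles the 20 raw d' values across phase bins, re-smooths, and
    recomputes r.  z = (r_obs - mean)/sd of the null; p uses the add-one
    permutation estimator.
    """
    import warnings

    if n_perm < 100:
        warnings.warn("n_perm < 100 gives unstable permutation z-scores")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    phases = profile.phases_rad
    r_obs = circ_linear_corr(phases, profile.dprime_smoothed)

    n = len(phases)
    perms = np.empty((n_perm, n))
    for i in range(n_perm):
        perms[i] = rng.permutation(profile.dprime_raw)
    smoothed = perms @ _smoothing_matrix(n, smooth_halfwidth).T
    r_perm = _circ_linear_corr_rows(phases, smoothed)

    z = (r_obs - r_perm.mean()) / r_perm.std(ddof=0)
    p = (1 + int(np.sum(r_perm >= r_obs))) / (n_perm + 1)
    return EntrainmentResult(
        circ_linear_r=r_obs, perm_z=float(z), perm_p=float(p), n_permutations=n_perm
    )


def fit_single_cycle_sine(
    values: np.ndarray,
    phases_deg: np.ndarray,
    f_m: float = 3.0,
) -> tuple[float, float, float]:
    """Least-squares fit of ``y = A*sin(2*pi*f_m*x + phi) + b``.

    The 20 smoothed d' values are mapped to time steps x = phase/(360*f_m)
    seconds spanning one modulation cycle.  The model is linear in
    ``(A*cos(phi), A*sin(phi), b)`` so the exact global optimum is found by
    ordinary least squares; the result is canonicalized to A >= 0 and
    phi in [0, 2*pi).  Returns ``(A, phi, b)``.
    """
    values = np.asarray(values, dtype=float)
    phases_deg = np.asarray(phases_deg, dtype=float)
    x = phases_deg / (360.0 * f_m)
    arg = 2 * np.pi * f_m * x
    design = np.column_stack([np.sin(arg), np.cos(arg), np.ones_like(arg)])
    (a, c, b), *_ = np.linalg.lstsq(design, values, rcond=None)
    amp = float(np.hypot(a, c))
    phi = float(np.arctan2(c, a) % (2 * np.pi))
    if amp == 0.0:
        phi = 0.0
    return amp, phi, float(b)


def peak_phase(sine_amplitude: float, sine_phase_lag: float, f_m: float = 3.0) -> float:
    """FM phase of peak performance from the sine fit: (pi/2 - phi) mod 2*pi.

    Equals ``x_max * 2*pi*f_m`` for x_max the within-cycle argmax of the
    fitted sine.
    """
    if sine_amplitude <= 0:
        raise ValueError("peak phase undefined for non-positive amplitude")
    return float((np.pi / 2 - sine_phase_lag) % (2 * np.pi))


def rayleigh_test(angles_rad: np.ndarray) -> tuple[float, float, float]:
    """Rayleigh test of circular uniformity.

    Returns ``(z, p, mean_angle)`` with R the mean resultant length,
    z = n*R^2 and p from the standard series approximation.
    """
    angles = np.asarray(angles_rad, dtype=float)
    n = len(angles)
    if n < 3:
        raise ValueError("need at least 3 angles")
    vec = np.exp(1j * angles).mean()
    big_r = np.abs(vec)
    z = n * big_r**2
    p = np.exp(np.sqrt(1 + 4 * n + 4 * (n**2 - (n * big_r) ** 2)) - (1 + 2 * n))
    return float(z), float(min(p, 1.0)), float(np.angle(vec) % (2 * np.pi))


def group_z_test(z_scores: np.ndarray) -> tuple[float, float, float]:
    """One-sample two-tailed t test of permutation z-scores against zero.

    Returns ``(t, p, cohens_d)`` with d = mean/sd.
    """
    z = np.asarray(z_scores, dtype=float)
    if len(z) < 2:
        raise ValueError("need at least 2 subjects")
    sd = z.std(ddof=1)
    if sd == 0:
        if z.mean() == 0:
            return 0.0, 1.0, 0.0
        raise ValueError("zero variance across subjects: t undefined")
    t, p = stats.ttest_1samp(z, 0.0)
    return float(t), float(p), float(z.mean() / sd)


def analyze_subject(
    trials: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    f_m: float = 3.0,
) -> tuple[EntrainmentResult, DPrimeProfile, dict]:
    """Full per-subject behavioral pipeline: filter -> d' -> permutation -> sine."""
    kept, report = filter_trials(trials)
    profile = dprime_by_phase(kept)
    result = permutation_entrainment(profile, n_perm=n_perm, seed=seed)
    amp, phi, b = fit_single_cycle_sine(profile.dprime_smoothed, profile.phases_deg, f_m)
    result.sine_amplitude = amp
    result.sine_phase_lag = phi
    result.sine_intercept = b
    if amp > 0:
        result.peak_phase_rad = peak_phase(amp, phi, f_m)
    return result, profile, report
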