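import numpy as np
import pytest

import xentrain as xt


@pytest.fixture(scope="session")
def grid():
    return xt.build_target_grid()


@pytest.fixture(scope="session")
def modulated_trials():
    """One strongly modulated 640-trial session (shared, read-only)."""
    observer = xt.ObserverModel(mod_amplitude=0.8, preferred_phase_rad=1.7)
    return observer, xt.simulate_behavior(observer, seed=11)


def make_sinusoid_epochs(
    phases_rad,
    freq_hz=3.0,
    sfreq=250.0,
    t_start_ms=-500.0,
    t_stop_ms=2500.0,
    channels=("Oz",),
    amplitudes=None,
):
    """Single-frequency epochs with prescribed per-trial phases (no noise)."""
    import pandas as pd

    phases_rad = np.asarray(phases_rad, dtype=float)
    n_tr = len(phases_rad)
    dt = 1000.0 / sfreq
    times = np.arange(t_start_ms, t_stop_ms, dt)
    t_s = times / 1000.0
    amps = np.ones(n_tr) if amplitudes is None else np.asarray(amplitudes, float)
    wave = amps[None, :] * np.sin(
        2 * np.pi * freq_hz * t_s[:, None] + phases_rad[None, :]
    )
    data = np.repeat(wave[None, :, :], len(channels), axis=0)
    trials = pd.DataFrame({"onset_phase_rad": np.zeros(n_tr)})
    return xt.EpochSet(data, times, list(channels), sfreq, trials)
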