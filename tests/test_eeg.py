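import numpy as np
import pandas as pd
import pytest

import xentrain as xt
from xentrain.simulate import DEFAULT_SIM_CHANNELS

from conftest import make_sinusoid_epochs


def _delta_epochs(onset_phases, sfreq=500.0, spike_at_ms=None):
    """Epochs containing a single delta spike per trial (for shift tracking)."""
    n_tr = len(onset_phases)
    dt = 1000.0 / sfreq
    times = np.arange(-2000.0, 4350.0, dt)
    data = np.zeros((1, len(times), n_tr))
    for j, t_ms in enumerate(spike_at_ms):
        data[0, np.argmin(np.abs(times - t_ms)), j] = 1.0
    trials = pd.DataFrame({"onset_phase_rad": onset_phases})
    return xt.EpochSet(data, times, ["Oz"], sfreq, trials)


class TestRealignment:
    def test_zero_onset_phase_no_shift(self):
        ep = _delta_epochs([0.0], spike_at_ms=[500.0])
        re = xt.realign_epochs(ep, baseline_ms=None)
        assert re.times_ms[np.argmax(re.data[0, :, 0])] == pytest.approx(500.0)

    def test_pi_onset_shifts_one_sixth_second(self):
        # shift = (2*pi - pi) / (2*pi*3) = 1/6 s
        ep = _delta_epochs([np.pi], spike_at_ms=[500.0])
        re = xt.realign_epochs(ep, baseline_ms=None)
        peak = re.times_ms[np.argmax(re.data[0, :, 0])]
        assert peak == pytest.approx(500.0 - 1000.0 / 6, abs=2.0)

    def test_missing_onset_phase_rejected(self):
        ep = _delta_epochs([0.0], spike_at_ms=[0.0])
        ep.trials = ep.trials.drop(columns=["onset_phase_rad"])
        with pytest.raises(ValueError):
            xt.realign_epochs(ep)

    def test_realignment_unifies_stimulus_phase(self):
        # entrained trials with mixed onset phases become phase-consistent:
        # ITPC at 3 Hz ~ 1 for a jitter-free cohort
        trials = xt.simulate_behavior(xt.ObserverModel(), n_trials=80, seed=0)
        ep = xt.simulate_eeg_epochs(
            trials, kappa_lock=np.inf, eeg_snr=20.0, seed=1,
            channels=xt.AUDITORY_ELECTRODES + xt.VISUAL_ELECTRODES,
        )
        re = xt.realign_epochs(ep)
        m = xt.itpc(
            re, freqs=np.array([3.0]), times_ms=np.array([750.0]),
            channels=["FC3"],
        )
        assert m.itpc[0, 0, 0] > 0.99


@pytest.fixture(scope="module")
def flat_epochs():
    rng = np.random.default_rng(0)
    times = np.arange(-200.0, 800.0, 4.0)
    series = rng.normal(size=(1, len(times), 6))
    data = np.repeat(series, len(DEFAULT_SIM_CHANNELS), axis=0)
    trials = pd.DataFrame({"onset_phase_rad": np.zeros(6)})
    return xt.EpochSet(data, times, list(DEFAULT_SIM_CHANNELS), 250.0, trials)


class TestSurfaceLaplacian:
    def test_annihilates_spatially_uniform_signal(self, flat_epochs):
        out = xt.surface_laplacian(flat_epochs)
        scale = np.abs(flat_epochs.data).max()
        assert np.abs(out.data).max() < 1e-6 * scale

    def test_linearity(self, flat_epochs):
        rng = np.random.default_rng(1)
        shape = flat_epochs.data.shape
        x = flat_epochs
        y = xt.EpochSet(
            rng.normal(size=shape), x.times_ms, list(x.channels), x.sfreq,
            x.trials.copy(),
        )
        combo = xt.EpochSet(
            2.0 * x.data + 3.0 * y.data, x.times_ms, list(x.channels), x.sfreq,
            x.trials.copy(),
        )
        lhs = xt.surface_laplacian(combo).data
        rhs = 2.0 * xt.surface_laplacian(x).data + 3.0 * xt.surface_laplacian(y).data
        np.testing.assert_allclose(lhs, rhs, atol=1e-8 * np.abs(rhs).max())

    def test_focal_source_stays_focal(self, flat_epochs):
        x = flat_epochs
        data = np.zeros_like(x.data)
        oz = x.channels.index("Oz")
        data[oz] = 1.0
        focal = xt.EpochSet(data, x.times_ms, list(x.channels), x.sfreq, x.trials.copy())
        out = xt.surface_laplacian(focal)
        mags = np.abs(out.data).mean(axis=(1, 2))
        far = [x.channels.index(c) for c in ("Fz", "FCz", "Cz", "FC3", "FC4")]
        assert mags[oz] > 3 * mags[far].max()

    def test_too_few_channels_refused(self):
        times = np.arange(0.0, 100.0, 4.0)
        trials = pd.DataFrame({"onset_phase_rad": [0.0]})
        small = xt.EpochSet(
            np.zeros((3, len(times), 1)), times, ["O1", "Oz", "O2"], 250.0, trials
        )
        with pytest.raises(ValueError):
            xt.surface_laplacian(small)


class TestITPC:
    def test_identical_trials_give_unity(self):
        ep = make_sinusoid_epochs(np.full(100, 1.1))
        m = xt.itpc(ep, freqs=np.array([3.0]), times_ms=np.array([1000.0]))
        assert m.itpc[0, 0, 0] == pytest.approx(1.0, abs=1e-9)

    def test_amplitude_scaling_invariance(self):
        rng = np.random.default_rng(2)
        phases = rng.uniform(0, 2 * np.pi, 60)
        a = make_sinusoid_epochs(phases)
        b = make_sinusoid_epochs(phases, amplitudes=rng.uniform(0.1, 10.0, 60))
        freqs, times = np.array([3.0]), np.array([1000.0])
        va = xt.itpc(a, freqs=freqs, times_ms=times).itpc
        vb = xt.itpc(b, freqs=freqs, times_ms=times).itpc
        np.testing.assert_allclose(va, vb, atol=1e-9)

    def test_common_phase_rotation_invariance(self):
        rng = np.random.default_rng(3)
        phases = rng.uniform(0, 2 * np.pi, 60)
        freqs, times = np.array([3.0]), np.array([1000.0])
        va = xt.itpc(make_sinusoid_epochs(phases), freqs=freqs, times_ms=times).itpc
        vb = xt.itpc(make_sinusoid_epochs(phases + 0.9), freqs=freqs, times_ms=times).itpc
        # equivariance is exact for analytic signals; real-signal spectral
        # leakage leaves a tiny residual
        np.testing.assert_allclose(va, vb, atol=5e-3)

    def test_bounds_and_edge_cells_missing(self):
        rng = np.random.default_rng(4)
        ep = make_sinusoid_epochs(rng.uniform(0, 2 * np.pi, 30))
        m = xt.itpc(
            ep,
            freqs=np.array([1.0, 3.0]),
            times_ms=np.array([-400.0, 1000.0, 2400.0]),
        )
        finite = m.itpc[np.isfinite(m.itpc)]
        assert (finite >= 0).all() and (finite <= 1).all()
        # 6 cycles at 1 Hz = 6 s window: no support anywhere in this epoch
        assert np.isnan(m.itpc[0, 0, :]).all()
        # 3 Hz (2 s window) unsupported at the epoch edges, supported at center
        assert np.isnan(m.itpc[0, 1, 0]) and np.isnan(m.itpc[0, 1, 2])
        assert np.isfinite(m.itpc[0, 1, 1])


class TestBandExtraction:
    def _uniform_map(self, value):
        freqs = np.arange(2.5, 3.51, 0.1)
        times = np.arange(500.0, 1001.0, 100.0)
        arr = np.full((3, len(freqs), len(times)), value)
        return xt.ITPCMap(arr, freqs, times, ["O1", "Oz", "O2"], 50)

    def test_constant_map(self):
        assert xt.extract_band(self._uniform_map(0.42), ["O1", "Oz", "O2"]) == (
            pytest.approx(0.42)
        )

    def test_matches_brute_force_mean(self):
        rng = np.random.default_rng(5)
        freqs = np.arange(2.0, 4.01, 0.1)
        times = np.arange(-800.0, 1001.0, 100.0)
        arr = rng.uniform(0, 1, size=(3, len(freqs), len(times)))
        m = xt.ITPCMap(arr, freqs, times, ["O1", "Oz", "O2"], 10)
        got = xt.extract_band(m, ["O1", "O2"], (2.5, 3.5), (500.0, 1000.0))
        total, count = 0.0, 0
        for ci in (0, 2):
            for fi, f in enumerate(freqs):
                for ti, t in enumerate(times):
                    if 2.5 - 1e-9 <= f <= 3.5 + 1e-9 and 500 <= t <= 1000:
                        total += arr[ci, fi, ti]
                        count += 1
        assert got == pytest.approx(total / count)

    def test_baseline_window_variant(self):
        freqs = np.arange(2.5, 3.51, 0.1)
        times = np.arange(-800.0, -299.0, 100.0)
        arr = np.full((3, len(freqs), len(times)), 0.05)
        m = xt.ITPCMap(arr, freqs, times, ["O1", "Oz", "O2"], 10)
        val = xt.extract_band(
            m, ["O1", "Oz", "O2"], window_ms=(-800.0, -300.0)
        )
        assert val == pytest.approx(0.05)

    def test_missing_channel_named(self):
        with pytest.raises(KeyError, match="P8"):
            xt.extract_band(self._uniform_map(0.1), ["Oz", "P8"])


class TestBaselineComparison:
    def test_identical_pairs(self):
        vals = np.array([0.1, 0.2, 0.3])
        t, p, d = xt.compare_to_baseline(vals, vals)
        assert (t, p, d) == (0.0, 1.0, 0.0)

    def test_constant_shift_flagged(self):
        base = np.array([0.05, 0.05, 0.05])
        with pytest.raises(ValueError):
            xt.compare_to_baseline(base + 0.04, base, arcsine=False)

    def test_arcsine_transform_preserves_ordering(self):
        rng = np.random.default_rng(6)
        stim = rng.uniform(0.1, 0.5, 21)
        base = stim - rng.uniform(0.01, 0.05, 21)
        t, p, d = xt.compare_to_baseline(stim, base)
        assert t > 0 and p < 0.05 and d > 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            xt.compare_to_baseline(np.ones(3) * 0.1, np.ones(4) * 0.1)


@pytest.fixture(scope="module")
def entrained():
    trials = xt.simulate_behavior(xt.ObserverModel(), n_trials=200, seed=7)
    kw = dict(
        kappa_lock=1.0, eeg_snr=0.4, seed=8,
        channels=xt.AUDITORY_ELECTRODES + xt.VISUAL_ELECTRODES,
        sfreq=250.0, epoch_window_ms=(-2000.0, 2650.0),
    )
    plain = xt.simulate_eeg_epochs(trials, target_evoked_amp=0.0, **kw)
    evoked = xt.simulate_eeg_epochs(trials, target_evoked_amp=3.0, **kw)
    return plain, evoked


class TestCycleSplit:
    def test_subset_sizes_sum_to_total(self, entrained):
        plain, _ = entrained
        re = xt.realign_epochs(plain, out_window_ms=(-2000.0, 2300.0))
        maps = xt.split_by_cycle(
            re, freqs=np.array([3.0]), times_ms=np.array([750.0])
        )
        assert maps[1].n_trials + maps[2].n_trials == re.n_trials

    def test_exchangeable_subsets_agree(self, entrained):
        plain, _ = entrained
        re = xt.realign_epochs(plain, out_window_ms=(-2000.0, 2300.0))
        maps = xt.split_by_cycle(
            re, freqs=np.array([3.0]), times_ms=np.array([750.0]), channels=["FC3"]
        )
        assert abs(maps[1].itpc[0, 0, 0] - maps[2].itpc[0, 0, 0]) < 0.2

    def test_pre_target_window_immune_to_target_transient(self, entrained):
        # second-cycle targets arrive after ~1333 ms; at the 500-ms analysis
        # point the taper weight at the transient is negligible
        plain, evoked = entrained
        vals = {}
        for name, ep in (("plain", plain), ("evoked", evoked)):
            re = xt.realign_epochs(ep, out_window_ms=(-2000.0, 2300.0))
            sub = re.subset_trials((re.trials["target_cycle"] == 2).to_numpy())
            m = xt.itpc(
                sub, freqs=np.array([3.0]), times_ms=np.array([500.0]),
                channels=["Oz"],
            )
            vals[name] = m.itpc[0, 0, 0]
        assert vals["evoked"] == pytest.approx(vals["plain"], abs=0.05)
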