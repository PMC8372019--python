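"""File interfaces: trial CSV, epoch HDF5, stimulus WAV, YAML configs.

Conventions: user-facing tables use degrees and milliseconds (radians and
seconds are internal); CSV is UTF-8 comma-separated with a header row; the
HDF5 epoch layout is versioned via a format attribute.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .behavior import TRIAL_COLUMNS
from .eeg import EpochSet

__all__ = [
    "write_trials_csv",
    "read_trials_csv",
    "write_epochs_h5",
    "read_epochs_h5",
    "write_wav",
    "load_config",
    "save_config",
    "config_hash",
]

EPOCHS_FORMAT_VERSION = "xentrain-epochs-1"

_TRIAL_DTYPES = {
    "onset_phase_rad": float,
    "target_phase_deg": float,
    "target_time_ms": float,
    "orientation": int,
    "response": int,
    "rt_ms": float,
    "blink": bool,
}


def _validate_trials(trials: pd.DataFrame) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    bad_orient = set(trials["orientation"].unique()) - {45, 135}
    if bad_orient:
        raise ValueError(f"invalid orientations: {sorted(bad_orient)}")
    bad_resp = set(trials["response"].unique()) - {0, 45, 135}
    if bad_resp:
        raise ValueError(f"invalid responses (0 = none): {sorted(bad_resp)}")


def write_trials_csv(trials: pd.DataFrame, path) -> None:
    _validate_trials(trials)
    trials.to_csv(path, index=False)


def read_trials_csv(path) -> pd.DataFrame:
    trials = pd.read_csv(path)
    _validate_trials(trials)
    for col, dtype in _TRIAL_DTYPES.items():
        trials[col] = trials[col].astype(dtype)
    return trials


def write_epochs_h5(epochs: EpochSet, path, attrs: dict | None = None) -> None:
    """Write an epoch container: data [channel x time x trial] + metadata."""
    with h5py.File(path, "w") as h5:
        h5.attrs["format"] = EPOCHS_FORMAT_VERSION
        h5.attrs["sfreq"] = float(epochs.sfreq)
        for key, val in (attrs or {}).items():
            h5.attrs[key] = val
        h5.create_dataset("data", data=epochs.data, compression="gzip", compression_opts=1)
        h5.create_dataset("times_ms", data=np.asarray(epochs.times_ms, dtype=float))
        h5.create_dataset(
            "channels", data=np.array(epochs.channels, dtype=h5py.string_dtype())
        )
        meta = h5.create_group("trials")
        for col in epochs.trials.columns:
            values = epochs.trials[col].to_numpy()
            if values.dtype == object:
                values = values.astype(h5py.string_dtype())
            meta.create_dataset(col, data=values)


def read_epochs_h5(path) -> tuple[EpochSet, dict]:
    """Read an epoch container; returns (EpochSet, file attributes)."""
    with h5py.File(path, "r") as h5:
        fmt = h5.attrs.get("format")
        if fmt != EPOCHS_FORMAT_VERSION:
            raise ValueError(
                f"unsupported epochs file format {fmt!r}; "
                f"expected {EPOCHS_FORMAT_VERSION!r}"
            )
        channels = [c.decode() if isinstance(c, bytes) else str(c) for c in h5["channels"][()]]
        trials = {}
        for col, ds in h5["trials"].items():
            values = ds[()]
            if values.dtype.kind in ("S", "O"):
                values = np.array([v.decode() if isinstance(v, bytes) else v for v in values])
            trials[col] = values
        epochs = EpochSet(
            data=h5["data"][()],
            times_ms=h5["times_ms"][()],
            channels=channels,
            sfreq=float(h5.attrs["sfreq"]),
            trials=pd.DataFrame(trials),
        )
        attrs = {k: h5.attrs[k] for k in h5.attrs}
    return epochs, attrs


def write_wav(waveform: np.ndarray, path, sample_rate_hz: float = 48_000.0) -> None:
    """Export a waveform as 16-bit PCM WAV, peak-normalized to -3 dBFS."""
    peak = np.max(np.abs(waveform))
    if peak == 0:
        raise ValueError("cannot export an all-zero waveform")
    scaled = waveform / peak * 10 ** (-3 / 20)
    pcm = np.round(scaled * 32767).astype(np.int16)
    wavfile.write(path, int(sample_rate_hz), pcm)


def load_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError("config file must contain a mapping")
    return config


def save_config(config: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def config_hash(config: dict) -> str:
    """Stable short hash of a config mapping, for output manifests."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
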