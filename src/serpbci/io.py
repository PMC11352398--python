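"""Reading and writing continuous recordings and session artifacts.

Continuous EEG travels as an MNE ``Raw`` file (``*_raw.fif``); real EDF(+)
recordings are read through :func:`mne.io.read_raw_edf`.  Stimulus events
live in a sidecar TSV (exact integer sample indices), ground truth in a JSON
sidecar.  Signals are held in µV in memory and stored in volts on disk, the
MNE convention.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .protocol import CHANNELS, MONTAGES, EventTable, ProtocolConfig


def write_recording(
    signal_uv: np.ndarray,
    config: ProtocolConfig,
    path: str | Path,
    montage: str = "right_impaired",
) -> Path:
    """Write a channels x samples µV matrix as an MNE FIF file."""
    import mne

    path = Path(path)
    if not path.name.endswith("raw.fif"):
        path = path.with_name(path.stem + "_raw.fif")
    names = [MONTAGES[montage][ch] for ch in CHANNELS]
    info = mne.create_info(names, sfreq=config.sampling_rate, ch_types="eeg")
    raw = mne.io.RawArray(np.asarray(signal_uv) * 1e-6, info, verbose="error")
    raw.save(path, overwrite=True, verbose="error")
    return path


def read_recording(
    path: str | Path,
    montage: str = "right_impaired",
) -> tuple[np.ndarray, float]:
    """Read a FIF or EDF(+) recording back into a µV matrix.

    Channels are returned in canonical generalized order (Ci, CPi, Pi, Cz,
    Cc, Fp1) resolved through the montage's physical labels.

    Returns ``(signal_uv, sampling_rate)``.
    """
    import mne

    path = Path(path)
    if path.suffix.lower() == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:
        raw = mne.io.read_raw_fif(path, preload=True, verbose="error")
    mapping = MONTAGES[montage]
    lookup = {name.upper(): i for i, name in enumerate(raw.ch_names)}
    rows = []
    for ch in CHANNELS:
        phys = mapping[ch].upper()
        if phys not in lookup:
            raise ValueError(f"channel {mapping[ch]} missing from {path.name}")
        rows.append(lookup[phys])
    data = raw.get_data()[rows] * 1e6
    return data, float(raw.info["sfreq"])


def load_session_files(
    eeg_path: str | Path,
    events_path: str | Path,
) -> tuple[np.ndarray, float, EventTable]:
    """Load a recording plus its sidecar event table."""
    events = EventTable.from_tsv(events_path)
    signal, fs = read_recording(eeg_path, montage=events.montage)
    return signal, fs, events
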