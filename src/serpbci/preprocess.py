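"""EEG preprocessing: filtering, epoching, artifact rejection, clustering.

The pipeline is strictly causal: the same forward-only band-pass filter is
used for training-phase and online processing, so the feature distributions
of the two phases are identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .protocol import (
    CHANNELS,
    SOMATOSENSORY_CHANNELS,
    EventTable,
    ProtocolConfig,
    StimulusEvent,
)

CONDITIONS: tuple[str, ...] = ("ADSD", "ADSV", "AVSD", "AVSV")
_EEG_ROWS = [CHANNELS.index(c) for c in SOMATOSENSORY_CHANNELS]
_FP1_ROW = CHANNELS.index("Fp1")


def design_filter(config: ProtocolConfig) -> np.ndarray:
    """Butterworth band-pass as second-order sections.

    A 4th-order prototype band-pass (8 poles), the conventional reading of a
    "fourth-order Butterworth filter" between two cut-offs; SOS form keeps
    the 0.1 Hz corner numerically stable at 1200 Hz.
    """
    return sps.butter(config.filter_order, config.filter_band,
                      btype="bandpass", fs=config.sampling_rate, output="sos")


def bandpass_filter(signal: np.ndarray, config: ProtocolConfig) -> np.ndarray:
    """Causal (forward-only) band-pass filtering along the last axis."""
    signal = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal contains non-finite values")
    return sps.sosfilt(design_filter(config), signal, axis=-1)


@dataclass
class Epoch:
    """One baseline-corrected, stimulus-locked EEG segment."""

    data: np.ndarray               # channels x epoch samples, µV
    stimulated: str                # {D, V}
    attended: str                  # {D, V}
    phase: str
    unit_id: int
    seq_index: int
    onset_sample: int
    event_index: int = -1
    accepted: bool = True
    reject_reason: str | None = None

    @property
    def condition(self) -> str:
        return f"A{self.attended}S{self.stimulated}"

    def post_stimulus(self, config: ProtocolConfig) -> np.ndarray:
        return self.data[:, config.n_baseline_samples:]


@dataclass
class EpochCluster:
    """Accepted epochs of one attended x stimulated condition."""

    condition: str
    epochs: list[Epoch] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.epochs)


def segment_epochs(
    filtered: np.ndarray,
    events: EventTable,
    config: ProtocolConfig,
) -> list[Epoch]:
    """Cut the filtered recording into baseline-corrected epochs.

    Each epoch spans the half-open window ``[onset - 100 ms, onset + 600 ms)``
    (840 samples at defaults); the per-channel mean of the 100 ms baseline is
    subtracted from the whole epoch.  Events too close to the recording edge,
    or within the initial ``lead_in`` filter-settling period, are marked
    rejected (reasons ``"edge"`` / ``"lead_in"``).
    """
    filtered = np.asarray(filtered, dtype=float)
    nb, npost = config.n_baseline_samples, config.n_post_samples
    lead = int(round(config.lead_in * config.sampling_rate))
    out: list[Epoch] = []
    for i, ev in enumerate(events):
        lo, hi = ev.onset_sample - nb, ev.onset_sample + npost
        common = dict(
            stimulated=ev.location, attended=ev.attended_location,
            phase=ev.phase, unit_id=ev.unit_id, seq_index=ev.seq_index,
            onset_sample=ev.onset_sample, event_index=i,
        )
        if lo < 0 or hi > filtered.shape[-1]:
            out.append(Epoch(data=np.zeros((filtered.shape[0], nb + npost)),
                             accepted=False, reject_reason="edge", **common))
            continue
        win = filtered[:, lo:hi].copy()
        win -= win[:, :nb].mean(axis=1, keepdims=True)
        reason = "lead_in" if ev.onset_sample < lead else None
        out.append(Epoch(data=win, accepted=reason is None,
                         reject_reason=reason, **common))
    return out


def reject_artifacts(epochs: list[Epoch], config: ProtocolConfig) -> list[Epoch]:
    """Amplitude-threshold rejection on baseline-corrected epochs.

    An epoch is accepted iff every sample of the five somatosensory channels
    lies within ±50 µV and every Fp1 sample within ±80 µV (defaults).
    Epochs already rejected (edge/lead-in) are left untouched.  The input
    list is modified in place and returned.
    """
    for ep in epochs:
        if not ep.accepted:
            continue
        if np.abs(ep.data[_EEG_ROWS]).max() > config.eeg_reject_threshold:
            ep.accepted = False
            ep.reject_reason = "eeg_amplitude"
        elif np.abs(ep.data[_FP1_ROW]).max() > config.eog_reject_threshold:
            ep.accepted = False
            ep.reject_reason = "eog_amplitude"
    return epochs


def cluster_and_balance(epochs: list[Epoch]) -> dict[str, EpochCluster]:
    """Distribute accepted epochs into the four condition clusters and balance.

    Larger clusters are trimmed to the minimum cluster size by dropping their
    chronologically last epochs (largest onset sample).  Raises if any
    condition has no accepted epochs.
    """
    clusters = {c: EpochCluster(condition=c) for c in CONDITIONS}
    for ep in epochs:
        if ep.accepted:
            clusters[ep.condition].epochs.append(ep)
    sizes = {c: len(cl) for c, cl in clusters.items()}
    if min(sizes.values()) == 0:
        empty = [c for c, n in sizes.items() if n == 0]
        raise ValueError(f"insufficient data: empty condition cluster(s) {empty}")
    n_min = min(sizes.values())
    for cl in clusters.values():
        cl.epochs.sort(key=lambda e: e.onset_sample)
        del cl.epochs[n_min:]
    return clusters


def preprocess_session(
    signal: np.ndarray,
    events: EventTable,
    config: ProtocolConfig,
    phase: str | None = None,
) -> list[Epoch]:
    """Filter -> segment -> reject, optionally restricted to one phase."""
    filtered = bandpass_filter(signal, config)
    if phase is not None:
        events = EventTable(events=events.phase_events(phase),
                            montage=events.montage)
    epochs = segment_epochs(filtered, events, config)
    return reject_artifacts(epochs, config)
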