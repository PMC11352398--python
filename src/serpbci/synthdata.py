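"""Synthetic continuous EEG with stimulus-locked sERP templates.

The generator emulates the statistical structure the classifier exploits:
each electrotactile stimulus adds a location-specific somatosensory
event-related potential (sERP) template to the ongoing EEG, and when the
stimulated location is the attended one the template's late components
(after ~150 ms) are amplitude-enhanced.  Early components (< 150 ms) are
attention-invariant, mirroring the observed grand-average morphology where
attended and unattended waveforms overlap early and diverge after ~150 ms.

Background activity is an order-2 autoregressive process (low-pass
character), ocular artifacts (blinks) are injected on Fp1 above the ±80 µV
rejection threshold, and slow drift artifacts are injected on somatosensory
channels above the ±50 µV threshold, so that every injected artifact is
rejectable by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .protocol import (
    CHANNELS,
    SOMATOSENSORY_CHANNELS,
    EventTable,
    ProtocolConfig,
    StimulusEvent,
    schedule_session,
)

FP1_INDEX = CHANNELS.index("Fp1")

#: Relative sERP amplitude per channel.  Largest over the ipsilesional
#: sensorimotor strip (Ci/CPi/Pi), attenuated on the midline and
#: contralesional channels, absent on Fp1 (which carries ocular activity).
DEFAULT_CHANNEL_GAINS: dict[str, float] = {
    "Ci": 1.0, "CPi": 0.9, "Pi": 0.75, "Cz": 0.5, "Cc": 0.35, "Fp1": 0.0,
}

#: Channel gains for a strictly lateralized response (no midline /
#: contralesional loading); used to probe feedback-channel selection.
IPSILESIONAL_CHANNEL_GAINS: dict[str, float] = {
    "Ci": 1.0, "CPi": 0.9, "Pi": 0.75, "Cz": 0.0, "Cc": 0.0, "Fp1": 0.0,
}


@dataclass
class SerpTemplate:
    """Stimulus-locked response template for one stimulation location.

    ``waveform`` holds the response of every channel over the 0..600 ms
    post-stimulus interval (zero outside it).  When the stimulated location
    is attended, amplitudes inside ``late_window`` are multiplied by
    ``attention_gain``, with a smooth 20 ms taper at the window edge.
    """

    location: str
    waveform: np.ndarray                       # channels x n_post samples, µV
    sampling_rate: float
    early_window: tuple[float, float] = (0.0, 150.0)    # ms
    late_window: tuple[float, float] = (150.0, 600.0)   # ms
    attention_gain: float = 2.0
    taper_ms: float = 20.0

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        if self.waveform.ndim != 2 or self.waveform.shape[0] != len(CHANNELS):
            raise ValueError("waveform must be (n_channels, n_post_samples)")
        if self.attention_gain < 1.0:
            raise ValueError("attention_gain must be >= 1")

    @property
    def n_samples(self) -> int:
        return self.waveform.shape[1]

    def gain_envelope(self) -> np.ndarray:
        """Multiplicative attended-condition envelope over 0..600 ms.

        1 inside the early window, ``attention_gain`` inside the late window,
        raised-cosine ramp over ``taper_ms`` starting at the late-window
        edge so no step discontinuity is introduced.
        """
        t = np.arange(self.n_samples) / self.sampling_rate * 1000.0  # ms
        t0 = self.late_window[0]
        ramp = np.clip((t - t0) / max(self.taper_ms, 1e-9), 0.0, 1.0)
        smooth = 0.5 - 0.5 * np.cos(np.pi * ramp)
        return 1.0 + (self.attention_gain - 1.0) * smooth

    def response(self, attended: bool) -> np.ndarray:
        """Channels x samples response under the given attention state."""
        if not attended or self.attention_gain == 1.0:
            return self.waveform
        return self.waveform * self.gain_envelope()[None, :]


def _gauss_bump(t_ms: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t_ms - center) / width) ** 2)


def default_templates(
    config: ProtocolConfig,
    attention_gain: float = 2.0,
    channel_gains: dict[str, float] | None = None,
) -> dict[str, SerpTemplate]:
    """Smooth biphasic sERP templates for locations D and V.

    Each waveform is a sum of Gaussian-windowed components: a negative
    deflection near 100 ms, a positive peak near 210-230 ms and a broad late
    positivity near 330-360 ms (amplitudes in µV, a few µV peak as typical
    for forearm electrical stimulation).  The two locations differ slightly
    in latency and amplitude.  Per-channel scaling follows ``channel_gains``
    (largest over ipsilesional channels by default).
    """
    if channel_gains is None:
        channel_gains = DEFAULT_CHANNEL_GAINS
    n = config.n_post_samples
    t = np.arange(n) / config.sampling_rate * 1000.0
    shapes = {
        "D": (-4.5 * _gauss_bump(t, 100.0, 25.0)
              + 5.0 * _gauss_bump(t, 210.0, 45.0)
              + 2.5 * _gauss_bump(t, 330.0, 80.0)),
        "V": (-4.0 * _gauss_bump(t, 110.0, 25.0)
              + 4.5 * _gauss_bump(t, 230.0, 50.0)
              + 2.2 * _gauss_bump(t, 360.0, 85.0)),
    }
    gains = np.array([channel_gains.get(ch, 0.0) for ch in CHANNELS])
    return {
        loc: SerpTemplate(
            location=loc,
            waveform=gains[:, None] * shape[None, :],
            sampling_rate=config.sampling_rate,
            attention_gain=attention_gain,
        )
        for loc, shape in shapes.items()
    }


@dataclass
class NoiseModel:
    """Background EEG noise plus injected, rejectable artifacts.

    ``background_std`` is the standard deviation (µV) of the AR(2)
    background process before any filtering.  Blinks are Gaussian bumps on
    Fp1 exceeding the ±80 µV ocular threshold; drifts are slow raised-cosine
    excursions on a random somatosensory channel exceeding the ±50 µV
    threshold.
    """

    background_std: float = 5.0            # µV
    ar_coeffs: tuple[float, float] = (1.7, -0.72)
    blink_rate: float = 2.0                # events / min on Fp1
    blink_amplitude: float = 150.0         # µV, must exceed 80
    blink_width_ms: float = 40.0           # Gaussian sigma
    drift_rate: float = 1.0                # events / min on EEG channels
    drift_amplitude: float = 100.0         # µV, must exceed 50
    drift_duration_ms: float = 600.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.blink_rate > 0 and self.blink_amplitude <= 80.0:
            raise ValueError("blink_amplitude must exceed the 80 µV Fp1 threshold")
        if self.drift_rate > 0 and self.drift_amplitude <= 50.0:
            raise ValueError("drift_amplitude must exceed the 50 µV EEG threshold")
        a1, a2 = self.ar_coeffs
        # stationarity of the AR(2) process
        if not (abs(a2) < 1 and a2 + a1 < 1 and a2 - a1 < 1):
            raise ValueError("ar_coeffs do not define a stationary AR(2) process")

    def ar_stationary_std(self) -> float:
        """Stationary std of the AR(2) process driven by unit white noise."""
        a1, a2 = self.ar_coeffs
        var = (1 - a2) / ((1 + a2) * ((1 - a2) ** 2 - a1 ** 2))
        return float(np.sqrt(var))

    def background(self, n_channels: int, n_samples: int,
                   rng: np.random.Generator) -> np.ndarray:
        """AR(2) background, scaled to ``background_std`` µV per channel."""
        if self.background_std == 0.0:
            return np.zeros((n_channels, n_samples))
        a1, a2 = self.ar_coeffs
        white = rng.standard_normal((n_channels, n_samples))
        ar = sps.lfilter([1.0], [1.0, -a1, -a2], white, axis=-1)
        return ar * (self.background_std / self.ar_stationary_std())


@dataclass
class SyntheticSession:
    """Continuous synthetic recording with full ground truth."""

    config: ProtocolConfig
    signal: np.ndarray                 # channels x samples, µV
    events: EventTable
    artifact_flags: np.ndarray         # bool per event: corrupted by injected artifact
    artifact_component: np.ndarray     # channels x samples, artifact signal only
    templates: dict[str, SerpTemplate]
    noise: NoiseModel

    @property
    def sampling_rate(self) -> float:
        return self.config.sampling_rate

    def ground_truth_json(self) -> str:
        gt = {
            "attended_by_unit": {
                phase: {str(u): evs[0].attended_location
                        for u, evs in self.events.units(phase).items()}
                for phase in ("training", "test")
            },
            "artifact_event_indices": np.flatnonzero(self.artifact_flags).tolist(),
            "attention_gain": self.templates["D"].attention_gain,
            "background_std": self.noise.background_std,
        }
        return json.dumps(gt, indent=1)


def _poisson_onsets(rate_per_min: float, n_samples: int, fs: float,
                    rng: np.random.Generator) -> np.ndarray:
    if rate_per_min <= 0:
        return np.array([], dtype=int)
    expected = rate_per_min * n_samples / fs / 60.0
    k = rng.poisson(expected)
    return np.sort(rng.integers(0, n_samples, size=k))


def _add_bump(track: np.ndarray, center: int, bump: np.ndarray) -> None:
    half = len(bump) // 2
    lo = max(center - half, 0)
    hi = min(center - half + len(bump), track.shape[-1])
    track[..., lo:hi] += bump[lo - (center - half): hi - (center - half)]


def generate_session(
    config: ProtocolConfig,
    templates: dict[str, SerpTemplate] | None = None,
    noise: NoiseModel | None = None,
    events: EventTable | None = None,
    first_target: str | None = None,
    montage: str = "right_impaired",
    rng: np.random.Generator | None = None,
    phases: tuple[str, ...] = ("training", "test"),
) -> SyntheticSession:
    """Generate one full synthetic session (training and/or test phase).

    Every stimulus adds its location's template at its onset, with the
    attended-condition gain envelope applied iff the stimulated location is
    the attended one.  Responses from consecutive stimuli sum linearly.
    Ground-truth artifact flags mark epochs whose *artifact component alone*,
    band-pass filtered and baseline-corrected like the real pipeline, exceeds
    the rejection thresholds with a safety margin, so that injected-artifact
    epochs are guaranteed rejectable regardless of the background noise.
    """
    if noise is None:
        noise = NoiseModel(seed=config.random_seed)
    if templates is None:
        templates = default_templates(config)
    for tpl in templates.values():
        if abs(tpl.sampling_rate - config.sampling_rate) > 1e-9:
            raise ValueError("template sampling rate does not match config")
    if rng is None:
        rng = np.random.default_rng(noise.seed)

    fs = config.sampling_rate
    if events is None:
        if first_target is None:
            first_target = str(rng.permutation(["D", "V"])[0])
        full = schedule_session(config, first_target, rng, montage=montage)
        kept = [e for e in full if e.phase in phases]
        if phases != ("training", "test"):
            # re-anchor so the kept phase still starts after the lead-in
            shift = kept[0].onset_sample - int(round(config.lead_in * fs))
            kept = [
                StimulusEvent(e.onset_sample - shift, e.location,
                              e.attended_location, e.phase, e.unit_id,
                              e.seq_index)
                for e in kept
            ]
        events = EventTable(events=kept, montage=montage)

    n_samples = events.events[-1].onset_sample + config.n_post_samples \
        + int(round(config.inter_block_pause * fs))
    n_ch = len(CHANNELS)

    signal = noise.background(n_ch, n_samples, rng)

    # stimulus-locked responses, summed linearly
    for ev in events:
        tpl = templates[ev.location]
        resp = tpl.response(attended=ev.attended_location == ev.location)
        signal[:, ev.onset_sample:ev.onset_sample + tpl.n_samples] += resp

    # injected artifacts, tracked separately for ground truth
    artifact = np.zeros_like(signal)
    blink_len = int(round(8 * noise.blink_width_ms / 1000.0 * fs))
    if blink_len:
        tb = (np.arange(blink_len) - blink_len / 2) / fs * 1000.0
        blink = noise.blink_amplitude * np.exp(
            -0.5 * (tb / noise.blink_width_ms) ** 2)
        for c in _poisson_onsets(noise.blink_rate, n_samples, fs, rng):
            _add_bump(artifact[FP1_INDEX], int(c), blink)
    drift_len = int(round(noise.drift_duration_ms / 1000.0 * fs))
    if drift_len:
        td = np.arange(drift_len) / max(drift_len - 1, 1)
        # raised cosine peaking at drift_amplitude mid-bump
        drift = noise.drift_amplitude * 0.5 * (1 - np.cos(2 * np.pi * td))
        for c in _poisson_onsets(noise.drift_rate, n_samples, fs, rng):
            ch = int(rng.integers(0, len(SOMATOSENSORY_CHANNELS)))
            _add_bump(artifact[ch], int(c), drift)
    signal = signal + artifact

    flags = _ground_truth_flags(artifact, events, config, templates, noise)

    return SyntheticSession(
        config=config, signal=signal, events=events, artifact_flags=flags,
        artifact_component=artifact, templates=templates, noise=noise,
    )


def _ground_truth_flags(
    artifact: np.ndarray,
    events: EventTable,
    config: ProtocolConfig,
    templates: dict[str, SerpTemplate],
    noise: NoiseModel,
) -> np.ndarray:
    """Flag events whose artifact component alone trips the rejection rule.

    The artifact track is passed through the same causal band-pass filter and
    per-epoch baseline correction as the real pipeline, then compared against
    thresholds inflated by a margin (6 x background std plus the maximum
    template amplitude) so a flagged epoch cannot be pushed back under
    threshold by noise or sERP content.
    """
    from .preprocess import bandpass_filter  # local import to avoid a cycle

    if not artifact.any():
        return np.zeros(len(events), dtype=bool)
    # tiny deterministic floor keeps the filter state out of the denormal
    # range (the track is mostly zero; decaying tails otherwise stall sosfilt)
    t = np.arange(artifact.shape[1]) / config.sampling_rate
    floor = 1e-12 * np.cos(2 * np.pi * 10.0 * t)   # in-band, pass-through
    filt = bandpass_filter(artifact + floor[None, :], config)
    tmax = max(float(np.max(np.abs(t.waveform))) * t.attention_gain
               for t in templates.values())
    margin = 6.0 * noise.background_std + tmax
    nb, npost = config.n_baseline_samples, config.n_post_samples
    eeg_idx = [CHANNELS.index(c) for c in SOMATOSENSORY_CHANNELS]
    flags = np.zeros(len(events), dtype=bool)
    for i, ev in enumerate(events):
        lo, hi = ev.onset_sample - nb, ev.onset_sample + npost
        if lo < 0 or hi > filt.shape[1]:
            continue
        win = filt[:, lo:hi] - filt[:, lo:lo + nb].mean(axis=1, keepdims=True)
        eeg_hit = np.abs(win[eeg_idx]).max() > config.eeg_reject_threshold + margin
        eog_hit = np.abs(win[FP1_INDEX]).max() > config.eog_reject_threshold + margin
        flags[i] = bool(eeg_hit or eog_hit)
    return flags
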