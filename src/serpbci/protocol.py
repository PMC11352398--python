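"""Experimental protocol: configuration, stimulus events and schedules.

The protocol has two phases.  A *training phase* of 30 blocks (15 per
selective-attention task): within a block, 30 single electrotactile pulses
are delivered in randomized order to the dorsal (D, radial nerve) and volar
(V, median nerve) forearm locations, 15 per location, with a 700 ms
inter-stimulus interval, while the subject attends to one target location.
A *test phase* of 20 online classification trials (10 per target location):
stimuli are delivered until 10 artifact-free epochs have been collected per
location, up to a budget of 30 stimuli per trial.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np
import pandas as pd
import yaml

Location = Literal["D", "V"]
Phase = Literal["training", "test"]

#: Generalized channel labels, in canonical order.  ``Ci``/``CPi``/``Pi`` lie
#: over the ipsilesional sensorimotor cortex, ``Cc`` is the contralesional
#: central channel, ``Fp1`` registers ocular artifacts only.
CHANNELS: tuple[str, ...] = ("Ci", "CPi", "Pi", "Cz", "Cc", "Fp1")

#: The five somatosensory channels used for classification (Fp1 excluded).
SOMATOSENSORY_CHANNELS: tuple[str, ...] = CHANNELS[:5]

#: Physical 10-20 electrode underlying each generalized label, per montage.
MONTAGES: dict[str, dict[str, str]] = {
    "right_impaired": {
        "Ci": "C3", "CPi": "CP5", "Pi": "P3", "Cz": "Cz", "Cc": "C4",
        "Fp1": "Fp1",
    },
    "left_impaired": {
        "Ci": "C4", "CPi": "CP6", "Pi": "P4", "Cz": "Cz", "Cc": "C3",
        "Fp1": "Fp1",
    },
}


class ConfigError(ValueError):
    """Raised when a ProtocolConfig violates a structural invariant."""


@dataclass(frozen=True)
class ProtocolConfig:
    """All acquisition and protocol constants.

    Onset-to-onset spacing uses ``isi`` (700 ms); the scheduled per-stimulus
    slot used for duration accounting is ``stim_period`` (750 ms), which
    reproduces the fixed 22.5 s block duration for 30 stimuli.  Both are kept
    as separate fields deliberately.
    """

    sampling_rate: float = 1200.0          # samples / s
    isi: float = 700.0                     # ms, onset-to-onset
    stim_period: float = 750.0             # ms, scheduled slot per stimulus
    n_training_blocks: int = 30
    blocks_per_task: int = 15
    stimuli_per_location_per_block: int = 15
    n_test_trials: int = 20
    trials_per_target: int = 10
    clean_epochs_per_location_per_trial: int = 10
    max_stimuli_per_trial: int = 30
    inter_block_pause: float = 5.0         # s
    epoch_window: tuple[float, float] = (-100.0, 600.0)   # ms
    baseline_window: tuple[float, float] = (-100.0, 0.0)  # ms
    filter_band: tuple[float, float] = (0.1, 25.0)        # Hz
    filter_order: int = 4
    eeg_reject_threshold: float = 50.0     # µV, somatosensory channels
    eog_reject_threshold: float = 80.0     # µV, Fp1
    downsample_factor: int = 8
    alpha: float = 0.05                    # screening significance level
    subaverage_size: int = 10              # epochs per sub-average
    lead_in: float = 5.0                   # s of recording excluded before the first event
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_training_blocks != 2 * self.blocks_per_task:
            raise ConfigError(
                "n_training_blocks must equal 2 * blocks_per_task "
                f"({self.n_training_blocks} != 2*{self.blocks_per_task})"
            )
        if self.n_test_trials != 2 * self.trials_per_target:
            raise ConfigError(
                "n_test_trials must equal 2 * trials_per_target "
                f"({self.n_test_trials} != 2*{self.trials_per_target})"
            )
        if self.max_stimuli_per_trial < 2 * self.clean_epochs_per_location_per_trial:
            raise ConfigError("max_stimuli_per_trial too small for required clean epochs")
        if self.epoch_window[0] >= self.epoch_window[1]:
            raise ConfigError("epoch_window must be increasing")
        if not (0 < self.filter_band[0] < self.filter_band[1] < self.sampling_rate / 2):
            raise ConfigError("filter_band must satisfy 0 < low < high < Nyquist")
        if self.sampling_rate <= 0 or self.isi <= 0 or self.stim_period <= 0:
            raise ConfigError("rates and periods must be positive")

    # -- derived sample counts -------------------------------------------------
    @property
    def isi_samples(self) -> int:
        return int(round(self.isi / 1000.0 * self.sampling_rate))

    @property
    def n_baseline_samples(self) -> int:
        """Samples in the pre-stimulus baseline (120 at defaults)."""
        return int(round(-self.epoch_window[0] / 1000.0 * self.sampling_rate))

    @property
    def n_post_samples(self) -> int:
        """Post-stimulus samples per epoch (720 at defaults)."""
        return int(round(self.epoch_window[1] / 1000.0 * self.sampling_rate))

    @property
    def n_epoch_samples(self) -> int:
        """Total samples per epoch (840 at defaults)."""
        return self.n_baseline_samples + self.n_post_samples

    @property
    def n_feature_samples(self) -> int:
        """Post-stimulus samples after decimation (90 at defaults)."""
        return -(-self.n_post_samples // self.downsample_factor)

    @property
    def stimuli_per_block(self) -> int:
        return 2 * self.stimuli_per_location_per_block

    def to_yaml(self, path: str | Path | None = None) -> str:
        d = dataclasses.asdict(self)
        for k in ("epoch_window", "baseline_window", "filter_band"):
            d[k] = list(d[k])
        text = yaml.safe_dump(d, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "ProtocolConfig":
        text = str(source)
        if isinstance(source, Path) or ("\n" not in text and Path(text).exists()):
            text = Path(source).read_text()
        raw = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        for k in ("epoch_window", "baseline_window", "filter_band"):
            if k in raw:
                raw[k] = tuple(raw[k])
        return cls(**raw)


@dataclass(frozen=True)
class StimulusEvent:
    """A single electrotactile stimulus in the continuous recording."""

    onset_sample: int          # 0-based sample index of stimulus onset
    location: Location         # stimulated location
    attended_location: Location
    phase: Phase
    unit_id: int               # block index (training) or trial index (test)
    seq_index: int             # position within its block/trial

    @property
    def condition(self) -> str:
        """Condition label: attended x stimulated (ADSD/ADSV/AVSD/AVSV)."""
        return f"A{self.attended_location}S{self.location}"


@dataclass
class EventTable:
    """Ordered stimulus stream plus montage metadata."""

    events: list[StimulusEvent]
    montage: str = "right_impaired"

    def __post_init__(self) -> None:
        if self.montage not in MONTAGES:
            raise ConfigError(f"unknown montage {self.montage!r}")
        onsets = [e.onset_sample for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ConfigError("events must be sorted by strictly increasing onset_sample")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[StimulusEvent]:
        return iter(self.events)

    def phase_events(self, phase: Phase) -> list[StimulusEvent]:
        return [e for e in self.events if e.phase == phase]

    def units(self, phase: Phase) -> dict[int, list[StimulusEvent]]:
        """Events of one phase grouped by block/trial id, preserving order."""
        out: dict[int, list[StimulusEvent]] = {}
        for e in self.phase_events(phase):
            out.setdefault(e.unit_id, []).append(e)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dataclasses.asdict(e) for e in self.events],
            columns=["onset_sample", "location", "attended_location",
                     "phase", "unit_id", "seq_index"],
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# montage={self.montage}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EventTable":
        text = Path(path).read_text()
        montage = "right_impaired"
        body = text
        if text.startswith("# montage="):
            header, body = text.split("\n", 1)
            montage = header[len("# montage="):].strip()
        df = pd.read_csv(io.StringIO(body), sep="\t")
        events = [
            StimulusEvent(
                onset_sample=int(r.onset_sample),
                location=str(r.location),
                attended_location=str(r.attended_location),
                phase=str(r.phase),
                unit_id=int(r.unit_id),
                seq_index=int(r.seq_index),
            )
            for r in df.itertuples()
        ]
        return cls(events=events, montage=montage)


def _balanced_shuffle(n_per_location: int, rng: np.random.Generator) -> list[str]:
    locs = ["D"] * n_per_location + ["V"] * n_per_location
    rng.shuffle(locs)
    return locs


def schedule_block(
    config: ProtocolConfig,
    attended: Location,
    block_id: int,
    start_sample: int,
    rng: np.random.Generator,
) -> list[StimulusEvent]:
    """Schedule one training block.

    Returns ``2 * stimuli_per_location_per_block`` events whose location
    sequence is a uniform shuffle of the balanced D/V multiset, with onsets
    spaced ``isi`` apart and all carrying ``attended_location = attended``.
    """
    locs = _balanced_shuffle(config.stimuli_per_location_per_block, rng)
    step = config.isi_samples
    return [
        StimulusEvent(
            onset_sample=start_sample + i * step,
            location=loc,
            attended_location=attended,
            phase="training",
            unit_id=block_id,
            seq_index=i,
        )
        for i, loc in enumerate(locs)
    ]


def schedule_trial(
    config: ProtocolConfig,
    target: Location,
    trial_id: int,
    start_sample: int,
    rng: np.random.Generator,
) -> list[StimulusEvent]:
    """Schedule one online test trial's stimulus budget.

    The first ``2 * clean_epochs_per_location_per_trial`` stimuli (20 at
    defaults) are a balanced shuffled multiset; the remaining budget up to
    ``max_stimuli_per_trial`` alternates D/V so the online loop can draw
    replacement stimuli for whichever location still lacks clean epochs.
    """
    n_core = 2 * config.clean_epochs_per_location_per_trial
    locs = _balanced_shuffle(config.clean_epochs_per_location_per_trial, rng)
    extra = config.max_stimuli_per_trial - n_core
    first = rng.permutation(["D", "V"])
    locs += [first[i % 2] for i in range(extra)]
    step = config.isi_samples
    return [
        StimulusEvent(
            onset_sample=start_sample + i * step,
            location=loc,
            attended_location=target,
            phase="test",
            unit_id=trial_id,
            seq_index=i,
        )
        for i, loc in enumerate(locs)
    ]


def block_duration(config: ProtocolConfig, n_stimuli: int | None = None) -> float:
    """Scheduled duration of one block/trial in seconds.

    Uses the 750 ms per-stimulus slot, giving the fixed 22.5 s block for 30
    stimuli and 15 s for a 20-stimulus trial.
    """
    if n_stimuli is None:
        n_stimuli = config.stimuli_per_block
    return n_stimuli * config.stim_period / 1000.0


def training_phase_duration(config: ProtocolConfig) -> float:
    """Total scheduled training-phase duration in seconds, pauses included."""
    n = config.n_training_blocks
    return n * block_duration(config) + (n - 1) * config.inter_block_pause


def schedule_session(
    config: ProtocolConfig,
    first_target: Location = "D",
    rng: np.random.Generator | int | None = None,
    montage: str = "right_impaired",
) -> EventTable:
    """Schedule a full two-phase session.

    Training blocks alternate the attended location starting from
    ``first_target``; test-phase targets are a seeded shuffle of the balanced
    10+10 target multiset (the experimenter's pseudo-randomization).  Unit
    slots are separated by ``inter_block_pause`` and sized by
    ``stim_period``; a ``lead_in`` precedes the first stimulus.
    """
    if rng is None:
        rng = config.random_seed
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    fs = config.sampling_rate
    pause = int(round(config.inter_block_pause * fs))
    events: list[StimulusEvent] = []
    cursor = int(round(config.lead_in * fs))

    other = {"D": "V", "V": "D"}
    attended = first_target
    slot = int(round(block_duration(config) * fs))
    for b in range(config.n_training_blocks):
        events.extend(schedule_block(config, attended, b, cursor, rng))
        attended = other[attended]
        cursor += slot + pause

    targets = _balanced_shuffle(config.trials_per_target, rng)
    trial_slot = int(round(block_duration(config, config.max_stimuli_per_trial) * fs))
    for t, target in enumerate(targets):
        events.extend(schedule_trial(config, target, t, cursor, rng))
        cursor += trial_slot + pause

    return EventTable(events=events, montage=montage)
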