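"""Simulated online test phase: trial loop, accuracy and information rate.

Each trial delivers stimuli until 10 artifact-free epochs are available per
stimulation location (or the 30-stimulus budget is exhausted).  The two
10-epoch averages are decimated, the training-phase index sets iD/iV are
applied, and each channel's SVM classifies the resulting vector; the
subject sees the selected feedback channel's decision.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import TrainedBci
from .preprocess import Epoch, preprocess_session
from .protocol import CHANNELS, SOMATOSENSORY_CHANNELS, EventTable, ProtocolConfig

SUBSET_1: tuple[str, ...] = ("Ci", "CPi", "Pi")   # ipsilesional channels
SUBSET_2: tuple[str, ...] = ("Cz", "Cc")          # midline + contralesional


@dataclass
class TrialOutcome:
    """Result of one online classification attempt."""

    trial_id: int
    target: str                       # attended location {D, V}
    predictions: dict[str, str]       # channel -> {AD, AV}
    feedback_prediction: str | None
    stimuli_delivered: int
    epochs_rejected: int
    status: str = "ok"                # "ok" | "budget_exhausted"

    @property
    def completed(self) -> bool:
        return self.status == "ok"

    @property
    def target_label(self) -> str:
        return f"A{self.target}"


@dataclass
class TrialTally:
    """Per-channel confusion counts over completed trials."""

    TP_AD: int = 0
    TP_AV: int = 0
    FP_AD: int = 0   # attended-D trials misclassified as AV
    FP_AV: int = 0   # attended-V trials misclassified as AD

    @property
    def total(self) -> int:
        return self.TP_AD + self.TP_AV + self.FP_AD + self.FP_AV

    def update(self, target_label: str, predicted: str) -> None:
        if target_label == "AD":
            if predicted == "AD":
                self.TP_AD += 1
            else:
                self.FP_AD += 1
        else:
            if predicted == "AV":
                self.TP_AV += 1
            else:
                self.FP_AV += 1


def compute_accuracy(tally: TrialTally) -> float:
    """Per-channel accuracy in percent: 100 (TP_AD + TP_AV) / all trials."""
    if tally.total == 0:
        raise ValueError("accuracy undefined: no completed trials in tally")
    return 100.0 * (tally.TP_AD + tally.TP_AV) / tally.total


def compute_itr(n_targets: int, seconds_per_decision: float,
                accuracy: float) -> float:
    """Wolpaw information transfer rate in bits/min.

    Bits per decision ``B = log2 N + P log2 P + (1-P) log2((1-P)/(N-1))``
    with the conventions ``B = log2 N`` at P = 1 and ``0 log2 0 = 0``;
    ITR = 60 B / T.
    """
    if n_targets < 2:
        raise ValueError("n_targets must be at least 2")
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError("accuracy must be a fraction in [0, 1]")
    if seconds_per_decision <= 0:
        raise ValueError("seconds_per_decision must be positive")
    p, n = accuracy, n_targets
    bits = np.log2(n)
    if p > 0:
        bits += p * np.log2(p)
    if p < 1:
        bits += (1 - p) * np.log2((1 - p) / (n - 1))
    return float(60.0 * bits / seconds_per_decision)


def _decimated_average(epochs: list[Epoch], config: ProtocolConfig) -> np.ndarray:
    """Mean of epochs, post-stimulus window decimated to 90 samples."""
    stack = np.stack([e.data for e in epochs]).mean(axis=0)
    return stack[:, config.n_baseline_samples:][:, ::config.downsample_factor]


def run_trial(
    epochs: list[Epoch],
    trained: TrainedBci,
    config: ProtocolConfig,
) -> TrialOutcome:
    """Run the online loop for one trial's scheduled epoch stream.

    The first ``2 x clean_epochs_per_location_per_trial`` scheduled stimuli
    (a balanced multiset) are always delivered; the remaining scheduled
    budget serves as replacement stimuli delivered only for a location still
    lacking clean epochs.  The trial aborts with status
    ``"budget_exhausted"`` if the budget runs out first.
    """
    if not epochs:
        raise ValueError("empty trial stream")
    needed = config.clean_epochs_per_location_per_trial
    target = epochs[0].attended
    trial_id = epochs[0].unit_id
    core = 2 * needed

    collected: dict[str, list[Epoch]] = {"D": [], "V": []}
    delivered = 0
    rejected = 0

    def _full() -> bool:
        return all(len(v) >= needed for v in collected.values())

    for ep in epochs[:core]:
        delivered += 1
        if ep.accepted:
            collected[ep.stimulated].append(ep)
        else:
            rejected += 1
        if _full():
            break
    for ep in epochs[core:]:
        if _full():
            break
        if len(collected[ep.stimulated]) >= needed:
            continue   # replacement not needed for this location
        delivered += 1
        if ep.accepted:
            collected[ep.stimulated].append(ep)
        else:
            rejected += 1

    if not _full():
        return TrialOutcome(
            trial_id=trial_id, target=target, predictions={},
            feedback_prediction=None, stimuli_delivered=delivered,
            epochs_rejected=rejected, status="budget_exhausted",
        )

    avg = {loc: _decimated_average(eps[:needed], config)
           for loc, eps in collected.items()}
    predictions: dict[str, str] = {}
    for ch in SOMATOSENSORY_CHANNELS:
        m = trained.channels[ch]
        row = CHANNELS.index(ch)
        vec = np.concatenate([avg["D"][row][m.index_set.iD],
                              avg["V"][row][m.index_set.iV]])
        predictions[ch] = m.predict(vec)
    return TrialOutcome(
        trial_id=trial_id, target=target, predictions=predictions,
        feedback_prediction=predictions[trained.feedback_channel],
        stimuli_delivered=delivered, epochs_rejected=rejected,
    )


@dataclass
class SessionResult:
    """Per-channel accuracies and summary measures of one test session."""

    per_channel_accuracy: dict[str, float]   # percent
    max_accuracy: float
    max_subset1: float                       # over Ci, CPi, Pi
    max_subset2: float                       # over Cz, Cc
    feedback_channel: str
    feedback_accuracy: float
    itr_bpm: float
    mean_decision_time_s: float
    n_trials_completed: int
    n_trials_aborted: int
    tallies: dict[str, TrialTally] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        import json

        d = {
            "per_channel_accuracy": self.per_channel_accuracy,
            "max_accuracy": self.max_accuracy,
            "max_subset1": self.max_subset1,
            "max_subset2": self.max_subset2,
            "feedback_channel": self.feedback_channel,
            "feedback_accuracy": self.feedback_accuracy,
            "itr_bpm": self.itr_bpm,
            "mean_decision_time_s": self.mean_decision_time_s,
            "n_trials_completed": self.n_trials_completed,
            "n_trials_aborted": self.n_trials_aborted,
            "tallies": {ch: dataclasses.asdict(t)
                        for ch, t in self.tallies.items()},
        }
        text = json.dumps(d, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def summarize_trials(
    outcomes: list[TrialOutcome],
    trained: TrainedBci,
    config: ProtocolConfig,
) -> SessionResult:
    """Tally completed trials and compute session-level measures."""
    tallies = {ch: TrialTally() for ch in SOMATOSENSORY_CHANNELS}
    completed = [o for o in outcomes if o.completed]
    if not completed:
        raise ValueError("no completed trials")
    for o in completed:
        for ch in SOMATOSENSORY_CHANNELS:
            tallies[ch].update(o.target_label, o.predictions[ch])
    acc = {ch: compute_accuracy(t) for ch, t in tallies.items()}
    mean_t = float(np.mean([o.stimuli_delivered for o in completed])) \
        * config.isi / 1000.0
    fb = trained.feedback_channel
    return SessionResult(
        per_channel_accuracy=acc,
        max_accuracy=max(acc.values()),
        max_subset1=max(acc[c] for c in SUBSET_1),
        max_subset2=max(acc[c] for c in SUBSET_2),
        feedback_channel=fb,
        feedback_accuracy=acc[fb],
        itr_bpm=compute_itr(2, mean_t, acc[fb] / 100.0),
        mean_decision_time_s=mean_t,
        n_trials_completed=len(completed),
        n_trials_aborted=len(outcomes) - len(completed),
        tallies=tallies,
    )


def run_test_phase(
    signal: np.ndarray,
    events: EventTable,
    trained: TrainedBci,
    config: ProtocolConfig,
) -> tuple[SessionResult, list[TrialOutcome]]:
    """Run all scheduled test trials of a continuous recording."""
    epochs = preprocess_session(signal, events, config, phase="test")
    by_trial: dict[int, list[Epoch]] = {}
    for ep in epochs:
        by_trial.setdefault(ep.unit_id, []).append(ep)
    outcomes = [run_trial(sorted(eps, key=lambda e: e.seq_index),
                          trained, config)
                for _, eps in sorted(by_trial.items())]
    return summarize_trials(outcomes, trained, config), outcomes


def trial_log_frame(outcomes: list[TrialOutcome]) -> pd.DataFrame:
    rows = []
    for o in outcomes:
        row = {"trial_id": o.trial_id, "target": o.target}
        for ch in SOMATOSENSORY_CHANNELS:
            row[f"pred_{ch}"] = o.predictions.get(ch, "")
        row.update(
            feedback_prediction=o.feedback_prediction or "",
            stimuli_delivered=o.stimuli_delivered,
            epochs_rejected=o.epochs_rejected,
            status=o.status,
        )
        rows.append(row)
    return pd.DataFrame(rows)
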