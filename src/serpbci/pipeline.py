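"""End-to-end convenience layer: simulate -> train -> online test."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import ChannelIndexSet, extract_features
from .model import ChannelModel, TrainedBci, select_feedback_channel, train_channel
from .online import SessionResult, TrialOutcome, run_test_phase
from .preprocess import cluster_and_balance, preprocess_session
from .protocol import SOMATOSENSORY_CHANNELS, EventTable, ProtocolConfig
from .synthdata import NoiseModel, SerpTemplate, SyntheticSession, generate_session


@dataclass
class TrainingReport:
    """Diagnostics of one classifier-training run."""

    cluster_sizes: dict[str, int]
    balanced_size: int
    n_subaverages: int
    n_rejected_epochs: int
    index_counts: dict[str, tuple[int, int]]       # channel -> (|iD|, |iV|)
    fallback_channels: list[str]
    loocv_accuracy: dict[str, float]
    feedback_channel: str

    def to_dict(self) -> dict:
        return {
            "cluster_sizes": self.cluster_sizes,
            "balanced_size": self.balanced_size,
            "n_subaverages": self.n_subaverages,
            "n_rejected_epochs": self.n_rejected_epochs,
            "index_counts": {k: list(v) for k, v in self.index_counts.items()},
            "fallback_channels": self.fallback_channels,
            "loocv_accuracy": self.loocv_accuracy,
            "feedback_channel": self.feedback_channel,
        }


def train_bci(
    signal: np.ndarray,
    events: EventTable,
    config: ProtocolConfig,
) -> tuple[TrainedBci, TrainingReport]:
    """Train the five channel classifiers from a training-phase recording."""
    epochs = preprocess_session(signal, events, config, phase="training")
    n_rej = sum(not e.accepted for e in epochs)
    pre_sizes: dict[str, int] = {}
    for e in epochs:
        if e.accepted:
            pre_sizes[e.condition] = pre_sizes.get(e.condition, 0) + 1
    clusters = cluster_and_balance(epochs)
    balanced = len(next(iter(clusters.values())))
    subs, index_sets, vectors = extract_features(clusters, config)
    models: dict[str, ChannelModel] = {
        ch: train_channel(vectors[ch], config, index_set=index_sets[ch])
        for ch in SOMATOSENSORY_CHANNELS
    }
    trained = select_feedback_channel(models, config)
    report = TrainingReport(
        cluster_sizes=pre_sizes,
        balanced_size=balanced,
        n_subaverages=len(subs["ADSD"]),
        n_rejected_epochs=n_rej,
        index_counts={ch: (len(s.iD), len(s.iV))
                      for ch, s in index_sets.items()},
        fallback_channels=[ch for ch, s in index_sets.items()
                           if s.fallback_d or s.fallback_v],
        loocv_accuracy={ch: m.loocv_accuracy for ch, m in models.items()},
        feedback_channel=trained.feedback_channel,
    )
    return trained, report


def run_simulated_session(
    config: ProtocolConfig,
    templates: dict[str, SerpTemplate] | None = None,
    noise: NoiseModel | None = None,
    seed: int | None = None,
    montage: str = "right_impaired",
) -> tuple[SyntheticSession, TrainedBci, TrainingReport, SessionResult,
           list[TrialOutcome]]:
    """Simulate one full two-phase session and run the whole pipeline."""
    if noise is None:
        noise = NoiseModel(seed=config.random_seed if seed is None else seed)
    elif seed is not None:
        noise = NoiseModel(**{**noise.__dict__, "seed": seed})
    session = generate_session(config, templates=templates, noise=noise,
                               montage=montage)
    trained, report = train_bci(session.signal, session.events, config)
    result, outcomes = run_test_phase(session.signal, session.events,
                                      trained, config)
    return session, trained, report, result, outcomes
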