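"""Per-channel RBF-SVM attention classifiers and feedback-channel selection.

One binary SVM (radial basis kernel) is trained per somatosensory channel on
that channel's AD/AV feature vectors.  The kernel scale is set by the
parameter-free median-pairwise-distance heuristic computed once on the full
training set (gamma = 1 / scale^2), the regularization constant is fixed at
C = 1, and leave-one-out cross-validation over all vectors estimates each
channel's accuracy.  The channel with the highest estimate drives the
subject's online feedback; ties break in ipsilesional-priority order
Ci > CPi > Pi > Cz > Cc.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.svm import SVC

from .features import ChannelIndexSet, FeatureVector
from .protocol import SOMATOSENSORY_CHANNELS, ProtocolConfig

CLASS_LABELS = ("AD", "AV")


def median_pairwise_distance(x: np.ndarray) -> float:
    """Median Euclidean distance among all training-vector pairs.

    Falls back to 1.0 when the median distance is zero (degenerate data).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        return 1.0
    med = float(np.median(pdist(x)))
    return med if med > 0 else 1.0


def _fit_svc(x: np.ndarray, y: np.ndarray, gamma: float, c: float) -> SVC:
    clf = SVC(kernel="rbf", C=c, gamma=gamma)
    clf.fit(x, y)
    return clf


@dataclass
class ChannelModel:
    """A trained attention classifier for one EEG channel."""

    channel: str
    x: np.ndarray                   # n_vectors x n_features training matrix
    y: np.ndarray                   # class labels, {AD, AV}
    kernel_scale: float
    c: float
    index_set: ChannelIndexSet
    loocv_accuracy: float
    _svc: SVC = field(repr=False, default=None)

    @property
    def gamma(self) -> float:
        return 1.0 / self.kernel_scale ** 2

    def predict(self, vector: np.ndarray) -> str:
        vector = np.asarray(vector, dtype=float).reshape(1, -1)
        if vector.shape[1] != self.x.shape[1]:
            raise ValueError(
                f"expected {self.x.shape[1]} features, got {vector.shape[1]}")
        return str(self._svc.predict(vector)[0])


def train_channel(
    vectors: list[FeatureVector],
    config: ProtocolConfig,
    index_set: ChannelIndexSet | None = None,
    c: float = 1.0,
) -> ChannelModel:
    """Train one channel's SVM and estimate its leave-one-out accuracy."""
    if not vectors:
        raise ValueError("no feature vectors")
    channel = vectors[0].channel
    x = np.stack([v.values for v in vectors])
    y = np.array([v.class_label for v in vectors])
    for label in CLASS_LABELS:
        if (y == label).sum() < 2:
            raise ValueError(f"need at least 2 vectors of class {label}")
    if (y == "AD").sum() != (y == "AV").sum():
        raise ValueError("class counts must be equal")

    scale = median_pairwise_distance(x)
    gamma = 1.0 / scale ** 2

    n = len(x)
    correct = 0
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        clf = _fit_svc(x[mask], y[mask], gamma, c)
        correct += int(clf.predict(x[i:i + 1])[0] == y[i])
        mask[i] = True
    loocv = correct / n

    if index_set is None:
        index_set = ChannelIndexSet(
            channel=channel, iD=np.arange(x.shape[1]), iV=np.array([], int),
            p_d=np.array([]), p_v=np.array([]))
    return ChannelModel(
        channel=channel, x=x, y=y, kernel_scale=scale, c=c,
        index_set=index_set, loocv_accuracy=loocv,
        _svc=_fit_svc(x, y, gamma, c),
    )


@dataclass
class TrainedBci:
    """The five per-channel models plus the selected feedback channel."""

    channels: dict[str, ChannelModel]
    feedback_channel: str
    config: ProtocolConfig

    def predict_all(self, vectors_by_channel: dict[str, np.ndarray]) -> dict[str, str]:
        return {ch: m.predict(vectors_by_channel[ch])
                for ch, m in self.channels.items()}

    # -- persistence ---------------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        def _ser(m: ChannelModel) -> dict:
            return {
                "channel": m.channel,
                "x": m.x.tolist(),
                "y": m.y.tolist(),
                "kernel_scale": m.kernel_scale,
                "c": m.c,
                "loocv_accuracy": m.loocv_accuracy,
                "iD": m.index_set.iD.tolist(),
                "iV": m.index_set.iV.tolist(),
                "p_d": m.index_set.p_d.tolist(),
                "p_v": m.index_set.p_v.tolist(),
                "fallback_d": m.index_set.fallback_d,
                "fallback_v": m.index_set.fallback_v,
            }
        payload = {
            "format": "serpbci.trained_bci.v1",
            "config": self.config.to_yaml(),
            "config_sha1": hashlib.sha1(
                self.config.to_yaml().encode()).hexdigest(),
            "feedback_channel": self.feedback_channel,
            "channels": {ch: _ser(m) for ch, m in self.channels.items()},
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "TrainedBci":
        text = str(source)
        if isinstance(source, Path) or ("\n" not in text and "{" not in text
                                        and Path(text).exists()):
            text = Path(source).read_text()
        payload = json.loads(text)
        if payload.get("format") != "serpbci.trained_bci.v1":
            raise ValueError("not a serpbci model archive")
        config = ProtocolConfig.from_yaml(payload["config"])
        channels: dict[str, ChannelModel] = {}
        for ch, d in payload["channels"].items():
            x = np.asarray(d["x"], dtype=float)
            y = np.asarray(d["y"], dtype=str)
            scale = float(d["kernel_scale"])
            idx = ChannelIndexSet(
                channel=ch,
                iD=np.asarray(d["iD"], dtype=int),
                iV=np.asarray(d["iV"], dtype=int),
                p_d=np.asarray(d["p_d"], dtype=float),
                p_v=np.asarray(d["p_v"], dtype=float),
                fallback_d=bool(d["fallback_d"]),
                fallback_v=bool(d["fallback_v"]),
            )
            channels[ch] = ChannelModel(
                channel=ch, x=x, y=y, kernel_scale=scale, c=float(d["c"]),
                index_set=idx, loocv_accuracy=float(d["loocv_accuracy"]),
                _svc=_fit_svc(x, y, 1.0 / scale ** 2, float(d["c"])),
            )
        return cls(channels=channels,
                   feedback_channel=payload["feedback_channel"],
                   config=config)


def select_feedback_channel(
    models: dict[str, ChannelModel],
    config: ProtocolConfig,
) -> TrainedBci:
    """Pick the feedback channel as the LOOCV-accuracy argmax.

    Deterministic tie-break follows ipsilesional priority:
    Ci > CPi > Pi > Cz > Cc.
    """
    missing = set(SOMATOSENSORY_CHANNELS) - set(models)
    if missing:
        raise ValueError(f"missing channel model(s): {sorted(missing)}")
    best = max(SOMATOSENSORY_CHANNELS,
               key=lambda ch: (models[ch].loocv_accuracy,
                               -SOMATOSENSORY_CHANNELS.index(ch)))
    return TrainedBci(channels=dict(models), feedback_channel=best,
                      config=config)
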