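"""Feature extraction: sub-averaging, rank-sum screening, feature vectors.

Ten consecutive epochs of a condition cluster are averaged into one
sub-average sERP; sub-averages are decimated to 90 post-stimulus samples.
For each channel and each time index, the Wilcoxon rank-sum test compares
attended vs unattended sub-averages of the same stimulated location
(ADSD vs AVSD for location D, AVSV vs ADSV for location V); indices with
p < alpha form the sets iD and iV.  Feature vectors per class are the
flattened concatenation [stimulated-D amplitudes at iD, stimulated-V
amplitudes at iV].
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .preprocess import CONDITIONS, Epoch, EpochCluster
from .protocol import CHANNELS, ProtocolConfig

#: largest per-group size for which the exact permutation null is enumerated
EXACT_ENUMERATION_MAX_N = 8


@dataclass
class SubAverage:
    """Average of one chronological group of 10 epochs, decimated."""

    condition: str
    group_index: int
    data: np.ndarray       # channels x 90 post-stimulus samples, µV


def make_subaverages(cluster: EpochCluster, config: ProtocolConfig) -> list[SubAverage]:
    """Partition a cluster chronologically into groups of ``subaverage_size``.

    Each group is averaged per channel; only post-stimulus samples are kept
    and decimated by taking every ``downsample_factor``-th sample starting at
    the stimulus onset (90 values at defaults).  Leftover epochs
    (``len(cluster) mod subaverage_size``) are discarded.
    """
    k = config.subaverage_size
    if len(cluster) < k:
        raise ValueError(
            f"cluster {cluster.condition} has {len(cluster)} epochs; "
            f"need at least {k} for one sub-average"
        )
    epochs = sorted(cluster.epochs, key=lambda e: e.onset_sample)
    nb = config.n_baseline_samples
    step = config.downsample_factor
    out: list[SubAverage] = []
    for g in range(len(epochs) // k):
        stack = np.stack([e.data for e in epochs[g * k:(g + 1) * k]])
        avg = stack.mean(axis=0)[:, nb:][:, ::step]
        out.append(SubAverage(condition=cluster.condition, group_index=g, data=avg))
    return out


def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Ties receive midranks.  For group sizes of at most
    ``EXACT_ENUMERATION_MAX_N`` the permutation null of the rank sum is
    enumerated exactly; larger groups use the normal approximation with tie
    and continuity corrections.  Degenerate input (every value identical
    across both groups) returns p = 1.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n, m = len(x), len(y)
    if n < 2 or m < 2:
        raise ValueError("both groups need at least 2 observations")
    combined = np.concatenate([x, y])
    if np.ptp(combined) == 0:
        return 1.0
    ranks = _midranks(combined)
    w = ranks[:n].sum()
    big_n = n + m
    mu = n * (big_n + 1) / 2.0
    if max(n, m) <= EXACT_ENUMERATION_MAX_N:
        dev = abs(w - mu)
        count = 0
        total = 0
        for idx in itertools.combinations(range(big_n), n):
            total += 1
            if abs(ranks[list(idx)].sum() - mu) >= dev - 1e-9:
                count += 1
        return count / total
    # normal approximation with tie correction and continuity correction
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()
                / ((big_n) * (big_n - 1.0)))
    sigma2 = n * m / 12.0 * ((big_n + 1.0) - tie_term)
    if sigma2 <= 0:
        return 1.0
    z = (w - mu - 0.5 * np.sign(w - mu)) / np.sqrt(sigma2)
    return float(2.0 * stats.norm.sf(abs(z)))


@dataclass
class ChannelIndexSet:
    """Screened time indices for one EEG channel."""

    channel: str
    iD: np.ndarray                 # sorted indices in 0..89
    iV: np.ndarray
    p_d: np.ndarray                # per-index p-values, location D contrast
    p_v: np.ndarray
    fallback_d: bool = False       # True when iD fell back to the min-p index
    fallback_v: bool = False

    @property
    def n_features(self) -> int:
        return len(self.iD) + len(self.iV)


#: mapping of screened location to its (attended, unattended) condition pair
SCREENING_CONTRASTS: dict[str, tuple[str, str]] = {
    "D": ("ADSD", "AVSD"),
    "V": ("AVSV", "ADSV"),
}


def screen_indices(
    subaverages: dict[str, list[SubAverage]],
    channel: str,
    config: ProtocolConfig,
) -> ChannelIndexSet:
    """Per-time-index rank-sum screening for one channel.

    Index ``t`` enters iD iff the ADSD vs AVSD rank-sum p-value at ``t`` is
    below ``alpha`` (iV analogously from AVSV vs ADSV).  If a location
    yields no significant index, the single minimum-p index is retained and
    the channel flagged, so the downstream classifier always receives a
    non-empty feature vector.
    """
    row = CHANNELS.index(channel)
    n_t = subaverages[CONDITIONS[0]][0].data.shape[1]
    sets: dict[str, np.ndarray] = {}
    pvals: dict[str, np.ndarray] = {}
    fallback: dict[str, bool] = {}
    for loc, (cond_att, cond_unatt) in SCREENING_CONTRASTS.items():
        a = np.stack([s.data[row] for s in subaverages[cond_att]])
        b = np.stack([s.data[row] for s in subaverages[cond_unatt]])
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need at least 2 sub-averages per condition")
        p = np.array([rank_sum_test(a[:, t], b[:, t]) for t in range(n_t)])
        sig = np.flatnonzero(p < config.alpha)
        fb = len(sig) == 0
        if fb:
            sig = np.array([int(np.argmin(p))])
        sets[loc], pvals[loc], fallback[loc] = sig, p, fb
    return ChannelIndexSet(
        channel=channel, iD=sets["D"], iV=sets["V"],
        p_d=pvals["D"], p_v=pvals["V"],
        fallback_d=fallback["D"], fallback_v=fallback["V"],
    )


@dataclass
class FeatureVector:
    """Flattened two-location amplitude vector for one attention class."""

    values: np.ndarray
    class_label: str               # {AD, AV}
    channel: str
    group_index: int


def build_feature_vectors(
    subaverages: dict[str, list[SubAverage]],
    index_set: ChannelIndexSet,
    channel: str,
) -> list[FeatureVector]:
    """Form paired AD/AV feature vectors for one channel.

    Sub-averages are paired by group index k:
    ``AD_k = [ADSD_k[iD], ADSV_k[iV]]`` and
    ``AV_k = [AVSD_k[iD], AVSV_k[iV]]``.
    """
    counts = {c: len(subaverages[c]) for c in CONDITIONS}
    if len(set(counts.values())) != 1:
        raise ValueError(f"mismatched sub-average counts per condition: {counts}")
    row = CHANNELS.index(channel)
    iD, iV = index_set.iD, index_set.iV
    out: list[FeatureVector] = []
    for k in range(counts["ADSD"]):
        for label, c_d, c_v in (("AD", "ADSD", "ADSV"), ("AV", "AVSD", "AVSV")):
            vec = np.concatenate([
                subaverages[c_d][k].data[row][iD],
                subaverages[c_v][k].data[row][iV],
            ])
            out.append(FeatureVector(values=vec, class_label=label,
                                     channel=channel, group_index=k))
    return out


def extract_features(
    clusters: dict[str, EpochCluster],
    config: ProtocolConfig,
) -> tuple[dict[str, list[SubAverage]], dict[str, ChannelIndexSet],
           dict[str, list[FeatureVector]]]:
    """Full feature stage for all somatosensory channels."""
    from .protocol import SOMATOSENSORY_CHANNELS

    subs = {c: make_subaverages(clusters[c], config) for c in CONDITIONS}
    index_sets = {ch: screen_indices(subs, ch, config)
                  for ch in SOMATOSENSORY_CHANNELS}
    vectors = {ch: build_feature_vectors(subs, index_sets[ch], ch)
               for ch in SOMATOSENSORY_CHANNELS}
    return subs, index_sets, vectors
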