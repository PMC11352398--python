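"""Cohort summaries, subset comparison and grand-average sERP waveforms.

The shipped cohort fixture transcribes the published per-patient online
accuracy table of the ten-patient feasibility study (one row per patient:
per-channel accuracies, best channel overall and best channel within the
ipsilesional and midline/contralesional subsets).

Quartile convention: the median is the mean of the two middle order
statistics; Q1/Q3 use the nearest-rank (inverted CDF) definition.  This is
the convention that reproduces the published summary row exactly and it is
fixed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .online import SUBSET_1, SUBSET_2
from .preprocess import CONDITIONS, Epoch
from .protocol import CHANNELS, SOMATOSENSORY_CHANNELS, ProtocolConfig

ACCURACY_COLUMNS: tuple[str, ...] = (
    "Ci", "CPi", "Pi", "Cz", "Cc", "max_all", "max_subset1", "max_subset2")


def load_table2() -> pd.DataFrame:
    """Published per-patient online accuracy table (cohort fixture)."""
    with resources.files("serpbci.data").joinpath("table2.csv").open() as fh:
        return pd.read_csv(fh)


def quartiles(values) -> tuple[float, float, float]:
    """(median, Q1, Q3) under the fixed cohort convention."""
    v = np.asarray(values, dtype=float)
    med = float(np.median(v))
    q1, q3 = np.quantile(v, [0.25, 0.75], method="inverted_cdf")
    return med, float(q1), float(q3)


def summarize_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Median and (Q1, Q3) per accuracy column of a cohort table.

    Row-wise maxima (over all five channels and over each subset) are
    recomputed from the per-channel columns rather than trusted from the
    input, then summarized alongside them.  Returns a frame indexed by
    column with columns ``median``, ``q1``, ``q3``.
    """
    if len(table) == 0:
        raise ValueError("empty cohort table")
    t = table.copy()
    t["max_all"] = t[list(SOMATOSENSORY_CHANNELS)].max(axis=1)
    t["max_subset1"] = t[list(SUBSET_1)].max(axis=1)
    t["max_subset2"] = t[list(SUBSET_2)].max(axis=1)
    rows = {}
    for col in ACCURACY_COLUMNS:
        med, q1, q3 = quartiles(t[col])
        rows[col] = {"median": med, "q1": q1, "q3": q3}
    return pd.DataFrame(rows).T[["median", "q1", "q3"]]


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test (paired subset comparison)

#: largest n for which the exact signed-rank null is computed
EXACT_SIGNED_RANK_MAX_N = 25


def signed_rank_test(differences) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped; ties among |differences| receive midranks.
    For n <= 25 the exact null distribution of W+ is computed by dynamic
    programming over the (doubled, hence integer) midranks; larger n uses
    the normal approximation.  Returns ``(W, p)`` where W is the smaller of
    the signed-rank sums.  All-zero differences give p = 1.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d), method="average")
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    w = min(w_pos, w_neg)
    if n > EXACT_SIGNED_RANK_MAX_N:
        res = stats.wilcoxon(d, correction=True, method="approx")
        return w, float(res.pvalue)
    # exact: distribution of 2*W+ over all 2^n sign assignments
    r2 = np.rint(2 * ranks).astype(int)
    total = r2.sum()
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:len(counts) - r]
        counts = counts + shifted
    counts /= 2.0 ** n
    w2 = int(np.rint(2 * w))
    p = 2.0 * counts[:w2 + 1].sum()
    return w, float(min(p, 1.0))


def compare_subsets(table: pd.DataFrame) -> tuple[float, float]:
    """Paired comparison of best ipsilesional vs best midline/contralesional
    channel accuracy across patients (two-sided Wilcoxon signed-rank)."""
    if len(table) < 6:
        raise ValueError("need at least 6 paired rows")
    s1 = table[list(SUBSET_1)].max(axis=1).to_numpy(dtype=float)
    s2 = table[list(SUBSET_2)].max(axis=1).to_numpy(dtype=float)
    return signed_rank_test(s1 - s2)


# ---------------------------------------------------------------------------
# Grand averages and divergence onset

#: condition pairs (attended, unattended) per stimulated location
_ATTENTION_PAIRS: dict[str, tuple[str, str]] = {
    "D": ("ADSD", "AVSD"),
    "V": ("AVSV", "ADSV"),
}


@dataclass
class GrandAverage:
    """Condition x channel mean waveforms and attention-divergence onsets."""

    means: dict[str, np.ndarray]       # condition -> channels x 840 samples
    times_ms: np.ndarray               # -100..600 ms axis
    n_epochs: dict[str, int]
    divergence_onset_ms: dict[tuple[str, str], float | None] = field(
        default_factory=dict)          # (stimulated location, channel)


def grand_average(
    epochs: list[Epoch],
    config: ProtocolConfig,
    criterion_factor: float = 3.0,
    min_consecutive: int = 5,
) -> GrandAverage:
    """Per-condition grand averages plus divergence-onset estimates.

    For each stimulated location and channel, the attended-minus-unattended
    difference waveform is compared against ``criterion_factor`` times its
    own baseline-period standard deviation; the divergence onset is the
    earliest post-stimulus time at which the criterion is exceeded for at
    least ``min_consecutive`` consecutive samples (None if never).
    """
    accepted = [e for e in epochs if e.accepted]
    if not accepted:
        raise ValueError("no accepted epochs")
    means: dict[str, np.ndarray] = {}
    n_epochs: dict[str, int] = {}
    for cond in CONDITIONS:
        sel = [e.data for e in accepted if e.condition == cond]
        if sel:
            means[cond] = np.stack(sel).mean(axis=0)
            n_epochs[cond] = len(sel)
    nb = config.n_baseline_samples
    n_tot = next(iter(means.values())).shape[1]
    times = (np.arange(n_tot) - nb) / config.sampling_rate * 1000.0

    onsets: dict[tuple[str, str], float | None] = {}
    for loc, (att, unatt) in _ATTENTION_PAIRS.items():
        if att not in means or unatt not in means:
            continue
        diff = means[att] - means[unatt]
        for ch in SOMATOSENSORY_CHANNELS:
            row = CHANNELS.index(ch)
            base_sd = float(diff[row, :nb].std())
            thr = criterion_factor * base_sd
            if thr == 0:
                exceed = np.abs(diff[row, nb:]) > 0
            else:
                exceed = np.abs(diff[row, nb:]) > thr
            onsets[(loc, ch)] = _first_run_ms(exceed, min_consecutive,
                                              config.sampling_rate)
    return GrandAverage(means=means, times_ms=times, n_epochs=n_epochs,
                        divergence_onset_ms=onsets)


def _first_run_ms(exceed: np.ndarray, min_run: int, fs: float) -> float | None:
    run = 0
    for i, flag in enumerate(exceed):
        run = run + 1 if flag else 0
        if run >= min_run:
            return (i - min_run + 1) / fs * 1000.0
    return None


def plot_grand_average(ga: GrandAverage, path: str | Path) -> None:
    """Two-row figure of attended vs unattended grand averages per channel."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, len(SOMATOSENSORY_CHANNELS),
                             figsize=(3 * len(SOMATOSENSORY_CHANNELS), 5),
                             sharex=True, sharey=True)
    for r, (loc, (att, unatt)) in enumerate(_ATTENTION_PAIRS.items()):
        color = "tab:blue" if loc == "D" else "tab:red"
        for c, ch in enumerate(SOMATOSENSORY_CHANNELS):
            ax = axes[r, c]
            row = CHANNELS.index(ch)
            ax.plot(ga.times_ms, ga.means[att][row], color=color,
                    label=f"attended (S{loc})")
            ax.plot(ga.times_ms, ga.means[unatt][row], color=color,
                    linestyle="--", label=f"unattended (S{loc})")
            ax.axvline(0, color="k", linestyle=":", linewidth=0.8)
            if r == 0:
                ax.set_title(ch)
            if c == 0:
                ax.set_ylabel("µV")
                ax.legend(fontsize=7)
    axes[-1, 0].set_xlabel("time (ms)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
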