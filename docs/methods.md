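# Methods

`serpbci` implements, end to end, the signal path of a two-class
electrotactile selective-attention BCI driven by somatosensory
event-related potentials (sERPs), together with a synthetic-EEG generator
that makes every stage testable without recordings.

## The paradigm being modeled

Two stimulation sites on the paretic forearm — dorsal (D, over the radial
nerve / extensor carpi radialis) and volar (V, over the median nerve /
flexor carpi radialis) — receive single electrical pulses in randomized
order with a 700 ms inter-stimulus interval while the subject covertly
counts the pulses at one *target* site and ignores the other.  Selective
spatial attention enhances the late components (after roughly 150 ms) of
the stimulus-locked EEG response; the classifier's job is to decide, from
one task period, which site was attended.

Six channels are recorded at 1200 Hz: five somatosensory sites
(generalized labels Ci, CPi, Pi, Cz, Cc, where the `i` channels lie over
the ipsilesional hemisphere and Cc is contralesional) plus Fp1 for ocular
artifacts.  A *training phase* of 30 blocks (15 per attention task, 30
stimuli per block, 15 per site) feeds classifier training; a *test phase*
of 20 online trials (10 per target) measures performance.

## Processing pipeline

1. **Filtering.** Causal (forward-only) Butterworth band-pass 0.1–25 Hz,
   4th-order prototype (8 poles), applied identically to training and
   online data.  Causality is non-negotiable: the online loop cannot see
   the future, and using one filter mode everywhere keeps the two phases'
   feature distributions identical.  The filter runs as second-order
   sections; at 0.1 Hz/1200 Hz a transfer-function form would be
   numerically fragile.  The first 5 s of each recording are excluded from
   epoching to let the filter state settle.
2. **Epoching.** Half-open windows `[onset − 100 ms, onset + 600 ms)`
   (840 samples), baseline-corrected by the mean of the 120 pre-stimulus
   samples.
3. **Artifact rejection.** An epoch survives iff all samples on the five
   somatosensory channels lie within ±50 µV and all Fp1 samples within
   ±80 µV, applied to baseline-corrected amplitudes (drift detection after
   DC removal).  Rejection is monotone in the thresholds.
4. **Condition clusters.** Accepted epochs are split by attended ×
   stimulated location into ADSD, ADSV, AVSD, AVSV and balanced by
   dropping the chronologically last epochs of larger clusters.  At
   protocol defaults each cluster holds 225 epochs before rejection
   (15 blocks/task × 15 stimuli/location).
5. **Sub-averaging and decimation.** Each cluster is partitioned
   chronologically into consecutive, non-overlapping groups of 10 epochs
   (remainder discarded; ~21–22 groups at defaults).  Group means keep
   only the 720 post-stimulus samples, decimated by stride 8 to 90 values.
   No extra anti-alias filter is applied: the 25 Hz low-pass already
   band-limits far below the 75 Hz post-decimation Nyquist.
6. **Index screening.** Per channel and per time index `t ∈ {0..89}`, a
   two-sided Wilcoxon rank-sum test compares attended vs unattended
   sub-averages of the same stimulated site (ADSD vs AVSD → iD, AVSV vs
   ADSV → iV); indices with p < 0.05 are retained.  No multiple-testing
   correction is applied — deliberately, to mirror the screening design.
   If a site yields no significant index, the single minimum-p index is
   kept and the channel flagged, so the classifier always has features.
7. **Feature vectors.** Sub-averages are paired by group index k:
   `AD_k = [ADSD_k(iD), ADSV_k(iV)]`, `AV_k = [AVSD_k(iD), AVSV_k(iV)]`.
   Pairing by shared group index preserves independence across vectors
   for the leave-one-out estimate.  No standardization: all features
   share µV units.
8. **Classification.** One RBF-kernel SVM per somatosensory channel,
   C = 1, kernel scale = median pairwise Euclidean distance of the
   training vectors (γ = 1/scale²) — the standard parameter-free
   heuristic, computed once on the full set.  Leave-one-out
   cross-validation over all vectors estimates each channel's accuracy;
   the argmax channel (ties broken Ci > CPi > Pi > Cz > Cc, ipsilesional
   priority) becomes the subject's feedback source.
9. **Online loop.** Per trial, stimuli are consumed in scheduled order
   until 10 artifact-free epochs exist per site.  The schedule holds a
   balanced, shuffled core of 20 stimuli plus an alternating reserve of
   10; reserve stimuli are delivered only for a site still lacking clean
   epochs, so an artifact-free trial uses exactly 20 stimuli and each
   rejection costs exactly one extra.  If the 30-stimulus budget runs out
   first the trial aborts (`budget_exhausted`) and is excluded from
   tallies.  The two 10-epoch averages are decimated, indexed with the
   *training-phase* iD/iV, classified per channel, and the feedback
   channel's decision is reported.
10. **Evaluation.** Per-channel accuracy
    `Acc = 100·(TP_AD + TP_AV)/(TP_AD + TP_AV + FP_AD + FP_AV)`;
    Wolpaw information transfer rate
    `B = log₂N + P·log₂P + (1−P)·log₂((1−P)/(N−1))`, ITR = 60·B/T with
    T the mean decision time (stimuli delivered × 700 ms; 14 s for an
    artifact-free trial, giving 4.29 bits/min at P = 1, N = 2).

## Protocol timing constants

Two per-stimulus constants coexist on purpose: onset-to-onset spacing uses
the 700 ms inter-stimulus interval, while scheduled block/trial *durations*
use a 750 ms per-stimulus slot (30 stimuli → the fixed 22.5 s block; a
20-stimulus trial → 15 s).  Which constant governed true onset spacing in
the original acquisition system is not determinable from the protocol
description, so both are config fields and each is used where its printed
consequence lives.

## Synthetic data generator

The generator emulates exactly the statistical structure the pipeline
exploits, nothing more:

- **Templates.** Per site, a smooth sum of Gaussian-windowed components
  (negative deflection near 100 ms, positive peak near 210–230 ms, broad
  late positivity near 330–360 ms; peaks of a few µV).  Channel loading is
  largest over Ci/CPi/Pi, attenuated on Cz/Cc, zero on Fp1; an
  ipsilesional-only loading is provided for laterality experiments.
- **Attention effect.** Multiplicative gain (default 2.0) on the late
  window (150–600 ms) with a 20 ms raised-cosine taper at the edge, applied
  iff the stimulated site is the attended one.  The clinical data do not
  quantify the attended-vs-unattended amplitude ratio, so the gain is a
  free simulator parameter, not a claim about patients.  Responses of
  consecutive stimuli sum linearly.
- **Background.** Order-2 autoregressive noise (poles at 0.9 and 0.8,
  low-pass character so filtering has a realistic effect), default std
  5 µV before filtering.
- **Artifacts.** Blinks: Gaussian bumps on Fp1, 150 µV peak, ~2/min.
  Drifts: 600 ms raised-cosine excursions of 100 µV on a random
  somatosensory channel, ~1/min.  Both exceed their rejection thresholds
  by construction.  Ground truth flags an epoch when the *artifact
  component alone*, filtered and baseline-corrected like the real
  pipeline, violates the thresholds with a margin of six background
  standard deviations plus the maximum template amplitude — so flagged
  epochs are rejectable regardless of the noise realization.

What the generator does **not** model: volume conduction and channel-wise
noise correlation, habituation and fatigue across the session, latency
jitter of sERP components, alpha rhythm and line noise, non-stationary
artifact morphology.  Passing tests therefore demonstrate that the
*pipeline* is correct and well calibrated, not that any particular
accuracy is attainable in patients.

## Calibration and bias findings (computed by the test suite)

- **Screening calibration.** With the attention gain at 1 (exchangeable
  conditions) the mean fraction of significant indices per channel over
  200 screenings is ≈ 0.05 (the acceptance run prints ≈ 0.047–0.053),
  i.e. the per-index test holds its nominal level at the sub-average
  group sizes (21–22), where the normal approximation with tie and
  continuity corrections is used; group sizes ≤ 8 use exact enumeration.
- **LOOCV optimism after screening.** Because index screening and LOOCV
  use the same training sub-averages, null-data LOOCV estimates are
  optimistically biased (≈ 0.6–0.7) — selection leakage inherent to this
  design.  Online test accuracy is computed on unseen trials and stays at
  chance under the null (the correct-trial count over 20 trials falls in
  the exact central 95% band of Binomial(20, ½)).  Feedback-channel
  *selection* still works because the bias is shared across channels.
- **LOOCV pessimism under permutation.** At the `train_channel` level,
  permuting labels yields mean LOOCV ≈ 0.44 rather than 0.50: holding out
  one vector tilts the balanced training set toward the opposite class —
  the standard leave-one-out anti-bias.
- **Recovery.** With gain ≥ 2 and background std ≤ 2 µV the simulated
  online session reaches 100% feedback accuracy in ≥ 90% of seeded runs;
  with ipsilesional-only template loading the selected feedback channel is
  ipsilesional in ≥ 95% of runs and Cc scores lowest — the simulated
  analogue of the clinical subset finding.

## Numerical and procedural choices

- **Quartiles.** Cohort summaries use median = mean of the two middle
  order statistics and Q1/Q3 = nearest rank (inverted CDF); this is the
  convention that reproduces the published cohort summary row exactly,
  verified cell by cell against the shipped fixture.
- **Signed-rank test.** Exact null distribution by dynamic programming
  over doubled midranks for n ≤ 25 (zero differences dropped), normal
  approximation beyond; two-sided p = 2·P(W ≤ min(W⁺, W⁻)), capped at 1.
- **Divergence onset.** The attended-minus-unattended grand-average
  difference is compared against 3× its own baseline-period std; the
  onset is the first time the criterion holds for a minimum run of
  consecutive samples (default 5).  At 1200 Hz a 5-sample run is shorter
  than the correlation time of 25 Hz band-limited noise, so the
  cohort-scale measurement in the acceptance script uses a 25 ms
  (30-sample) run and pools epochs over five sessions, emulating an
  all-patient grand average; it lands at ≈ 170 ms (late-window edge
  150 ms + taper + threshold-crossing lag).  A causal-filter subtlety:
  IIR response tails leak across the 700 ms stimulus spacing, so even
  gain-1 data show a tiny sequence-dependent inter-condition difference
  after filtering; exact zero-difference holds only pre-filter.
- **Model persistence.** The archive stores training vectors, labels,
  kernel parameters and index sets as JSON; loading refits the SVM, which
  is deterministic, so reloaded models reproduce predictions exactly.
- **Problem sizes.** Statistical properties in the tests use 20 seeded
  sessions (recovery, null calibration at 200 screenings) and 100 seeded
  training runs (laterality); these sizes put the Monte-Carlo error well
  below the asserted margins while keeping the suite convenient to run.

## Known limitations

- Continuous recordings are exchanged as MNE FIF; EDF(+) is supported for
  *reading* real recordings, and event tables always travel as sidecar
  TSV with integer sample indices.
- The online loop is a faithful simulation of the decision procedure, not
  a real-time implementation: no latency guarantees, no amplifier I/O.
- The clinical-score correlation analyses of the feasibility study are
  out of scope; the cohort fixture carries only the accuracy columns.
- The 700 ms epoch spacing makes consecutive epochs exactly contiguous:
  template responses do not overlap, but filtered response tails do (see
  above), as they would in any causal acquisition chain.
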