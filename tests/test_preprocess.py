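import numpy as np
import pytest

from serpbci.preprocess import (
    Epoch,
    bandpass_filter,
    cluster_and_balance,
    preprocess_session,
    reject_artifacts,
    segment_epochs,
)
from serpbci.protocol import CHANNELS, EventTable, StimulusEvent
from serpbci.synthdata import NoiseModel, generate_session

from conftest import replace


def _rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


def _sine(freq, fs, seconds, amp=10.0):
    t = np.arange(int(seconds * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)[None, :]


class TestBandpassFilter:
    def test_50_hz_attenuated_by_20_db(self, config):
        fs = config.sampling_rate
        x = _sine(50.0, fs, 10.0)
        y = bandpass_filter(x, config)
        steady = slice(int(2 * fs), None)
        assert _rms(y[:, steady]) < _rms(x[:, steady]) / 10.0  # > 20 dB

    def test_dc_offset_removed(self, config):
        fs = config.sampling_rate
        x = np.full((1, int(60 * fs)), 100.0)
        y = bandpass_filter(x, config)
        assert abs(y[:, -int(5 * fs):].mean()) < 1.0

    def test_10_hz_in_passband(self, config):
        fs = config.sampling_rate
        x = _sine(10.0, fs, 10.0)
        y = bandpass_filter(x, config)
        steady = slice(int(2 * fs), None)
        ratio = _rms(y[:, steady]) / _rms(x[:, steady])
        assert ratio > 10 ** (-3 / 20)  # within 3 dB

    def test_nonfinite_rejected(self, config):
        x = np.zeros((1, 100))
        x[0, 10] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            bandpass_filter(x, config)

    def test_causality(self, config):
        """The filter output before an impulse is exactly zero."""
        x = np.zeros((1, 2400))
        x[0, 1200] = 1.0
        y = bandpass_filter(x, config)
        assert np.all(y[0, :1200] == 0.0)


def _events(onsets, loc="D", att="D", phase="training", unit=0):
    return EventTable(events=[
        StimulusEvent(o, loc, att, phase, unit, i)
        for i, o in enumerate(onsets)
    ])


class TestSegmentEpochs:
    def test_constant_channel_zero_after_baseline(self, config):
        sig = np.full((6, 20000), 7.0)
        eps = segment_epochs(sig, _events([8000]), config)
        assert eps[0].accepted
        np.testing.assert_allclose(eps[0].data, 0.0, atol=1e-12)

    def test_epoch_has_840_samples(self, config):
        sig = np.zeros((6, 20000))
        eps = segment_epochs(sig, _events([8000]), config)
        assert eps[0].data.shape == (6, 840)

    def test_event_near_edge_rejected(self, config):
        sig = np.zeros((6, 20000))
        eps = segment_epochs(sig, _events([50, 19990]), config)
        assert [e.reject_reason for e in eps] == ["edge", "edge"]

    def test_event_in_lead_in_rejected(self, config):
        sig = np.zeros((6, 20000))
        eps = segment_epochs(sig, _events([3000]), config)
        assert eps[0].reject_reason == "lead_in"

    def test_baseline_mean_is_zero(self, config, small_session, small_config):
        eps = preprocess_session(small_session.signal, small_session.events,
                                 small_config)
        nb = small_config.n_baseline_samples
        for e in eps[:20]:
            assert np.abs(e.data[:, :nb].mean(axis=1)).max() < 1e-9


def _epoch_with(config, ch_label, amp, stim="D", att="D", onset=10_000):
    data = np.zeros((6, config.n_epoch_samples))
    data[CHANNELS.index(ch_label), 400] = amp
    return Epoch(data=data, stimulated=stim, attended=att, phase="training",
                 unit_id=0, seq_index=0, onset_sample=onset)


class TestRejectArtifacts:
    def test_60_uv_on_pi_rejected(self, config):
        eps = reject_artifacts([_epoch_with(config, "Pi", 60.0)], config)
        assert not eps[0].accepted and eps[0].reject_reason == "eeg_amplitude"

    def test_70_uv_on_fp1_only_accepted(self, config):
        eps = reject_artifacts([_epoch_with(config, "Fp1", 70.0)], config)
        assert eps[0].accepted

    def test_90_uv_on_fp1_rejected(self, config):
        eps = reject_artifacts([_epoch_with(config, "Fp1", -90.0)], config)
        assert not eps[0].accepted and eps[0].reject_reason == "eog_amplitude"

    def test_matches_brute_force_rescan(self, config, default_session):
        """Threshold rejection agrees with an independent per-sample re-scan
        of every epoch."""
        eps = preprocess_session(default_session.signal,
                                 default_session.events, config)
        eeg = [CHANNELS.index(c) for c in CHANNELS[:5]]
        fp1 = CHANNELS.index("Fp1")
        for e in eps[:300]:
            if e.reject_reason in ("edge", "lead_in"):
                continue
            ok = True
            for row in eeg:
                for v in e.data[row]:
                    if v > 50.0 or v < -50.0:
                        ok = False
            for v in e.data[fp1]:
                if v > 80.0 or v < -80.0:
                    ok = False
            assert e.accepted == ok

    def test_rejection_monotone_in_threshold(self, config, small_session,
                                             small_config):
        base = preprocess_session(small_session.signal, small_session.events,
                                  small_config)
        loose_cfg = replace(small_config, eeg_reject_threshold=80.0,
                            eog_reject_threshold=120.0)
        loose = preprocess_session(small_session.signal, small_session.events,
                                   loose_cfg)
        for b, l in zip(base, loose):
            if b.accepted:
                assert l.accepted


class TestClusterAndBalance:
    def _mk(self, cond_counts, config):
        eps = []
        onset = 10_000
        for cond, n in cond_counts.items():
            att, stim = cond[1], cond[3]
            for _ in range(n):
                eps.append(Epoch(
                    data=np.zeros((6, config.n_epoch_samples)),
                    stimulated=stim, attended=att, phase="training",
                    unit_id=0, seq_index=0, onset_sample=onset))
                onset += 840
        return eps

    def test_trims_to_minimum_chronologically(self, config):
        eps = self._mk({"ADSD": 225, "ADSV": 220, "AVSD": 223, "AVSV": 218},
                       config)
        clusters = cluster_and_balance(eps)
        assert all(len(c) == 218 for c in clusters.values())
        for c in clusters.values():
            onsets = [e.onset_sample for e in c.epochs]
            survivors = set(onsets)
            dropped = [e for e in eps if e.condition == c.condition
                       and e.onset_sample not in survivors]
            if dropped:
                assert min(e.onset_sample for e in dropped) > max(onsets)

    def test_equal_sizes_unchanged(self, config):
        eps = self._mk({c: 20 for c in ("ADSD", "ADSV", "AVSD", "AVSV")},
                       config)
        clusters = cluster_and_balance(eps)
        assert all(len(c) == 20 for c in clusters.values())

    def test_empty_cluster_raises(self, config):
        eps = self._mk({"ADSD": 5, "ADSV": 5, "AVSD": 5, "AVSV": 0}, config)
        with pytest.raises(ValueError, match="insufficient data"):
            cluster_and_balance(eps)

    def test_default_session_clusters_225_before_balancing(self, config):
        """15 blocks per task x 15 stimuli per location = 225 epochs per
        condition when nothing is rejected."""
        noise = NoiseModel(background_std=0.5, blink_rate=0.0, drift_rate=0.0,
                           seed=2)
        sess = generate_session(config, noise=noise, phases=("training",))
        eps = preprocess_session(sess.signal, sess.events, config)
        counts = {}
        for e in eps:
            if e.accepted:
                counts[e.condition] = counts.get(e.condition, 0) + 1
        assert counts == {c: 225 for c in ("ADSD", "ADSV", "AVSD", "AVSV")}


class TestDeterminism:
    def test_pipeline_bit_identical_on_reapplication(self, small_session,
                                                     small_config):
        a = preprocess_session(small_session.signal, small_session.events,
                               small_config)
        b = preprocess_session(small_session.signal, small_session.events,
                               small_config)
        for ea, eb in zip(a, b):
            np.testing.assert_array_equal(ea.data, eb.data)
            assert ea.accepted == eb.accepted
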