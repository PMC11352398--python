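import numpy as np
import pytest
from scipy import stats

from serpbci.features import (
    ChannelIndexSet,
    SubAverage,
    build_feature_vectors,
    make_subaverages,
    rank_sum_test,
    screen_indices,
)
from serpbci.preprocess import CONDITIONS, Epoch, EpochCluster
from serpbci.protocol import CHANNELS

from conftest import replace


def _cluster(n_epochs, config, fill=None, cond="ADSD"):
    eps = []
    for i in range(n_epochs):
        data = (np.zeros((6, config.n_epoch_samples)) if fill is None
                else fill(i))
        eps.append(Epoch(data=data, stimulated=cond[3], attended=cond[1],
                         phase="training", unit_id=0, seq_index=i,
                         onset_sample=10_000 + 840 * i))
    return EpochCluster(condition=cond, epochs=eps)


class TestMakeSubaverages:
    def test_218_epochs_give_21_subaverages(self, config):
        cl = _cluster(218, config)
        subs = make_subaverages(cl, config)
        assert len(subs) == 21
        assert subs[0].data.shape == (6, 90)

    def test_identical_epochs_average_to_single_epoch(self, config):
        rng = np.random.default_rng(0)
        proto = rng.standard_normal((6, config.n_epoch_samples))
        cl = _cluster(10, config, fill=lambda i: proto.copy())
        subs = make_subaverages(cl, config)
        expected = proto[:, config.n_baseline_samples:][:, ::8]
        np.testing.assert_allclose(subs[0].data, expected)

    def test_ramp_decimation_strides(self, config):
        ramp = np.zeros((6, config.n_epoch_samples))
        ramp[:, config.n_baseline_samples:] = np.arange(720)
        cl = _cluster(10, config, fill=lambda i: ramp.copy())
        subs = make_subaverages(cl, config)
        np.testing.assert_array_equal(subs[0].data[0], np.arange(0, 720, 8))
        assert subs[0].data.shape[1] == 90

    def test_small_cluster_raises(self, config):
        with pytest.raises(ValueError, match="at least"):
            make_subaverages(_cluster(9, config), config)


class TestRankSumTest:
    def test_exact_separated_triples(self):
        assert rank_sum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_degenerate_identical_values(self):
        assert rank_sum_test([2, 2, 2], [2, 2, 2]) == 1.0

    def test_identical_multisets(self):
        assert rank_sum_test([1, 2, 3], [3, 1, 2]) == 1.0

    def test_too_small_group_raises(self):
        with pytest.raises(ValueError):
            rank_sum_test([1.0], [2.0, 3.0])

    def test_exact_matches_scipy_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            x = rng.standard_normal(int(rng.integers(2, 9)))
            y = rng.standard_normal(int(rng.integers(2, 9)))
            expected = stats.mannwhitneyu(x, y, alternative="two-sided",
                                          method="exact").pvalue
            assert rank_sum_test(x, y) == pytest.approx(expected, abs=1e-12)

    def test_type_i_error_near_alpha(self):
        """Monte-Carlo size of the large-sample branch at the sub-average
        group sizes used by the screening step."""
        rng = np.random.default_rng(7)
        reps = 10_000
        rej = sum(
            rank_sum_test(rng.standard_normal(21), rng.standard_normal(22))
            < 0.05
            for _ in range(reps)
        )
        assert abs(rej / reps - 0.05) < 0.01


def _null_subaverages(rng, n=8, n_t=90, shift=None):
    subs = {c: [] for c in CONDITIONS}
    for c in CONDITIONS:
        for k in range(n):
            data = rng.standard_normal((6, n_t))
            if shift and c in shift:
                idx, amount = shift[c]
                data[:, idx] += amount
            subs[c].append(SubAverage(condition=c, group_index=k, data=data))
    return subs


class TestScreenIndices:
    def test_shifted_indices_detected(self, config):
        """A large attended-condition shift at known indices puts exactly
        those indices into iD/iV."""
        rng = np.random.default_rng(1)
        shift = {"ADSD": ([5, 40], 50.0), "AVSV": ([60], 50.0)}
        subs = _null_subaverages(rng, n=8, shift=shift)
        res = screen_indices(subs, "Ci", config)
        assert set(res.iD) >= {5, 40}
        assert 60 in set(res.iV)
        assert not res.fallback_d and not res.fallback_v

    def test_alpha_zero_triggers_fallback(self, config):
        rng = np.random.default_rng(2)
        subs = _null_subaverages(rng)
        cfg = replace(config, alpha=0.0)
        res = screen_indices(subs, "Cz", cfg)
        assert res.fallback_d and res.fallback_v
        assert len(res.iD) == 1 and len(res.iV) == 1
        assert res.iD[0] == np.argmin(res.p_d)

    def test_needs_two_subaverages(self, config):
        rng = np.random.default_rng(3)
        subs = _null_subaverages(rng, n=1)
        with pytest.raises(ValueError, match="at least 2"):
            screen_indices(subs, "Ci", config)


class TestBuildFeatureVectors:
    def _index_set(self, iD, iV, ch="Ci"):
        return ChannelIndexSet(channel=ch, iD=np.asarray(iD, int),
                               iV=np.asarray(iV, int),
                               p_d=np.zeros(90), p_v=np.zeros(90))

    def test_vector_length_is_sum_of_index_sets(self, config):
        rng = np.random.default_rng(4)
        subs = _null_subaverages(rng, n=5)
        vecs = build_feature_vectors(subs, self._index_set([1, 2, 3, 4],
                                                           [10, 11, 12, 13, 14, 15]),
                                     "Ci")
        assert all(len(v.values) == 10 for v in vecs)

    def test_counts_and_labels(self, config):
        rng = np.random.default_rng(5)
        subs = _null_subaverages(rng, n=21)
        vecs = build_feature_vectors(subs, self._index_set([0], [1]), "Ci")
        labels = [v.class_label for v in vecs]
        assert labels.count("AD") == 21 and labels.count("AV") == 21

    def test_layout_is_stimD_then_stimV(self, config):
        rng = np.random.default_rng(6)
        subs = _null_subaverages(rng, n=3)
        iD, iV = [2, 7], [1]
        vecs = build_feature_vectors(subs, self._index_set(iD, iV), "CPi")
        row = CHANNELS.index("CPi")
        ad0 = next(v for v in vecs if v.class_label == "AD"
                   and v.group_index == 0)
        expected = np.concatenate([subs["ADSD"][0].data[row][iD],
                                   subs["ADSV"][0].data[row][iV]])
        np.testing.assert_array_equal(ad0.values, expected)
        av0 = next(v for v in vecs if v.class_label == "AV"
                   and v.group_index == 0)
        expected_av = np.concatenate([subs["AVSD"][0].data[row][iD],
                                      subs["AVSV"][0].data[row][iV]])
        np.testing.assert_array_equal(av0.values, expected_av)

    def test_empty_iD_gives_stimV_only_vectors(self, config):
        rng = np.random.default_rng(8)
        subs = _null_subaverages(rng, n=3)
        vecs = build_feature_vectors(subs, self._index_set([], [4, 5]), "Pi")
        assert all(len(v.values) == 2 for v in vecs)

    def test_mismatched_counts_raise(self, config):
        rng = np.random.default_rng(9)
        subs = _null_subaverages(rng, n=4)
        subs["AVSV"] = subs["AVSV"][:-1]
        with pytest.raises(ValueError, match="mismatched"):
            build_feature_vectors(subs, self._index_set([0], [0]), "Ci")
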