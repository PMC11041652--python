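"""Spike features, foot-shock classification, and embedding."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import lhbpipe as lp
from lhbpipe.core import ExclusionError, InsufficientDataError


def rec_from_isis(isis_s, neuron_id="n0"):
    times = np.cumsum(np.concatenate([[1.0], isis_s]))
    return lp.SpikeTrainRecording(
        neuron_id=neuron_id,
        spike_times_s=times,
        duration_s=float(times[-1] + 1.0),
    )


class TestSpikeFeatures:
    def test_burst_index_counts_short_isis(self):
        feats = lp.spike_train_features(
            rec_from_isis([0.010, 0.030, 0.020, 0.050])
        )
        assert feats.burst_index == 0.5  # 2 of 4 ISIs below 25 ms

    def test_regular_train(self):
        times = np.arange(300) * 0.2 + 0.1  # 5 Hz for 60 s
        rec = lp.SpikeTrainRecording("r", times, duration_s=60.0)
        feats = lp.spike_train_features(rec)
        assert feats.cv == pytest.approx(0.0, abs=1e-9)
        assert feats.firing_rate_hz == pytest.approx(5.0)
        assert feats.isi_hist.sum() == pytest.approx(1.0)
        # all mass in the 200-ms bin (float rounding may split it across
        # the shared bin edge)
        assert feats.isi_hist[19:21].sum() == pytest.approx(1.0)

    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        isis = rng.exponential(0.2, size=200)
        a = lp.spike_train_features(rec_from_isis(isis))
        times = np.cumsum(np.concatenate([[1.0], isis])) + 5.0
        shifted = lp.SpikeTrainRecording(
            "n0", times, duration_s=float(times[-1] + 1.0 + 5.0)
        )
        b = lp.spike_train_features(shifted)
        assert np.array_equal(a.isi_hist, b.isi_hist)
        assert np.array_equal(a.acg_500, b.acg_500)
        assert a.cv == pytest.approx(b.cv, rel=1e-9)
        assert a.burst_index == b.burst_index

    def test_fs_windows_excised_from_spontaneous_statistics(self):
        """A huge burst of spikes inside the post-shock second does not
        contaminate rate or ISI statistics."""
        quiet = np.arange(1, 30) * 1.0
        burst = 30.0 + np.arange(100) * 0.005
        rec = lp.SpikeTrainRecording(
            "n", np.sort(np.concatenate([quiet, burst])), duration_s=60.0,
            fs_event_times_s=np.array([30.0]),
        )
        feats = lp.spike_train_features(rec)
        assert feats.burst_index == 0.0
        assert feats.firing_rate_hz == pytest.approx(29 / 59, rel=0.01)

    def test_too_few_spikes(self):
        rec = lp.SpikeTrainRecording("n", np.array([1.0]), duration_s=10.0)
        with pytest.raises(InsufficientDataError):
            lp.spike_train_features(rec)


class TestModulationIndex:
    @pytest.mark.parametrize(
        "stim,base,expected", [(3, 1, 0.5), (2, 2, 0.0), (0, 4, -1.0),
                               (4, 0, 1.0), (0, 0, 0.0)]
    )
    def test_examples(self, stim, base, expected):
        assert lp.fs_modulation_index(stim, base) == expected

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            lp.fs_modulation_index(-1.0, 2.0)

    @given(
        st.floats(min_value=0.01, max_value=50.0),
        st.floats(min_value=0.01, max_value=50.0),
    )
    def test_antisymmetric_and_bounded(self, a, b):
        m = lp.fs_modulation_index(a, b)
        assert m == pytest.approx(-lp.fs_modulation_index(b, a))
        assert -1.0 <= m <= 1.0


class TestFSClassification:
    def test_planted_excited_neurons_recovered(self):
        p = lp.SpikeCohortParams(
            n_neurons=10, effect_ratio=3.0, baseline_rate_median_hz=5.0,
            baseline_rate_sigma=0.0, frac_excited=1.0, frac_inhibited=0.0,
            frac_nonmod=0.0, duration_s=30.0, seed=5,
        )
        recs, _ = lp.generate_spike_cohort(p)
        classes = [lp.classify_fs_response(r).klass for r in recs]
        assert classes.count(lp.Klass.EXCITED) >= 9

    def test_exclusion_below_trial_threshold(self):
        rec = lp.SpikeTrainRecording(
            "n", np.arange(0.5, 200, 0.2), duration_s=200.0,
            fs_event_times_s=np.arange(10.0, 110.0, 5.0),  # exactly 20
        )
        with pytest.raises(ExclusionError, match="20"):
            lp.classify_fs_response(rec)

    def test_silent_neuron_degenerate(self):
        rec = lp.SpikeTrainRecording(
            "n", np.empty(0), duration_s=300.0,
            fs_event_times_s=np.arange(10.0, 120.0, 5.0),
        )
        resp = lp.classify_fs_response(rec)
        assert resp.degenerate
        assert resp.modulation_index == 0.0
        assert resp.klass is lp.Klass.NON_RESPONSIVE
        assert resp.p_value == 1.0

    def test_klass_consistent_with_p_and_direction(self, small_spike_cohort):
        recs, _ = small_spike_cohort
        cfg = lp.AnalysisConfig()
        for rec in recs:
            r = lp.classify_fs_response(rec, cfg)
            if r.klass is lp.Klass.EXCITED:
                assert r.p_value <= cfg.alpha
                assert r.fr_stimulus_hz > r.fr_baseline_hz
            elif r.klass is lp.Klass.INHIBITED:
                assert r.p_value <= cfg.alpha
                assert r.fr_stimulus_hz < r.fr_baseline_hz


class TestRateModulationCorrelation:
    @staticmethod
    def _fake(rates, mods):
        feats = [
            lp.SpikeFeatureSet(str(i), r, 1.0, 0.1, np.zeros(100),
                               np.zeros(500), np.zeros(100))
            for i, r in enumerate(rates)
        ]
        resps = [
            lp.FSResponse(str(i), 1.0, 1.0, np.zeros((1, 2)), 0.5,
                          lp.Klass.NON_RESPONSIVE, m)
            for i, m in enumerate(mods)
        ]
        return resps, feats

    def test_perfect_anticorrelation(self):
        resps, feats = self._fake([1.0, 2.0, 3.0], [0.5, 0.0, -0.5])
        r, p = lp.rate_modulation_correlation(resps, feats)
        assert r == pytest.approx(-1.0)

    def test_constant_modulation_rejected(self):
        resps, feats = self._fake([1.0, 2.0, 3.0], [0.2, 0.2, 0.2])
        with pytest.raises(ValueError, match="zero variance"):
            lp.rate_modulation_correlation(resps, feats)


class TestEmbedding:
    def test_feature_vector_length_and_duplicates(self, small_spike_cohort):
        recs, _ = small_spike_cohort
        feats = [lp.spike_train_features(r) for r in recs[:12]]
        feats.append(feats[0])  # duplicate neuron
        emb = lp.build_embedding_input(feats, seed=0)
        assert emb.features_15.shape == (13, 15)
        assert len(emb.feature_names) == 15
        assert np.allclose(emb.features_15[0], emb.features_15[-1])

    def test_embedding_deterministic(self, small_spike_cohort):
        recs, _ = small_spike_cohort
        feats = [lp.spike_train_features(r) for r in recs[:15]]
        a, _ = lp.cohort_embedding(feats, seed=42)
        b, _ = lp.cohort_embedding(feats, seed=42)
        assert np.array_equal(a, b)

    def test_separated_clusters_stay_separated(self):
        """High-rate regular versus low-rate bursty neurons keep a positive
        silhouette in the 2-D embedding."""
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(1)
        feats = []
        for i in range(10):  # fast, regular
            isis = rng.normal(0.05, 0.002, size=400).clip(0.01)
            feats.append(lp.spike_train_features(rec_from_isis(isis)))
        for i in range(10):  # slow, bursty
            isis = np.concatenate([
                rng.exponential(0.8, size=100),
                rng.uniform(0.005, 0.02, size=100),
            ])
            rng.shuffle(isis)
            feats.append(lp.spike_train_features(rec_from_isis(isis)))
        coords, _ = lp.cohort_embedding(feats, seed=0)
        labels = [0] * 10 + [1] * 10
        assert silhouette_score(coords, labels) > 0

    def test_too_few_neurons(self):
        feats = [
            lp.SpikeFeatureSet("a", 1, 1, 0.1, np.zeros(100), np.zeros(500),
                               np.zeros(100))
        ] * 5
        with pytest.raises(InsufficientDataError):
            lp.cohort_embedding(feats)
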