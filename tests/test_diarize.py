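import numpy as np
import pytest

from pdvoice import diarize, synth
from pdvoice.audio import Waveform
from pdvoice.diarize import (
    Diarization,
    DiarizationConfig,
    cluster_speakers,
    embed_window,
    extract_speaker_audio,
    segment_stream,
    smooth_labels,
    timeline_agreement,
)


class TestSegmentStream:
    def test_window_count(self):
        w = Waveform(np.zeros(160000), 16000)
        wins = segment_stream(w, DiarizationConfig())
        assert len(wins) == 19  # 1 + floor((10-1)/0.5)

    def test_disjoint_when_hop_equals_window(self):
        w = Waveform(np.zeros(48000), 16000)
        cfg = DiarizationConfig(window_s=1.0, hop_s=1.0)
        wins = segment_stream(w, cfg)
        spans = [s for _, s in wins]
        assert spans == [(0.0, 1.0), (1.0, 2.0), (2.0, 3.0)]

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            segment_stream(Waveform(np.zeros(100), 16000), DiarizationConfig())


class TestEmbedWindow:
    def test_deterministic_and_26_dim(self, clean_voice):
        cfg = DiarizationConfig()
        e1 = embed_window(clean_voice, cfg)
        e2 = embed_window(clean_voice, cfg)
        assert e1.vector.shape == (26,)
        assert np.array_equal(e1.vector, e2.vector)

    def test_between_speaker_distance_exceeds_within(self):
        """Windows of two distinct voices are farther apart than repeats."""
        a = synth.hc_spec(f0_mean=100.0, hnr_db=None)
        b = synth.hc_spec(f0_mean=220.0, hnr_db=None,
                          formants=((600.0, 80.0), (1800.0, 120.0), (3000.0, 160.0)))
        cfg = DiarizationConfig()
        embs = {0: [], 1: []}
        for i in range(10):
            embs[0].append(embed_window(synth.synth_voice(a, 1.0, 16000, i), cfg).vector)
            embs[1].append(embed_window(synth.synth_voice(b, 1.0, 16000, 100 + i), cfg).vector)
        within = np.mean([np.linalg.norm(x - y)
                          for spk in (0, 1)
                          for x in embs[spk] for y in embs[spk]])
        between = np.mean([np.linalg.norm(x - y)
                           for x in embs[0] for y in embs[1]])
        assert between > within

    def test_unknown_embedder_rejected(self, clean_voice):
        with pytest.raises(KeyError):
            embed_window(clean_voice, DiarizationConfig(embedder="dnn-xvector"))

    def test_registered_embedder_used(self, clean_voice):
        diarize.register_embedder("constant", lambda w, cfg: np.ones(4))
        try:
            e = embed_window(clean_voice, DiarizationConfig(embedder="constant"))
            assert np.array_equal(e.vector, np.ones(4))
        finally:
            del diarize.EMBEDDERS["constant"]


class TestKMeans:
    def test_separated_clouds_recovered(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.1, (30, 4))
        b = rng.normal(5, 0.1, (25, 4))
        labels = cluster_speakers(np.vstack([a, b]), 2, seed=1)
        assert len(set(labels[:30])) == 1
        assert len(set(labels[30:])) == 1
        assert labels[0] != labels[-1]

    def test_k1_centroid_is_mean(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (20, 3))
        labels = cluster_speakers(X, 1, seed=0)
        assert np.all(labels == labels[0])

    def test_objective_monotone_nonincreasing(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (100, 5))
        _, history = cluster_speakers(X, 4, seed=3, return_history=True)
        assert all(b <= a + 1e-9 for a, b in zip(history, history[1:]))

    def test_fixed_point_is_lloyd_solution(self):
        """Converged labels: every point is nearest its own centroid."""
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (60, 3))
        labels = cluster_speakers(X, 3, seed=4)
        centroids = np.array([X[labels == j].mean(axis=0) for j in range(3)])
        d2 = ((X[:, None, :] - centroids[None]) ** 2).sum(axis=2)
        assert np.array_equal(np.argmin(d2, axis=1), labels)

    def test_k_exceeds_points_raises(self):
        with pytest.raises(ValueError):
            cluster_speakers(np.zeros((3, 2)), 4, seed=0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (50, 4))
        assert np.array_equal(cluster_speakers(X, 3, seed=9),
                              cluster_speakers(X, 3, seed=9))


class TestSmoothing:
    @pytest.mark.parametrize("seq,width,expected", [
        ([0, 0, 1, 0, 0], 3, [0, 0, 0, 0, 0]),
        ([1, 1, 1, 1], 5, [1, 1, 1, 1]),
        ([0, 1, 0, 1, 0], 1, [0, 1, 0, 1, 0]),
    ])
    def test_examples(self, seq, width, expected):
        assert smooth_labels(seq, width).tolist() == expected

    def test_tie_prefers_previous_label(self):
        # at i=1 the truncated window [0,1,1] votes 1; at i=0 window [0,1]
        # ties and keeps the original 0
        assert smooth_labels([0, 1, 1, 0], 3).tolist()[0] == 0

    def test_idempotent_on_binary_width3(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            seq = rng.integers(0, 2, 30)
            once = smooth_labels(seq, 3)
            assert np.array_equal(smooth_labels(once, 3), once)

    def test_even_width_rejected(self):
        with pytest.raises(ValueError):
            smooth_labels([0, 1], 2)


class TestDiarizePipeline:
    def test_recovers_synthetic_timeline(self, two_speaker_conversation):
        conv, tl = two_speaker_conversation
        d = diarize.diarize(conv, DiarizationConfig(n_speakers=2, seed=0))
        assert timeline_agreement(d, tl.segments) >= 0.95

    def test_single_speaker_single_segment(self, clean_voice):
        w = synth.synth_voice(synth.hc_spec(), 5.0, 16000, 2)
        d = diarize.diarize(w, DiarizationConfig(n_speakers=1, seed=0))
        assert len(d.segments) == 1
        assert d.segments[0][0] == 0.0
        assert d.segments[0][1] == pytest.approx(5.0)

    def test_deterministic(self, two_speaker_conversation):
        conv, _ = two_speaker_conversation
        cfg = DiarizationConfig(n_speakers=2, seed=7)
        assert diarize.diarize(conv, cfg) == diarize.diarize(conv, cfg)

    def test_noise_cluster_flagged_as_lowest_energy(self, two_speaker_conversation):
        conv, tl = two_speaker_conversation
        cfg = DiarizationConfig(n_speakers=2, include_noise_cluster=True, seed=0)
        d = diarize.diarize(conv, cfg)
        assert d.noise_cluster in d.cluster_ids()


class TestExtractSpeakerAudio:
    def test_whole_stream_single_cluster(self, clean_voice):
        d = Diarization(((0.0, clean_voice.duration, 0),))
        out = extract_speaker_audio(clean_voice, d, 0)
        assert np.array_equal(out.samples, clean_voice.samples)

    def test_sample_exact_slices(self, two_speaker_conversation):
        conv, _ = two_speaker_conversation
        d = Diarization(((0.0, 1.0, 0), (2.0, 3.0, 1), (3.0, 4.0, 0)))
        out = extract_speaker_audio(conv, d, 0)
        expected = np.concatenate([conv.samples[:16000],
                                   conv.samples[48000:64000]])
        assert np.array_equal(out.samples, expected)

    def test_unknown_cluster_raises(self, clean_voice):
        d = Diarization(((0.0, 1.0, 0),))
        with pytest.raises(KeyError):
            extract_speaker_audio(clean_voice, d, 5)

    def test_extracted_subject_purity(self, two_speaker_conversation):
        conv, tl = two_speaker_conversation
        d = diarize.diarize(conv, DiarizationConfig(n_speakers=2, seed=0))
        best = max(d.cluster_ids(),
                   key=lambda c: diarize.speaker_purity(conv, d, c, tl.segments, 0))
        assert diarize.speaker_purity(conv, d, best, tl.segments, 0) >= 0.9


class TestAgreementScorer:
    def test_label_permutation_invariance(self, two_speaker_conversation):
        _, tl = two_speaker_conversation
        d = Diarization(((0.0, 2.0, 0), (2.0, 4.5, 1), (4.5, 13.0, 0)))
        swapped = Diarization(((0.0, 2.0, 1), (2.0, 4.5, 0), (4.5, 13.0, 1)))
        assert timeline_agreement(d, tl.segments) == \
            timeline_agreement(swapped, tl.segments)

    def test_perfect_hypothesis_scores_one(self, two_speaker_conversation):
        _, tl = two_speaker_conversation
        d = Diarization(tl.segments)
        assert timeline_agreement(d, tl.segments) == pytest.approx(1.0, abs=1e-6)


def test_rttm_round_trip(tmp_path):
    d = Diarization(((0.0, 1.25, 0), (1.25, 3.5, 1), (3.5, 4.0, 0)))
    path = tmp_path / "d.rttm"
    diarize.write_rttm(path, d, "conv1")
    back = diarize.read_rttm(path)
    for (s1, e1, c1), (s2, e2, c2) in zip(d.segments, back.segments):
        assert s1 == pytest.approx(s2, abs=1e-3)
        assert e1 == pytest.approx(e2, abs=1e-3)
        assert c1 == c2
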