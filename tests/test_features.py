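import numpy as np
import pandas as pd
import pytest
from scipy.fft import dct

from pdvoice import audio, features
from pdvoice.audio import FrameMatrix, Waveform
from pdvoice.features import (
    CepstralConfig,
    build_gammatone_filterbank,
    build_mel_filterbank,
    erb_bandwidth,
    erb_rate,
    erb_rate_inverse,
    featurize_sample,
    gtcc,
    mel_inverse,
    mel_scale,
    mfcc,
    zscore_apply,
    zscore_fit,
)

from oracles import oracle_cepstra

SMALL_CFG = CepstralConfig(n_mel_filters=20, n_gammatone_filters=20, fmax=4000.0)


def small_frames(frames_array, rate=8000):
    return FrameMatrix(np.asarray(frames_array, float), 64, 32, "rectangular", rate)


class TestFrequencyScales:
    def test_mel_at_zero_and_1k(self):
        assert mel_scale(0.0) == 0.0
        assert mel_scale(1000.0) == pytest.approx(2595 * np.log10(1 + 1000 / 700))

    @pytest.mark.parametrize("variant", ["htk", "slaney"])
    def test_mel_round_trip(self, variant):
        rng = np.random.default_rng(0)
        f = rng.uniform(0, 8000, 100)
        back = mel_inverse(mel_scale(f, variant), variant)
        assert np.allclose(back, f, rtol=1e-9, atol=1e-9)

    def test_mel_monotone(self):
        f = np.linspace(0, 8000, 1000)
        assert np.all(np.diff(mel_scale(f)) > 0)

    def test_erb_values(self):
        assert erb_bandwidth(0.0) == pytest.approx(24.7)
        assert erb_bandwidth(1000.0) == pytest.approx(24.7 * 5.37)

    def test_erb_rate_round_trip(self):
        rng = np.random.default_rng(1)
        f = rng.uniform(0, 8000, 100)
        assert np.allclose(erb_rate_inverse(erb_rate(f)), f, rtol=1e-9, atol=1e-9)

    def test_negative_frequency_rejected(self):
        for fn in (mel_scale, erb_bandwidth, erb_rate):
            with pytest.raises(ValueError):
                fn(-1.0)


class TestMelFilterbank:
    def test_argmax_at_center(self):
        bank = build_mel_filterbank(CepstralConfig(), 512, 16000)
        freqs = features.fft_bin_freqs(512, 16000)
        bin_width = 16000 / 512
        for row, fc in zip(bank.weights, bank.center_freqs):
            assert abs(freqs[np.argmax(row)] - fc) <= bin_width

    def test_supports_tile_passband(self):
        cfg = CepstralConfig()
        bank = build_mel_filterbank(cfg, 512, 16000)
        freqs = features.fft_bin_freqs(512, 16000)
        inside = (freqs > cfg.fmin + 40) & (freqs < 8000 - 200)
        assert np.all(bank.weights[:, inside].sum(axis=0) > 0)

    def test_pure_tone_maximises_own_filter(self):
        cfg = CepstralConfig()
        bank = build_mel_filterbank(cfg, 512, 16000)
        k = 12
        fc = bank.center_freqs[k]
        t = np.arange(512) / 16000
        tone = np.sin(2 * np.pi * fc * t)
        power = np.abs(np.fft.rfft(tone)) ** 2
        response = bank.weights @ power
        assert np.argmax(response) == k

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            build_mel_filterbank(CepstralConfig(), 64, 16000)


class TestGammatoneFilterbank:
    def test_centers_increasing(self):
        bank = build_gammatone_filterbank(CepstralConfig(), 512, 16000)
        assert len(bank.center_freqs) == 40
        assert np.all(np.diff(bank.center_freqs) > 0)

    def test_peak_within_one_erb(self):
        bank = build_gammatone_filterbank(CepstralConfig(), 1024, 16000)
        freqs = features.fft_bin_freqs(1024, 16000)
        for row, fc in zip(bank.weights, bank.center_freqs):
            peak_f = freqs[np.argmax(row)]
            assert abs(peak_f - fc) <= erb_bandwidth(fc)

    def test_half_power_bandwidth(self):
        """3 dB width within 30 % of the 4th-order relation 0.887*ERB."""
        bank = build_gammatone_filterbank(CepstralConfig(), 4096, 16000)
        freqs = features.fft_bin_freqs(4096, 16000)
        for row, fc in zip(bank.weights[5:-5], bank.center_freqs[5:-5]):
            above = freqs[row >= 0.5 * row.max()]
            width = above.max() - above.min()
            assert abs(width - 0.887 * erb_bandwidth(fc)) < 0.3 * 0.887 * erb_bandwidth(fc)


class TestCepstra:
    def test_zero_frame(self):
        """Silence: constant log spectrum, c0 = sqrt(M) log(floor), rest 0."""
        cfg = SMALL_CFG
        out = mfcc(small_frames(np.zeros((1, 64))), cfg)
        assert out[0, 0] == pytest.approx(np.sqrt(20) * np.log(cfg.log_floor))
        assert np.allclose(out[0, 1:], 0.0, atol=1e-9)
        assert np.allclose(gtcc(small_frames(np.zeros((1, 64))), cfg)[0, 1:],
                           0.0, atol=1e-9)

    def test_dct_orthonormality(self):
        for m in (13, 20, 40):
            D = dct(np.eye(m), type=2, norm="ortho", axis=0)
            assert np.allclose(D.T @ D, np.eye(m), atol=1e-10)

    def test_log_mel_inversion(self):
        """Full DCT is invertible: reconstructing log energies to 1e-8."""
        rng = np.random.default_rng(0)
        frame = rng.uniform(-0.5, 0.5, 64)
        cfg = SMALL_CFG
        n_fft = 64
        bank = build_mel_filterbank(cfg, n_fft, 8000)
        power = np.abs(np.fft.rfft(frame, n_fft)) ** 2
        logE = np.log(np.maximum(power @ bank.weights.T, cfg.log_floor))
        full = dct(logE, type=2, norm="ortho")
        back = dct(full, type=3, norm="ortho")
        assert np.allclose(back, logE, atol=1e-8)

    @pytest.mark.parametrize("kind", ["mel", "gammatone"])
    def test_oracle_equivalence(self, kind):
        """FFT pipeline equals the naive-DFT matrix oracle, 50 frames."""
        rng = np.random.default_rng(7)
        cfg = SMALL_CFG
        frames = rng.uniform(-0.8, 0.8, (50, 64))
        fast = (mfcc if kind == "mel" else gtcc)(small_frames(frames), cfg)
        for i in range(50):
            slow = oracle_cepstra(frames[i], 8000, kind, 20, 13,
                                  cfg.fmin, 4000.0, cfg.log_floor)
            scale = np.max(np.abs(slow))
            assert np.max(np.abs(fast[i] - slow)) / scale < 1e-8

    def test_gtcc_differs_from_mfcc(self):
        rng = np.random.default_rng(2)
        frames = small_frames(rng.uniform(-0.5, 0.5, (1, 64)))
        assert not np.allclose(mfcc(frames, SMALL_CFG), gtcc(frames, SMALL_CFG))


class TestFeaturizeSample:
    def test_identical_frames_equal_single_frame(self):
        """A perfectly stationary sample: mean over frames = any frame."""
        rng = np.random.default_rng(4)
        period = rng.uniform(-0.5, 0.5, 160)
        x = np.tile(period, 120)  # 1.2 s at 16 kHz, 10 ms period = hop
        w = Waveform(x, 16000)
        cfg = CepstralConfig(preemphasis=0.0)  # avoid the y[0] boundary sample
        vec = featurize_sample(w, cfg)
        per_frame = mfcc(audio.frame_signal(w), cfg)
        assert np.allclose(per_frame, per_frame[0], atol=1e-12)
        assert np.allclose(vec.mfcc, per_frame[0], atol=1e-9)

    def test_amplitude_scaling_moves_only_c0(self):
        spec_w = Waveform(np.sin(2 * np.pi * 200 * np.arange(16000) / 16000) * 0.4,
                          16000)
        v1 = featurize_sample(spec_w)
        v2 = featurize_sample(Waveform(spec_w.samples * 2.0, 16000))
        assert abs(v2.mfcc[0] - v1.mfcc[0]) > 1e-3
        assert np.allclose(v1.mfcc[1:], v2.mfcc[1:], atol=1e-6)
        assert np.allclose(v1.gtcc[1:], v2.gtcc[1:], atol=1e-6)

    def test_deterministic(self, clean_voice):
        v1 = featurize_sample(clean_voice)
        v2 = featurize_sample(clean_voice)
        assert np.array_equal(v1.concat(), v2.concat())

    def test_too_short_sample_raises(self):
        with pytest.raises(ValueError):
            featurize_sample(Waveform(np.zeros(100), 16000))

    def test_csv_round_trip(self, tmp_path, clean_voice):
        vec = featurize_sample(clean_voice, label="HC", chunk_index=2)
        df = features.features_to_frame([vec])
        path = tmp_path / "f.csv"
        features.write_feature_csv(path, df)
        back = features.read_feature_csv(path)
        assert list(back.columns) == list(df.columns)
        assert np.allclose(back[features.FEATURE_COLUMNS].to_numpy(),
                           df[features.FEATURE_COLUMNS].to_numpy(), rtol=1e-9)


class TestZScore:
    def test_self_normalisation(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(3.0, 2.0, (50, 26)),
                          columns=features.FEATURE_COLUMNS)
        stats = zscore_fit(df)
        z = zscore_apply(df, stats)[features.FEATURE_COLUMNS]
        assert np.all(np.abs(z.mean(axis=0)) < 1e-9)
        assert np.allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-9)

    def test_hand_computed_column(self):
        df = pd.DataFrame({"mfcc_0": [0.0, 0.0, 10.0]})
        stats = zscore_fit(df, ["mfcc_0"])
        z = zscore_apply(df, stats)["mfcc_0"].to_numpy()
        # mean 10/3, sd sqrt(2*(10/3)^2 + (20/3)^2)/sqrt(2) = 5.7735
        assert np.allclose(z, [-0.57735027, -0.57735027, 1.15470054])

    def test_affine_transform_of_applied_rows(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.normal(0, 1, (30, 2)), columns=["mfcc_0", "mfcc_1"])
        stats = zscore_fit(df, ["mfcc_0", "mfcc_1"])
        shifted = df * 2.0 + 3.0
        z = zscore_apply(shifted, stats)[["mfcc_0", "mfcc_1"]].to_numpy()
        z0 = zscore_apply(df, stats)[["mfcc_0", "mfcc_1"]].to_numpy()
        expected = 2.0 * z0 + (3.0 + (2.0 - 1.0) * stats.mean) / stats.sd
        assert np.allclose(z, expected)

    def test_zero_variance_column_named(self):
        df = pd.DataFrame({"mfcc_0": [1.0, 1.0, 1.0], "mfcc_1": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError, match="mfcc_0"):
            zscore_fit(df, ["mfcc_0", "mfcc_1"])
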