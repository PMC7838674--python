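"""STFT encoding: window closed forms, DFT oracle, frame bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dms_eeg import (STFTConfig, SynthParams, Trial, WindowSpec,
                     bundle_from_trials, dft_oracle, encode_features, stft,
                     window_coefficients)
from dms_eeg.stft import band_bins, n_frames, rotation_factor


class TestWindows:
    def test_boxcar_is_all_ones(self):
        assert np.array_equal(window_coefficients(WindowSpec("boxcar", 4)),
                              np.ones(4))

    def test_hann_closed_form_n5(self):
        w = window_coefficients(WindowSpec("hann", 5))
        assert w == pytest.approx([0.0, 0.5, 1.0, 0.5, 0.0], abs=1e-12)

    def test_hamming_closed_form_n3(self):
        w = window_coefficients(WindowSpec("hamming", 3))
        assert w == pytest.approx([0.08, 1.0, 0.08], abs=1e-12)

    def test_bartlett_touches_zero_triang_does_not(self):
        for n in (5, 8, 33):
            bart = window_coefficients(WindowSpec("bartlett", n))
            tri = window_coefficients(WindowSpec("triang", n))
            assert bart[0] == bart[-1] == 0.0
            assert tri[0] > 0.0 and tri[-1] > 0.0

    @pytest.mark.parametrize("name", ["boxcar", "triang", "hamming", "hann",
                                      "bartlett"])
    def test_symmetry_and_range(self, name):
        for n in range(3, 66):
            w = window_coefficients(WindowSpec(name, n))
            assert np.allclose(w, w[::-1], atol=1e-13)
            assert w.min() >= 0.0 and w.max() <= 1.0 + 1e-12

    def test_unknown_window_rejected(self):
        with pytest.raises(ValueError):
            WindowSpec("kaiser", 8)
        with pytest.raises(ValueError):
            WindowSpec("hann", 0)


class TestDftOracle:
    def test_impulse_gives_flat_spectrum(self):
        assert np.allclose(dft_oracle([1, 0, 0, 0]), np.ones(4))

    def test_constant_gives_dc_only(self):
        assert np.allclose(dft_oracle([1, 1, 1, 1]), [4, 0, 0, 0])

    def test_quadrature_sequence(self):
        got = dft_oracle([0, 1, 0, -1])
        assert np.allclose(got, [0, -2j, 0, 2j], atol=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            dft_oracle([])

    def test_matches_numpy_fft(self, rng):
        x = rng.standard_normal(17)
        assert np.allclose(dft_oracle(x), np.fft.fft(x), atol=1e-10)


class TestRotationFactor:
    @pytest.mark.parametrize("N", [4, 8, 16, 64])
    def test_half_period_antisymmetry_and_periodicity(self, N):
        k = np.arange(N)
        assert np.abs(rotation_factor(N, k + N // 2)
                      + rotation_factor(N, k)).max() < 1e-12
        assert np.abs(rotation_factor(N, k + N)
                      - rotation_factor(N, k)).max() < 1e-12


class TestStft:
    CFG = STFTConfig(window=WindowSpec("hann", 64), hop=16, n_fft=64)

    def test_zero_signal_gives_zero_matrix(self):
        out = stft(np.zeros(384), self.CFG)
        assert out.shape == (64, 21)
        assert np.abs(out).max() == 0.0

    def test_frame_count_arithmetic(self):
        assert n_frames(384, 64, 16) == 21
        assert stft(np.zeros(384), self.CFG).shape[1] == 21

    def test_signal_shorter_than_window_rejected(self):
        with pytest.raises(ValueError):
            stft(np.zeros(32), self.CFG)

    def test_frames_match_dft_oracle(self, rng):
        cfg = STFTConfig(window=WindowSpec("hamming", 16), hop=5, n_fft=16)
        x = rng.standard_normal(60)
        w = window_coefficients(cfg.window)
        out = stft(x, cfg)
        for m in range(out.shape[1]):
            seg = x[m * 5 : m * 5 + 16] * w
            assert np.abs(out[:, m] - dft_oracle(seg)).max() < 1e-9

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.floats(-3, 3), st.floats(-3, 3))
    def test_linearity(self, seed, a, b):
        r = np.random.default_rng(seed)
        x, y = r.standard_normal((2, 100))
        cfg = STFTConfig(window=WindowSpec("hann", 32), hop=8, n_fft=32)
        lhs = stft(a * x + b * y, cfg)
        rhs = a * stft(x, cfg) + b * stft(y, cfg)
        assert np.abs(lhs - rhs).max() < 1e-9


class TestEncodeFeatures:
    def _bundle(self, n_channels=2, n_samples=384, fs=128.0, fill=None):
        data = (np.zeros((n_channels, n_samples)) if fill is None
                else fill)
        names = ("C3", "C4", "Cz")[:n_channels]
        tr = Trial(data=data, channel_names=names, fs=fs, label="left")
        return bundle_from_trials([tr])

    def test_channel_stacking_and_band_bins(self):
        feats = encode_features(self._bundle(), STFTConfig())
        assert feats[0].values.shape == (15, 21, 2)
        assert np.array_equal(feats[0].bin_freqs, np.arange(2, 31, 2))

    def test_band_excluding_all_bins_rejected(self):
        cfg = STFTConfig(band=(0.1, 0.2))
        with pytest.raises(ValueError):
            encode_features(self._bundle(), cfg)

    def test_pure_sinusoid_peaks_at_its_bin(self):
        fs, f0 = 128.0, 10.0
        t = np.arange(384) / fs
        sig = np.sin(2 * np.pi * f0 * t)
        bundle = self._bundle(n_channels=1, fill=sig[None, :])
        cfg = STFTConfig(normalize=False)
        feats = encode_features(bundle, cfg)
        values = feats[0].values[:, :, 0]
        peak_bins = feats[0].bin_freqs[np.argmax(values, axis=0)]
        assert np.all(peak_bins == f0)

    def test_normalization_zscores_each_trial(self, small_bundle):
        from dms_eeg import segment_trials, select_channels
        prepared = segment_trials(select_channels(small_bundle, ("C3", "C4")),
                                  3.0, 6.0)
        feats = encode_features(prepared, STFTConfig())
        for f in feats:
            assert f.values.mean() == pytest.approx(0.0, abs=1e-9)
            assert f.values.std() == pytest.approx(1.0, abs=1e-9)

    def test_feature_round_trip(self, small_bundle, tmp_path):
        from dms_eeg import segment_trials
        from dms_eeg.stft import load_features, save_features
        feats = encode_features(segment_trials(small_bundle, 3.0, 6.0),
                                STFTConfig())
        path = tmp_path / "feats.npz"
        save_features(feats, path)
        back = load_features(path)
        for a, b in zip(feats, back):
            assert a.label == b.label
            assert np.array_equal(a.values, b.values)


def test_band_bins_width():
    idx = band_bins(128.0, 64, (0.5, 30.0))
    assert np.array_equal(idx, np.arange(1, 16))


def test_stft_config_validation():
    with pytest.raises(ValueError):
        STFTConfig(window=WindowSpec("hann", 64), hop=0)
    with pytest.raises(ValueError):
        STFTConfig(window=WindowSpec("hann", 64), hop=16, n_fft=32)
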