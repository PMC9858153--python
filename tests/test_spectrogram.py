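"""STFT framing, thresholding and heat-map rendering."""

import numpy as np
import pytest

from bcgmixer.preprocessing import Segment
from bcgmixer.spectrogram import (
    SpectrogramConfig,
    TFMatrix,
    build_image_dataset,
    hanning_window,
    render_heatmap,
    spectrogram_pipeline,
    stft_magnitude,
    threshold_spectrogram,
)


class TestHanningWindow:
    def test_small_windows(self):
        assert np.allclose(hanning_window(3), [0, 1, 0])
        assert np.allclose(hanning_window(5), [0, 0.5, 1, 0.5, 0])

    def test_symmetry_128(self):
        w = hanning_window(128)
        assert np.allclose(w, w[::-1])
        assert w[0] == 0.0 and w[-1] == 0.0

    def test_matches_numpy_symmetric(self):
        assert np.allclose(hanning_window(64), np.hanning(64))

    def test_periodic_variant(self):
        w = hanning_window(8, periodic=True)
        assert np.allclose(w, np.hanning(9)[:8])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            hanning_window(1)


class TestSTFT:
    def test_default_shape_for_30s_segment(self, noise_segment):
        tf = stft_magnitude(noise_segment, SpectrogramConfig())
        assert tf.values.shape == (65, 360)  # nfft/2+1 x floor((3000-128)/8)+1
        assert tf.freq_resolution_hz == pytest.approx(100 / 128)
        assert tf.time_step_s == pytest.approx(8 / 100)

    @pytest.mark.parametrize("L,W,H", [(300, 64, 8), (301, 64, 8), (1000, 128, 120),
                                       (256, 256, 1), (999, 100, 37)])
    def test_frame_count_formula(self, rng, L, W, H):
        """Naive sliding-window oracle: count windows that fit entirely."""
        cfg = SpectrogramConfig(window_len=W, overlap=W - H, nfft=max(W, 128))
        tf = stft_magnitude(rng.normal(size=L), cfg, fs=100)
        count = 0
        start = 0
        while start + W <= L:
            count += 1
            start += H
        assert tf.n_frames == count == (L - W) // H + 1

    def test_tone_localization_all_clean_bins(self):
        """A tone at k*fs/nfft puts the per-frame argmax in row k."""
        cfg = SpectrogramConfig()
        t = np.arange(3000) / 100.0
        for k in range(2, 63):
            tone = np.sin(2 * np.pi * (k * 100 / 128) * t)
            tf = stft_magnitude(tone, cfg, fs=100)
            assert np.all(np.argmax(tf.values, axis=0) == k), f"bin {k}"

    def test_against_direct_dft_oracle(self, rng):
        """Windowed-DFT loop oracle on a short segment, linear power scale."""
        cfg = SpectrogramConfig(window_len=32, overlap=24, nfft=32, scale="linear")
        x = rng.normal(size=200)
        tf = stft_magnitude(x, cfg, fs=100)
        win = hanning_window(32)
        n = np.arange(32)
        for f in range(tf.n_frames):
            frame = x[f * 8 : f * 8 + 32] * win
            for k in range(17):
                dft = np.sum(frame * np.exp(-2j * np.pi * k * n / 32))
                assert tf.values[k, f] == pytest.approx(abs(dft) ** 2, rel=1e-9, abs=1e-12)

    def test_zero_segment(self):
        cfg_lin = SpectrogramConfig(scale="linear")
        assert np.all(stft_magnitude(np.zeros(500), cfg_lin, fs=100).values == 0.0)
        cfg_db = SpectrogramConfig()
        assert np.all(stft_magnitude(np.zeros(500), cfg_db, fs=100).values == -120.0)

    def test_parseval_energy_per_frame(self, rng):
        """Two-sided spectral power equals nfft x windowed frame energy."""
        cfg = SpectrogramConfig(scale="linear")
        x = rng.normal(size=1000)
        tf = stft_magnitude(x, cfg, fs=100)
        win = hanning_window(128)
        for f in (0, 5, tf.n_frames - 1):
            frame = x[f * 8 : f * 8 + 128] * win
            two_sided = tf.values[0, f] + tf.values[64, f] + 2 * tf.values[1:64, f].sum()
            assert two_sided == pytest.approx(128 * np.sum(frame**2), rel=1e-9)

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            stft_magnitude(np.zeros(100), SpectrogramConfig(), fs=100)


class TestThreshold:
    def _tf(self, values):
        return TFMatrix(values=np.asarray(values, float), fs=100, window_len=128,
                        hop=8, nfft=128, scale="db")

    def test_example(self):
        out = threshold_spectrogram(self._tf([[0, -50], [-10, -90]]), -40.0)
        assert np.array_equal(out.values, [[0, -40], [-10, -40]])

    def test_values_within_threshold_unchanged(self, rng):
        v = rng.uniform(-30, 0, size=(8, 8))
        out = threshold_spectrogram(self._tf(v), -40.0)
        assert np.array_equal(out.values, v)

    def test_idempotent_and_monotone(self, rng):
        v = rng.uniform(-80, 0, size=(16, 16))
        once = threshold_spectrogram(self._tf(v), -40.0)
        twice = threshold_spectrogram(once, -40.0)
        assert np.array_equal(once.values, twice.values)
        floor = v.max() - 40.0
        changed = once.values != v
        assert np.all(once.values[changed] == floor)
        assert np.all(once.values >= v)  # never lowers, only floors

    def test_boundaries(self):
        tf = self._tf([[0.0, -10.0]])
        with pytest.raises(ValueError):
            threshold_spectrogram(tf, -0.0)
        out = threshold_spectrogram(tf, -np.inf)
        assert np.array_equal(out.values, tf.values)

    def test_linear_scale_rejected(self):
        tf = TFMatrix(values=np.ones((2, 2)), fs=100, window_len=128, hop=8,
                      nfft=128, scale="linear")
        with pytest.raises(ValueError, match="dB"):
            threshold_spectrogram(tf, -40.0)


class TestRender:
    def _tf(self, values):
        return TFMatrix(values=np.asarray(values, float), fs=100, window_len=128,
                        hop=8, nfft=128, scale="db")

    def test_shape_and_range(self, rng):
        img = render_heatmap(self._tf(rng.uniform(-60, 0, (65, 360))), SpectrogramConfig())
        assert img.rgb.shape == (224, 224, 3)
        assert img.rgb.min() >= 0.0 and img.rgb.max() <= 1.0

    def test_constant_matrix_renders_uniform(self):
        img = render_heatmap(self._tf(np.full((65, 360), -17.0)), SpectrogramConfig())
        assert np.all(img.rgb == img.rgb[0, 0])

    def test_additive_db_offset_invariance(self, rng):
        v = rng.uniform(-60, 0, (65, 360))
        cfg = SpectrogramConfig()
        a = render_heatmap(self._tf(v), cfg)
        b = render_heatmap(self._tf(v + 17.3), cfg)
        assert np.array_equal(a.rgb, b.rgb)

    def test_low_frequencies_at_bottom(self):
        # energy only in the lowest-frequency row -> bright at image bottom
        v = np.full((65, 360), -80.0)
        v[0, :] = 0.0
        img = render_heatmap(self._tf(v), SpectrogramConfig())
        assert img.rgb[-5:].sum() > img.rgb[:5].sum()

    def test_nonfinite_rejected(self):
        v = np.zeros((4, 4))
        v[0, 0] = np.nan
        with pytest.raises(ValueError):
            render_heatmap(self._tf(v), SpectrogramConfig())


class TestPipeline:
    def test_deterministic_png_bytes(self, noise_segment, tmp_path):
        cfg = SpectrogramConfig()
        img = spectrogram_pipeline(noise_segment, cfg)
        img.to_png(tmp_path / "a.png")
        spectrogram_pipeline(noise_segment, cfg).to_png(tmp_path / "b.png")
        assert (tmp_path / "a.png").read_bytes() == (tmp_path / "b.png").read_bytes()

    def test_easy_classes_have_distinct_dominant_rows(self):
        """4 Hz vs 10 Hz beat wavelets concentrate energy in different rows."""
        cfg = SpectrogramConfig()
        t = np.arange(3000) / 100.0
        rows = {}
        for name, f0 in (("A", 4.0), ("B", 10.0)):
            beat = sum(
                np.cos(2 * np.pi * f0 * (t - tb)) * np.exp(-0.5 * ((t - tb) / 0.15) ** 2)
                for tb in np.arange(0.4, 29.6, 0.8)
            )
            tf = threshold_spectrogram(stft_magnitude(beat, cfg, fs=100), cfg.threshold_db)
            rows[name] = int(np.bincount(np.argmax(tf.values, axis=0)).argmax())
        assert rows["A"] != rows["B"]

    def test_image_dataset_manifest(self, tmp_path, rng):
        segs = [
            Segment(rng.normal(size=3000), subject_id=f"S{i}", segment_index=j,
                    label="HPT" if i else "NRT", fs=100)
            for i in range(2) for j in range(3)
        ]
        images, manifest = build_image_dataset(segs, SpectrogramConfig(), out_dir=tmp_path)
        assert images.shape == (6, 224, 224, 3) and images.dtype == np.uint8
        assert len(manifest) == 6
        assert list(manifest.columns) == ["image_path", "subject_id", "segment_index", "label"]
        for p in manifest["image_path"]:
            assert (tmp_path / p).exists()
        assert (tmp_path / "images_manifest.csv").exists()
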