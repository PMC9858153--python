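"""STFT spectrograms of 30-s BCG segments and their heat-map renderings.

Each segment is windowed (Hann, 128 samples), hopped by ``window_len -
overlap`` samples (overlap ratio 15/16, i.e. hop 8), transformed with a
128-point FFT, converted to dB power, floored at a configurable threshold
below the per-segment maximum, and rendered through a colormap to an RGB heat
map: first at 420x560 and then bilinearly resized to the classifier's
224x224x3 input.  The threshold is the single most consequential free
parameter of the imaging stage (the relative floor decides how much
low-energy texture survives into the image) and is fully configurable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from PIL import Image

from .preprocessing import Segment

__all__ = [
    "SpectrogramConfig",
    "TFMatrix",
    "SpectrogramImage",
    "hanning_window",
    "stft_magnitude",
    "threshold_spectrogram",
    "render_heatmap",
    "spectrogram_pipeline",
    "build_image_dataset",
]

_DB_FLOOR = -120.0  # dB assigned to exactly-zero power bins


@dataclass
class SpectrogramConfig:
    """Parameters of the segment -> image transform."""

    window_type: str = "hanning"
    window_len: int = 128  # samples
    overlap: int = 120  # samples; 120/128 = 15/16 overlap ratio
    nfft: int = 128
    scale: str = "db_power"  # or "linear" (power)
    threshold_db: float = -40.0  # relative floor below the per-segment max
    colormap: str = "viridis"  # perceptually ordered default
    render_size: tuple[int, int] = (420, 560)  # (height, width)
    final_size: tuple[int, int] = (224, 224)
    periodic_window: bool = False  # symmetric Hann by default

    def __post_init__(self) -> None:
        if self.window_type != "hanning":
            raise ValueError("only the Hanning window is supported")
        if not (0 <= self.overlap < self.window_len):
            raise ValueError("overlap must satisfy 0 <= overlap < window_len")
        if self.nfft < self.window_len:
            raise ValueError("nfft must be at least window_len")
        if self.scale not in ("db_power", "linear"):
            raise ValueError("scale must be 'db_power' or 'linear'")
        if min(self.render_size) <= 0 or min(self.final_size) <= 0:
            raise ValueError("image sizes must be positive")

    @property
    def hop(self) -> int:
        return self.window_len - self.overlap

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class TFMatrix:
    """One-sided time-frequency matrix: ``nfft/2 + 1`` rows x n_frames columns.

    Row k is frequency ``k * fs / nfft`` Hz; column f covers samples
    ``[f*hop, f*hop + window_len)``.  ``scale`` records whether values are
    linear power or dB power.
    """

    values: np.ndarray
    fs: float
    window_len: int
    hop: int
    nfft: int
    scale: str  # "linear" | "db"

    @property
    def freq_resolution_hz(self) -> float:
        return self.fs / self.nfft

    @property
    def time_step_s(self) -> float:
        return self.hop / self.fs

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class SpectrogramImage:
    """Rendered RGB heat map plus provenance."""

    rgb: np.ndarray  # (H, W, 3) float in [0, 1]
    subject_id: str = ""
    segment_index: int = 0
    label: Optional[str] = None
    config_hash: str = ""

    def to_png(self, path: str | Path) -> None:
        arr = np.clip(np.round(self.rgb * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(arr).save(path, format="PNG")


def hanning_window(n: int, periodic: bool = False) -> np.ndarray:
    """Hann (raised-cosine) weights of length n.

    Symmetric by default: ``0.5 * (1 - cos(2*pi*k/(n-1)))`` with zero
    endpoints.  The periodic variant divides by n instead, as used for
    spectral averaging.
    """
    if n < 2:
        raise ValueError("window length must be at least 2")
    k = np.arange(n)
    denom = n if periodic else n - 1
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * k / denom))


def _frames(x: np.ndarray, window_len: int, hop: int) -> np.ndarray:
    """(n_frames, window_len) view; n_frames = floor((L - W)/H) + 1."""
    return np.lib.stride_tricks.sliding_window_view(x, window_len)[::hop]


def stft_magnitude(
    seg: Union[Segment, np.ndarray], cfg: SpectrogramConfig, fs: Optional[float] = None
) -> TFMatrix:
    """One-sided power spectrogram of a segment.

    Frame f covers samples ``[f*hop, f*hop + window_len)``; the number of
    frames is ``floor((L - window_len)/hop) + 1`` (no padding).  Values are
    linear power, converted to dB (``10*log10``, floor -120 dB for zeros)
    when ``cfg.scale == 'db_power'``.
    """
    if isinstance(seg, Segment):
        x, fs = seg.samples, seg.fs
    else:
        x = np.asarray(seg, dtype=float)
        if fs is None:
            fs = 100.0
    if x.size < cfg.window_len:
        raise ValueError(
            f"segment of {x.size} samples is shorter than the {cfg.window_len}-sample window"
        )
    win = hanning_window(cfg.window_len, periodic=cfg.periodic_window)
    frames = _frames(x, cfg.window_len, cfg.hop) * win
    spec = np.fft.rfft(frames, n=cfg.nfft, axis=1)
    power = np.abs(spec) ** 2
    if cfg.scale == "db_power":
        values = 10.0 * np.log10(np.maximum(power, 10.0 ** (_DB_FLOOR / 10.0)))
        scale = "db"
    else:
        values = power
        scale = "linear"
    return TFMatrix(
        values=values.T,  # frequency rows x time columns
        fs=float(fs),
        window_len=cfg.window_len,
        hop=cfg.hop,
        nfft=cfg.nfft,
        scale=scale,
    )


def threshold_spectrogram(tf: TFMatrix, threshold_db: float) -> TFMatrix:
    """Clamp every value below ``max + threshold_db`` to that floor.

    Low-amplitude time-frequency points carry little reliable spectral
    information; flooring them simplifies the image the classifier sees.
    Idempotent, and monotone in the sense that values at or above the floor
    pass through unchanged.
    """
    if tf.scale != "db":
        raise ValueError("thresholding operates on dB-scaled spectrograms")
    if not threshold_db < 0:
        raise ValueError("threshold_db must be negative (a floor below the maximum)")
    floor = float(np.max(tf.values)) + threshold_db
    return replace(tf, values=np.maximum(tf.values, floor))


def _colormap_lut(name: str) -> np.ndarray:
    import matplotlib

    cmap = matplotlib.colormaps[name]
    return (cmap(np.linspace(0.0, 1.0, 256))[:, :3] * 255.0).round().astype(np.uint8)


def render_heatmap(
    tf: TFMatrix,
    cfg: SpectrogramConfig,
    subject_id: str = "",
    segment_index: int = 0,
    label: Optional[str] = None,
) -> SpectrogramImage:
    """Min-max normalize, colormap, and bilinearly resize to the final size.

    Low frequencies end up at the bottom of the image and time runs left to
    right; no axes or margins are drawn.  A constant matrix renders as a
    uniform image.  Because of the min-max normalization the rendering is
    invariant to additive dB offsets.
    """
    v = np.asarray(tf.values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("time-frequency matrix contains non-finite values")
    vmin, vmax = float(v.min()), float(v.max())
    norm = np.zeros_like(v) if vmax == vmin else (v - vmin) / (vmax - vmin)
    norm = norm[::-1]  # low frequencies at the bottom row
    lut = _colormap_lut(cfg.colormap)
    idx = np.clip(np.round(norm * 255.0), 0, 255).astype(np.uint8)
    rgb8 = lut[idx]
    h0, w0 = cfg.render_size
    h1, w1 = cfg.final_size
    img = Image.fromarray(rgb8)
    img = img.resize((w0, h0), Image.BILINEAR)
    img = img.resize((w1, h1), Image.BILINEAR)
    return SpectrogramImage(
        rgb=np.asarray(img, dtype=float) / 255.0,
        subject_id=subject_id,
        segment_index=segment_index,
        label=label,
        config_hash=cfg.config_hash(),
    )


def spectrogram_pipeline(seg: Segment, cfg: SpectrogramConfig) -> SpectrogramImage:
    """Full segment -> image chain: STFT -> dB -> threshold -> render."""
    if cfg.scale != "db_power":
        raise ValueError("the canonical image pipeline uses the dB power scale")
    tf = stft_magnitude(seg, cfg)
    tf = threshold_spectrogram(tf, cfg.threshold_db)
    return render_heatmap(
        tf,
        cfg,
        subject_id=seg.subject_id,
        segment_index=seg.segment_index,
        label=seg.label.value if seg.label is not None else None,
    )


def build_image_dataset(
    segments: list[Segment],
    cfg: SpectrogramConfig,
    out_dir: Optional[str | Path] = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render every segment; return stacked uint8 images plus a manifest.

    The manifest has columns ``image_path, subject_id, segment_index, label``
    (``image_path`` empty when images are kept in memory only).  Images are
    returned as a (N, H, W, 3) uint8 array to keep large datasets compact.
    """
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    h, w = cfg.final_size
    images = np.empty((len(segments), h, w, 3), dtype=np.uint8)
    rows = []
    for i, seg in enumerate(segments):
        im = spectrogram_pipeline(seg, cfg)
        images[i] = np.clip(np.round(im.rgb * 255.0), 0, 255).astype(np.uint8)
        rel = f"{seg.subject_id}_seg{seg.segment_index:04d}.png"
        if out_path is not None:
            im.to_png(out_path / rel)
        rows.append(
            {
                "image_path": rel if out_path is not None else "",
                "subject_id": seg.subject_id,
                "segment_index": seg.segment_index,
                "label": seg.label.value if seg.label is not None else "",
            }
        )
    manifest = pd.DataFrame(rows, columns=["image_path", "subject_id", "segment_index", "label"])
    if out_path is not None:
        manifest.to_csv(out_path / "images_manifest.csv", index=False)
    return images, manifest
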