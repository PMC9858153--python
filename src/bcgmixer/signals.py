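"""Recording containers, plain-text I/O and the synthetic BCG cohort generator.

A ballistocardiogram (BCG) records the micro-movements of the body produced by
the ejection of blood at each heartbeat.  The public recordings this package
targets are single-channel series digitized at 100 Hz with a 16-bit ADC, from a
cohort of 61 hypertensive (HPT) and 67 normotensive (NRT) sleepers.  The
synthetic generator here emulates the statistical structure the downstream
pipeline relies on -- class-dependent heart rates, subject-dependent amplitude
scale, sub-hertz baseline wander and broadband sensor noise -- without claiming
physiological fidelity of the beat waveform itself.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Label",
    "BCGRecording",
    "CohortManifest",
    "ManifestEntry",
    "SyntheticParams",
    "generate_subject",
    "generate_cohort",
    "read_recording",
    "write_recording",
]


class Label(str, enum.Enum):
    """Clinical class of a subject: hypertensive or normotensive."""

    HPT = "HPT"
    NRT = "NRT"

    @classmethod
    def coerce(cls, value: "Label | str") -> "Label":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).upper())
        except ValueError:
            raise ValueError(
                f"unknown class label {value!r}; expected one of {[m.value for m in cls]}"
            ) from None


@dataclass
class BCGRecording:
    """One subject's raw amplitude series.

    Parameters
    ----------
    subject_id : str
        Unique subject identifier.
    label : Label
        HPT (hypertensive) or NRT (normotensive).
    samples : ndarray
        Amplitude series in arbitrary units.
    fs : float
        Sampling rate in Hz (100 for the emulated acquisition system).
    bit_depth : int, optional
        ADC resolution when quantization is emulated (16 for the real system).
    """

    subject_id: str
    label: Label
    samples: np.ndarray
    fs: float = 100.0
    bit_depth: Optional[int] = None

    def __post_init__(self) -> None:
        self.label = Label.coerce(self.label)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def trimmed(self, duration_s: float) -> "BCGRecording":
        """Return the first ``duration_s`` seconds of the recording."""
        n = int(round(duration_s * self.fs))
        if self.samples.size < n:
            raise ValueError(
                f"recording {self.subject_id!r} is {self.duration_s:.1f} s long, "
                f"shorter than the requested {duration_s:.1f} s"
            )
        return replace(self, samples=self.samples[:n].copy())


@dataclass
class ManifestEntry:
    subject_id: str
    label: Label
    path: str
    duration_s: float


@dataclass
class CohortManifest:
    """Index of a cohort on disk: one row per subject plus class counts."""

    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.subject_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("subject_ids in a manifest must be unique")

    @property
    def n_hpt(self) -> int:
        return sum(1 for e in self.entries if e.label == Label.HPT)

    @property
    def n_nrt(self) -> int:
        return sum(1 for e in self.entries if e.label == Label.NRT)

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [e.subject_id for e in self.entries],
                "label": [e.label.value for e in self.entries],
                "path": [e.path for e in self.entries],
                "duration_s": [e.duration_s for e in self.entries],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortManifest":
        df = pd.read_csv(path)
        required = {"subject_id", "label", "path", "duration_s"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"manifest {path} is missing columns {sorted(missing)}")
        entries = [
            ManifestEntry(
                subject_id=str(r.subject_id),
                label=Label.coerce(r.label),
                path=str(r.path),
                duration_s=float(r.duration_s),
            )
            for r in df.itertuples()
        ]
        return cls(entries=entries)


@dataclass
class SyntheticParams:
    """Parameters of the synthetic BCG model.

    The generated signal is::

        scale * (beat-wavelet train, respiration-modulated) + wander + noise [+ mains]

    with per-subject heart rate drawn from the class distribution, beat-interval
    jitter emulating heart-rate variability, a log-normal per-subject amplitude
    scale emulating body-weight differences, and a sub-passband sinusoidal
    baseline wander.  ``separation_mode='easy'`` moves the two classes' beat
    wavelets to disjoint center frequencies (4 vs 10 Hz) so the classes are
    separable by construction, for fast end-to-end checks.
    """

    hr_mean_hpt: float = 77.1  # BPM, hypertensive class mean
    hr_sd_hpt: float = 9.2
    hr_mean_nrt: float = 73.6  # BPM, normotensive class mean
    hr_sd_nrt: float = 8.3
    hrv_jitter: float = 0.05  # fractional SD of beat intervals
    amp_log_sigma: float = 0.5  # sigma of the log-normal subject scale (median 1)
    wander_freq: float = 0.2  # Hz, must stay below the 1 Hz passband edge
    wander_amp: float = 0.5
    resp_mod_freq: float = 0.25  # Hz, respiration-like amplitude modulation
    resp_mod_depth: float = 0.2
    noise_sd: float = 0.1
    mains_freq: Optional[float] = None  # e.g. 50.0 to add a mains tone
    mains_amp: float = 0.02
    wavelet_center_hz: float = 5.0  # Gaussian-modulated sinusoid center
    wavelet_width_s: float = 0.15  # Gaussian envelope sigma, seconds
    separation_mode: str = "realistic"  # or "easy"
    quantize_bits: Optional[int] = None  # 16 to emulate the ADC; off by default

    # Easy-mode class wavelet centers: disjoint spectral signatures.
    easy_center_hpt: float = 4.0
    easy_center_nrt: float = 10.0
    # Easy-mode HR distributions do not overlap.
    easy_hr_hpt: tuple[float, float] = (85.0, 2.0)
    easy_hr_nrt: tuple[float, float] = (65.0, 2.0)

    def __post_init__(self) -> None:
        for name in (
            "hr_mean_hpt",
            "hr_sd_hpt",
            "hr_mean_nrt",
            "hr_sd_nrt",
            "hrv_jitter",
            "amp_log_sigma",
            "wander_freq",
            "noise_sd",
            "wavelet_center_hz",
            "wavelet_width_s",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.wander_freq >= 1.0:
            raise ValueError(
                "wander_freq must lie below the 1 Hz lower passband edge so the "
                "bandpass filter can remove it"
            )
        if self.separation_mode not in ("realistic", "easy"):
            raise ValueError("separation_mode must be 'realistic' or 'easy'")

    @classmethod
    def realistic(cls, **overrides) -> "SyntheticParams":
        return cls(**overrides)

    @classmethod
    def easy(cls, **overrides) -> "SyntheticParams":
        overrides.setdefault("separation_mode", "easy")
        return cls(**overrides)

    def hr_distribution(self, label: Label) -> tuple[float, float]:
        """(mean, sd) of the heart-rate distribution for a class, in BPM."""
        if self.separation_mode == "easy":
            return self.easy_hr_hpt if label == Label.HPT else self.easy_hr_nrt
        if label == Label.HPT:
            return self.hr_mean_hpt, self.hr_sd_hpt
        return self.hr_mean_nrt, self.hr_sd_nrt

    def wavelet_center(self, label: Label) -> float:
        if self.separation_mode == "easy":
            return self.easy_center_hpt if label == Label.HPT else self.easy_center_nrt
        return self.wavelet_center_hz


def _beat_train(
    beat_times: np.ndarray,
    n: int,
    fs: float,
    center_hz: float,
    width_s: float,
) -> np.ndarray:
    """Sum of Gaussian-modulated cosines, one per beat, evaluated on the grid."""
    train = np.zeros(n)
    half = int(np.ceil(4.0 * width_s * fs))  # +/-4 sigma support
    for tb in beat_times:
        c = int(round(tb * fs))
        lo, hi = max(0, c - half), min(n, c + half + 1)
        if lo >= hi:
            continue
        t_rel = np.arange(lo, hi) / fs - tb
        train[lo:hi] += np.cos(2 * np.pi * center_hz * t_rel) * np.exp(
            -0.5 * (t_rel / width_s) ** 2
        )
    return train


def synthesize_components(
    label: Label | str,
    duration_s: float,
    fs: float,
    params: SyntheticParams,
    seed: int | np.random.SeedSequence,
) -> dict:
    """Generate one subject's signal and return its constituent parts.

    Returns a dict with keys ``samples``, ``clean`` (scaled modulated beat
    train, pre-noise), ``beat_times``, ``heart_rate_bpm``, ``amplitude_scale``,
    ``wander`` and ``noise``.  Exposed so tests can reason about the noise-free
    beat train directly.
    """
    label = Label.coerce(label)
    if duration_s < 30:
        raise ValueError(f"duration_s must be at least 30 s, got {duration_s}")
    center = params.wavelet_center(label)
    if fs < 2 * center:
        raise ValueError(
            f"fs={fs} Hz cannot represent a {center} Hz beat wavelet (need fs >= {2 * center})"
        )
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    hr_mean, hr_sd = params.hr_distribution(label)
    hr = float(np.clip(rng.normal(hr_mean, hr_sd), 40.0, 120.0))
    mean_rr = 60.0 / hr

    # Beat times: jittered quasi-periodic point process.
    n_beats_max = int(np.ceil(duration_s / mean_rr)) + 8
    intervals = mean_rr * (1.0 + params.hrv_jitter * rng.standard_normal(n_beats_max))
    intervals = np.clip(intervals, 0.3, None)
    beat_times = rng.uniform(0, mean_rr) + np.cumsum(intervals) - intervals[0]
    beat_times = beat_times[beat_times < duration_s]

    train = _beat_train(beat_times, n, fs, center, params.wavelet_width_s)
    resp_phase = rng.uniform(0, 2 * np.pi)
    modulation = 1.0 + params.resp_mod_depth * np.sin(
        2 * np.pi * params.resp_mod_freq * t + resp_phase
    )
    scale = float(np.exp(params.amp_log_sigma * rng.standard_normal()))
    clean = scale * train * modulation

    wander = params.wander_amp * np.sin(
        2 * np.pi * params.wander_freq * t + rng.uniform(0, 2 * np.pi)
    )
    noise = params.noise_sd * rng.standard_normal(n)
    samples = clean + wander + noise
    if params.mains_freq is not None:
        samples = samples + params.mains_amp * np.sin(
            2 * np.pi * params.mains_freq * t + rng.uniform(0, 2 * np.pi)
        )
    if params.quantize_bits is not None:
        samples = _quantize(samples, params.quantize_bits)
    return {
        "samples": samples,
        "clean": clean,
        "beat_times": beat_times,
        "heart_rate_bpm": hr,
        "amplitude_scale": scale,
        "wander": wander,
        "noise": noise,
    }


def _quantize(x: np.ndarray, bits: int) -> np.ndarray:
    """Emulate a full-range ADC: scale to the integer range, round, rescale."""
    peak = np.max(np.abs(x))
    if peak == 0:
        return x
    levels = 2 ** (bits - 1) - 1
    return np.round(x / peak * levels) / levels * peak


def generate_subject(
    label: Label | str,
    duration_s: float,
    fs: float,
    params: SyntheticParams,
    seed: int | np.random.SeedSequence,
    subject_id: Optional[str] = None,
) -> BCGRecording:
    """Generate one synthetic subject; deterministic for a fixed seed."""
    label = Label.coerce(label)
    parts = synthesize_components(label, duration_s, fs, params, seed)
    if subject_id is None:
        subject_id = f"{label.value}-synthetic"
    return BCGRecording(
        subject_id=subject_id,
        label=label,
        samples=parts["samples"],
        fs=fs,
        bit_depth=params.quantize_bits,
    )


def generate_cohort(
    n_hpt: int,
    n_nrt: int,
    duration_s: float,
    params: SyntheticParams,
    seed: int,
    fs: float = 100.0,
    out_dir: Optional[str | Path] = None,
) -> tuple[CohortManifest, list[BCGRecording]]:
    """Generate a two-class cohort, optionally writing files plus a manifest.

    Per-subject seeds are spawned deterministically from the master seed, so an
    entire cohort is reproducible from one integer.
    """
    if n_hpt < 1 or n_nrt < 1:
        raise ValueError("both class counts must be at least 1")
    labels = [Label.HPT] * n_hpt + [Label.NRT] * n_nrt
    children = np.random.SeedSequence(seed).spawn(len(labels))
    recordings: list[BCGRecording] = []
    entries: list[ManifestEntry] = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    hpt_i = nrt_i = 0
    for lab, child in zip(labels, children):
        if lab == Label.HPT:
            hpt_i += 1
            sid = f"HPT{hpt_i:03d}"
        else:
            nrt_i += 1
            sid = f"NRT{nrt_i:03d}"
        rec = generate_subject(lab, duration_s, fs, params, child, subject_id=sid)
        recordings.append(rec)
        rel = f"{sid}.csv"
        if out_path is not None:
            write_recording(rec, out_path / rel)
        entries.append(
            ManifestEntry(subject_id=sid, label=lab, path=rel, duration_s=rec.duration_s)
        )
    manifest = CohortManifest(entries=entries)
    if out_path is not None:
        manifest.to_csv(out_path / "manifest.csv")
    return manifest, recordings


def read_recording(
    path: str | Path,
    fs: float = 100.0,
    label: Label | str = Label.NRT,
    subject_id: Optional[str] = None,
) -> BCGRecording:
    """Read a single-column amplitude series (one sample per line).

    An optional single header line (e.g. ``amplitude``) is skipped.  Any other
    non-numeric row is reported with its 1-based line number.
    """
    path = Path(path)
    values: list[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            text = raw.strip()
            if not text:
                continue
            try:
                values.append(float(text))
            except ValueError:
                if lineno == 1 and not values:
                    continue  # header line
                raise ValueError(
                    f"{path}: non-numeric value {text!r} on line {lineno}"
                ) from None
    if not values:
        raise ValueError(f"{path}: file contains no samples")
    if subject_id is None:
        subject_id = path.stem
    return BCGRecording(
        subject_id=subject_id, label=Label.coerce(label), samples=np.array(values), fs=fs
    )


def write_recording(rec: BCGRecording, path: str | Path) -> None:
    """Write one sample per line; round-trips with :func:`read_recording`."""
    if rec.samples.size < 1:
        raise ValueError("refusing to write an empty recording")
    np.savetxt(path, rec.samples, fmt="%.12g")


def load_cohort(
    manifest: CohortManifest, base_dir: str | Path, fs: float = 100.0
) -> list[BCGRecording]:
    """Load every recording referenced by a manifest (paths relative to base_dir)."""
    base = Path(base_dir)
    out = []
    for e in manifest.entries:
        p = Path(e.path)
        if not p.is_absolute():
            p = base / p
        out.append(read_recording(p, fs=fs, label=e.label, subject_id=e.subject_id))
    return out
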