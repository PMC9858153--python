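"""MAD-based z-score normalization, Chebyshev type II bandpass filtering and
non-overlapping 30-second segmentation.

Normalization removes subject-dependent amplitude scale (body weight directly
affects BCG amplitude) by centering on the median and dividing by the median
absolute deviation, so every recording ends up with median 0 and MAD 1.  The
canonical bandpass filter is carried as a fixed set of published constants (see
:func:`canonical_filter`); a configurable Chebyshev II designer is provided for
variants but the fixed coefficients are the reproducible contract.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import signal as sps

from .signals import BCGRecording, Label

__all__ = [
    "mad",
    "mad_zscore_normalize",
    "NormalizedSignal",
    "FilterCoefficients",
    "canonical_filter",
    "design_cheby2_bandpass",
    "apply_iir_filter",
    "Segment",
    "segment",
    "preprocess_recording",
]


def mad(x) -> float:
    """Median absolute deviation: ``median(|x - median(x)|)``.

    No Gaussian consistency constant is applied -- the normalization contract
    is that the rescaled signal has MAD exactly 1, not SD 1.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise ValueError("mad() of an empty sequence is undefined")
    return float(np.median(np.abs(x - np.median(x))))


@dataclass
class NormalizedSignal:
    """A MAD z-scored signal plus the location/scale that was removed."""

    samples: np.ndarray
    median: float
    mad: float


def mad_zscore_normalize(x) -> NormalizedSignal:
    """Center on the median and scale by the MAD.

    The output has median 0 and MAD 1 (up to floating point).  Constant
    signals have MAD 0 and are rejected as degenerate rather than silently
    dividing by zero.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("normalization needs at least 2 samples")
    med = float(np.median(x))
    scale = mad(x)
    if scale == 0:
        raise ValueError("degenerate (constant) signal: MAD is zero")
    return NormalizedSignal(samples=(x - med) / scale, median=med, mad=scale)


@dataclass
class FilterCoefficients:
    """IIR transfer function b/a with design metadata.

    Invariants: ``a[0] == 1``, numerator and denominator have equal length,
    and all poles lie strictly inside the unit circle.
    """

    b: np.ndarray
    a: np.ndarray
    order: int
    f_low: float
    f_high: float
    fs: float
    description: str = ""

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if self.b.shape != self.a.shape:
            raise ValueError("numerator and denominator must have equal length")
        if not np.isclose(self.a[0], 1.0):
            raise ValueError("denominator must be normalized (a[0] = 1)")

    def poles(self) -> np.ndarray:
        return np.roots(self.a)

    def is_stable(self) -> bool:
        return bool(np.all(np.abs(self.poles()) < 1.0))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "b": self.b.tolist(),
                    "a": self.a.tolist(),
                    "order": self.order,
                    "f_low": self.f_low,
                    "f_high": self.f_high,
                    "fs": self.fs,
                    "description": self.description,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "FilterCoefficients":
        d = json.loads(Path(path).read_text())
        return cls(**d)


#: Published constants of the 4th-order Chebyshev type II bandpass (1-50 Hz,
#: fs = 100 Hz) used by the canonical pipeline.  Note the printed constants and
#: the nominal band description are not mutually consistent (the DC gain of
#: these coefficients is ~0.96, and a 50 Hz upper edge coincides with Nyquist
#: at 100 Hz); the constants are treated as authoritative.  See docs/methods.md.
_CANONICAL_B = (0.028, 0.053, 0.071, 0.053, 0.028)
_CANONICAL_A = (1.0, -2.026, 2.148, -1.159, 0.279)


def canonical_filter() -> FilterCoefficients:
    """The fixed bandpass coefficients used by the canonical pipeline."""
    return FilterCoefficients(
        b=np.array(_CANONICAL_B),
        a=np.array(_CANONICAL_A),
        order=4,
        f_low=1.0,
        f_high=50.0,
        fs=100.0,
        description="canonical 4th-order Chebyshev II bandpass, fixed published constants",
    )


def design_cheby2_bandpass(
    order: int,
    f_low: float,
    f_high: float,
    fs: float,
    stop_atten_db: float = 40.0,
) -> FilterCoefficients:
    """Design a Chebyshev type II bandpass of the given transfer-function order.

    ``order`` is the order of the resulting polynomial (so 4 gives 5 taps,
    matching the canonical coefficients' length) and must be even.  Band edges
    must lie strictly inside (0, Nyquist); a digital bandpass edge at exactly
    Nyquist is not designable.
    """
    if order < 2 or order % 2 != 0:
        raise ValueError("bandpass order must be an even integer >= 2")
    nyq = fs / 2.0
    if not (0 < f_low < f_high < nyq):
        raise ValueError(
            f"band edges must satisfy 0 < f_low < f_high < fs/2 = {nyq} Hz; "
            f"got ({f_low}, {f_high})"
        )
    b, a = sps.cheby2(
        order // 2, stop_atten_db, [f_low / nyq, f_high / nyq], btype="bandpass"
    )
    return FilterCoefficients(
        b=b,
        a=a,
        order=order,
        f_low=f_low,
        f_high=f_high,
        fs=fs,
        description=f"designed Chebyshev II bandpass, {stop_atten_db} dB stopband",
    )


def apply_iir_filter(x, coeffs: FilterCoefficients, zero_phase: bool = False) -> np.ndarray:
    """Apply the IIR filter with zero initial state.

    Single-pass causal filtering by default (``scipy.signal.lfilter``); set
    ``zero_phase=True`` for forward-backward filtering when phase distortion
    matters more than causality.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise ValueError("cannot filter an empty signal")
    if not coeffs.is_stable():
        raise ValueError("unstable filter: poles on or outside the unit circle")
    if zero_phase:
        return sps.filtfilt(coeffs.b, coeffs.a, x)
    return sps.lfilter(coeffs.b, coeffs.a, x)


@dataclass
class Segment:
    """A fixed-length window of a preprocessed recording with provenance."""

    samples: np.ndarray
    subject_id: str
    segment_index: int
    label: Optional[Label] = None
    fs: float = 100.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.label is not None:
            self.label = Label.coerce(self.label)


def segment(
    x,
    fs: float,
    window_s: float = 30.0,
    subject_id: str = "",
    label: Optional[Label | str] = None,
) -> list[Segment]:
    """Cut a signal into consecutive non-overlapping windows of ``window_s``.

    The trailing remainder shorter than one window is discarded; a signal
    shorter than one window yields an empty list.
    """
    x = np.asarray(x, dtype=float)
    n_win = fs * window_s
    if abs(n_win - round(n_win)) > 1e-9:
        raise ValueError(f"fs*window_s = {n_win} is not an integer number of samples")
    n_win = int(round(n_win))
    n_seg = x.size // n_win
    return [
        Segment(
            samples=x[i * n_win : (i + 1) * n_win].copy(),
            subject_id=subject_id,
            segment_index=i,
            label=label,
            fs=fs,
        )
        for i in range(n_seg)
    ]


def preprocess_recording(
    rec: BCGRecording,
    coeffs: Optional[FilterCoefficients] = None,
    window_s: float = 30.0,
    zero_phase: bool = False,
) -> list[Segment]:
    """Canonical per-recording chain: normalize -> filter -> segment.

    Normalization is computed over the whole (already trimmed) recording, not
    per segment, so every segment of a subject shares one location/scale.
    """
    if coeffs is None:
        coeffs = canonical_filter()
    norm = mad_zscore_normalize(rec.samples)
    filtered = apply_iir_filter(norm.samples, coeffs, zero_phase=zero_phase)
    return segment(filtered, rec.fs, window_s, subject_id=rec.subject_id, label=rec.label)
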