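"""Short-time Fourier transform spectrograms.

A normalized 10-s, 500-Hz segment is framed (frame_length 256, hop 128),
tapered with a periodic Hann window, and transformed frame-by-frame; the
one-sided magnitude spectrum per frame forms the T x F matrix the
classifier consumes. With the defaults a 5000-sample segment yields
exactly 38 frames x 129 bins:

    T = floor((5000 - 256) / 128) + 1 = 38,    F = 256 / 2 + 1 = 129.

No padding is applied; the partial tail frame is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import InvalidArgumentError, ShapeError
from .signal_io import ECGRecord, normalize

__all__ = [
    "STFTParams",
    "Spectrogram",
    "hann_window",
    "stft_magnitude",
    "to_model_input",
    "frame_count",
]

DEFAULT_FRAME_LENGTH = 256
DEFAULT_FRAME_STEP = 128


@dataclass(frozen=True)
class STFTParams:
    """Framing parameters of the short-time Fourier transform.

    ``frame_length`` is the analysis-window span N (must be even);
    ``frame_step`` the hop between successive frames. Only the Hann taper
    is supported — Hamming trades leakage suppression for a wider main
    lobe and is deliberately not offered.
    """

    frame_length: int = DEFAULT_FRAME_LENGTH
    frame_step: int = DEFAULT_FRAME_STEP
    window: str = "hann"

    def __post_init__(self) -> None:
        if self.frame_length < 2 or self.frame_length % 2 != 0:
            raise InvalidArgumentError(
                f"frame_length must be an even integer >= 2, got {self.frame_length}"
            )
        if not (0 < self.frame_step <= self.frame_length):
            raise InvalidArgumentError(
                f"frame_step must satisfy 0 < step <= frame_length, got {self.frame_step}"
            )
        if self.window != "hann":
            raise InvalidArgumentError(f"unsupported window: {self.window!r}")

    @property
    def n_bins(self) -> int:
        return self.frame_length // 2 + 1


@dataclass(frozen=True)
class Spectrogram:
    """T x F nonnegative magnitude matrix (time frames x frequency bins)."""

    values: np.ndarray
    params: STFTParams = field(default_factory=STFTParams)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2:
            raise ShapeError(f"spectrogram must be 2-D, got shape {values.shape}")
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


def hann_window(n: int) -> np.ndarray:
    """Periodic Hann taper w[k] = 0.5 - 0.5 cos(2 pi k / n), k = 0..n-1.

    The denominator is n (periodic form), so w[0] = 0 and, for even n,
    the center weight w[n/2] = 1.
    """
    if n < 2:
        raise InvalidArgumentError(f"window length must be >= 2, got {n}")
    k = np.arange(n)
    return 0.5 - 0.5 * np.cos(2.0 * np.pi * k / n)


def frame_count(n_samples: int, params: STFTParams) -> int:
    """Number of complete frames: floor((L - frame_length)/frame_step) + 1."""
    if n_samples < params.frame_length:
        return 0
    return (n_samples - params.frame_length) // params.frame_step + 1


def stft_magnitude(signal: np.ndarray, params: STFTParams | None = None) -> Spectrogram:
    """One-sided magnitude STFT of a 1-D signal.

    Frame f covers samples [f*step, f*step + frame_length); each frame is
    multiplied pointwise by the Hann taper and transformed; the magnitude
    of the one-sided spectrum (frame_length/2 + 1 bins) is returned. The
    signal must contain at least one full frame; no padding is performed.
    """
    params = params or STFTParams()
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 1:
        raise InvalidArgumentError(f"signal must be 1-D, got shape {x.shape}")
    if x.size < params.frame_length:
        raise InvalidArgumentError(
            f"signal length {x.size} shorter than one frame ({params.frame_length})"
        )
    n_frames = frame_count(x.size, params)
    frames = sliding_window_view(x, params.frame_length)[:: params.frame_step][:n_frames]
    tapered = frames * hann_window(params.frame_length)
    mags = np.abs(np.fft.rfft(tapered, axis=1))
    return Spectrogram(values=mags, params=params)


def to_model_input(
    record: ECGRecord,
    params: STFTParams | None = None,
    *,
    expected_duration_s: float = 10.0,
    expected_fs: float = 500.0,
) -> Spectrogram:
    """Normalize a fixed-duration segment and convert it to a spectrogram.

    The record must already be at the working rate and exact window
    duration (default 10 s at 500 Hz = 5000 samples); anything else raises
    a :class:`ShapeError` naming expected vs actual, since silent padding
    or truncation here would desynchronize inputs from labels.
    """
    params = params or STFTParams()
    expected_n = round(expected_duration_s * expected_fs)
    if record.fs != expected_fs or record.n_samples != expected_n:
        raise ShapeError(
            f"expected {expected_n} samples at {expected_fs:g} Hz "
            f"({expected_duration_s:g} s), got {record.n_samples} samples at "
            f"{record.fs:g} Hz — resample/segment first"
        )
    return stft_magnitude(normalize(record).samples, params)
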