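"""Waveform I/O, resampling, amplitude normalization, and segmentation.

Records come in as delimited-text columns (one column per lead) or WAV
audio; they are resampled to the working rate (default 500 Hz), cut into
fixed-length labeled windows, and min-max normalized to [-1, 1] before
spectrogram conversion.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

from .errors import FormatError, InvalidArgumentError, MissingRateError

__all__ = [
    "QualityLabel",
    "ECGRecord",
    "LabelRegion",
    "read_waveform",
    "resample",
    "segment_labeled",
    "normalize",
]


class QualityLabel(enum.IntEnum):
    """Binary quality class; the integer value is the training encoding."""

    UNACCEPTABLE = 0
    ACCEPTABLE = 1

    @classmethod
    def parse(cls, text: str) -> "QualityLabel":
        key = str(text).strip().lower()
        if key in {"acceptable", "a", "1", "good"}:
            return cls.ACCEPTABLE
        if key in {"unacceptable", "u", "0", "bad"}:
            return cls.UNACCEPTABLE
        raise InvalidArgumentError(f"unrecognized quality label: {text!r}")


@dataclass(frozen=True)
class ECGRecord:
    """A single-lead amplitude series.

    Parameters
    ----------
    samples
        Amplitude series, arbitrary units.
    fs
        Sampling rate in Hz (> 0).
    lead_id
        Lead name ("I", "V5", "lead_3", ...).
    group_id
        Identity of the source recording; all leads extracted from one
        multi-lead file share it, which is what group-aware splitting keys
        on to prevent leakage.
    meta
        Free-form provenance (e.g. synthetic-generation parameters).
    """

    samples: np.ndarray
    fs: float
    lead_id: str = "I"
    group_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size < 1:
            raise InvalidArgumentError(
                f"record must be a non-empty 1-D series, got shape {samples.shape}"
            )
        if not (self.fs > 0) or not math.isfinite(self.fs):
            raise InvalidArgumentError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass(frozen=True)
class LabelRegion:
    """A contiguous time span carrying one quality label."""

    start_s: float
    end_s: float
    label: QualityLabel

    def __post_init__(self) -> None:
        if not (self.end_s > self.start_s) or self.start_s < 0:
            raise InvalidArgumentError(
                f"region must satisfy 0 <= start < end, got [{self.start_s}, {self.end_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def _sniff_text_matrix(path: Path) -> np.ndarray:
    raw = path.read_text()
    if not raw.strip():
        raise FormatError(f"{path}: empty waveform file")
    lines = [ln for ln in raw.splitlines() if ln.strip()]
    delimiter = "," if ("," in lines[0]) else None
    skip = 0
    try:  # tolerate a single non-numeric header row
        first = lines[0].replace(",", " ").split()
        [float(v) for v in first]
    except ValueError:
        skip = 1
    try:
        data = np.loadtxt(path, delimiter=delimiter, skiprows=skip, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: cannot parse delimited waveform ({exc})") from exc
    if data.size == 0:
        raise FormatError(f"{path}: no numeric samples found")
    return data


def read_waveform(path: str | Path, fs_hint: float | None = None) -> list[ECGRecord]:
    """Read a waveform file and return one :class:`ECGRecord` per lead.

    Text files are whitespace- or comma-delimited with one column per lead
    (no header required; a single header row is tolerated); the sampling
    rate must come from ``fs_hint``. WAV files carry their rate in the
    header. All leads share ``group_id`` = the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    if path.stat().st_size == 0:
        raise FormatError(f"{path}: empty file")

    if path.suffix.lower() == ".wav":
        try:
            rate, data = wavfile.read(path)
        except Exception as exc:  # wavfile raises bare ValueError on corruption
            raise FormatError(f"{path}: cannot parse WAV ({exc})") from exc
        # integer PCM amplitudes are kept as-is; normalization removes units
        data = np.asarray(data, dtype=np.float64)
        fs = float(rate)
        matrix = data[:, None] if data.ndim == 1 else data
    else:
        if fs_hint is None:
            raise MissingRateError(
                f"{path}: text waveform needs a sampling-rate hint (fs_hint or config)"
            )
        fs = float(fs_hint)
        matrix = _sniff_text_matrix(path)

    if not fs > 0:
        raise FormatError(f"{path}: non-positive sampling rate {fs}")
    group = path.stem
    return [
        ECGRecord(matrix[:, j], fs=fs, lead_id=f"lead_{j + 1}", group_id=group)
        for j in range(matrix.shape[1])
    ]


def resample(record: ECGRecord, target_fs: float) -> ECGRecord:
    """Band-limited (polyphase) resampling to ``target_fs``.

    Output length is round(n * target_fs / fs). A no-op when the rates
    already match.
    """
    if not target_fs > 0:
        raise InvalidArgumentError(f"target_fs must be positive, got {target_fs}")
    if target_fs == record.fs:
        return record
    ratio = Fraction(target_fs / record.fs).limit_denominator(10_000)
    out = resample_poly(record.samples, ratio.numerator, ratio.denominator)
    n_expected = round(record.n_samples * target_fs / record.fs)
    if out.size > n_expected:
        out = out[:n_expected]
    elif out.size < n_expected:
        out = np.pad(out, (0, n_expected - out.size), mode="edge")
    return replace(record, samples=out, fs=float(target_fs))


def segment_labeled(
    record: ECGRecord,
    regions: list[LabelRegion],
    window_s: float = 10.0,
) -> list[tuple[ECGRecord, QualityLabel]]:
    """Cut labeled regions into fixed non-overlapping windows.

    Each region yields floor(duration / window_s) consecutive windows
    anchored at the region start, all inheriting the region label; the tail
    remainder and any region shorter than one window are discarded. Windows
    keep the parent ``group_id``.
    """
    if not window_s > 0:
        raise InvalidArgumentError(f"window_s must be positive, got {window_s}")
    ordered = sorted(regions, key=lambda r: r.start_s)
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.start_s < prev.end_s:
            raise InvalidArgumentError(
                f"overlapping label regions: [{prev.start_s},{prev.end_s}) and "
                f"[{cur.start_s},{cur.end_s})"
            )
    duration = record.duration_s
    out: list[tuple[ECGRecord, QualityLabel]] = []
    win_n = round(window_s * record.fs)
    for region in ordered:
        if region.end_s > duration + 1e-9:
            raise InvalidArgumentError(
                f"region [{region.start_s},{region.end_s}) exceeds record duration {duration:.6g}s"
            )
        n_windows = int(region.duration_s // window_s)
        start_n = round(region.start_s * record.fs)
        for w in range(n_windows):
            lo = start_n + w * win_n
            seg = record.samples[lo : lo + win_n]
            out.append(
                (
                    replace(
                        record,
                        samples=seg,
                        meta={**record.meta, "window_index": w, "region_start_s": region.start_s},
                    ),
                    region.label,
                )
            )
    return out


def normalize(record: ECGRecord) -> ECGRecord:
    """Min-max normalize amplitudes to [-1, 1].

    Non-constant input maps onto the full range (both endpoints attained);
    constant input maps to all zeros so downstream stages see a well-defined
    silent segment instead of a divide-by-zero.
    """
    x = record.samples
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return replace(record, samples=np.zeros_like(x))
    return replace(record, samples=2.0 * (x - lo) / (hi - lo) - 1.0)
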