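"""Synthetic single-lead ECG with controlled contamination.

The generator produces 10-s, 500-Hz phantoms: a quasi-periodic PQRST
waveform (five Gaussian bumps per beat, mild RR jitter) plus one of the
four canonical ECG noise families — baseline wander, powerline tone,
EMG-like broadband noise, electrode-motion transients — or a composite,
scaled to an exact target signal-to-noise ratio. It exists so that every
stage of the quality-assessment pipeline is exercisable end-to-end with no
external recordings; it makes no claim of physiological fidelity beyond
morphology plausible enough for a quality (not diagnosis) classifier.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, filtfilt

from .datasets import Corpus
from .errors import InvalidArgumentError
from .signal_io import ECGRecord, QualityLabel

__all__ = ["NoiseKind", "NoiseSpec", "make_clean_ecg", "add_noise", "make_labeled_corpus"]

# Per-beat morphology: (offset, width, amplitude), offsets and widths as
# fractions of the RR interval so beats compress cleanly at high rates.
# At 60 bpm (RR = 1 s) these are the usual textbook timings in seconds.
_PQRST = (
    (-0.20, 0.025, 0.15),  # P
    (-0.03, 0.010, -0.10),  # Q
    (0.00, 0.012, 1.00),  # R
    (0.03, 0.012, -0.25),  # S
    (0.25, 0.060, 0.35),  # T
)

DEFAULT_SNR_ACCEPTABLE_DB = 15.0
DEFAULT_SNR_UNACCEPTABLE_DB = -5.0


class NoiseKind(str, enum.Enum):
    BASELINE_WANDER = "baseline_wander"
    POWERLINE = "powerline"
    EMG = "emg"
    ELECTRODE_MOTION = "electrode_motion"
    COMPOSITE = "composite"


@dataclass(frozen=True)
class NoiseSpec:
    """Recipe for one contamination: family, target SNR, mains frequency, seed."""

    kind: NoiseKind = NoiseKind.COMPOSITE
    target_snr_db: float = 0.0
    powerline_hz: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if math.isnan(self.target_snr_db):
            raise InvalidArgumentError("target_snr_db must not be NaN")
        if self.powerline_hz not in (50.0, 60.0, 50, 60):
            raise InvalidArgumentError(
                f"powerline_hz must be 50 or 60, got {self.powerline_hz}"
            )
        object.__setattr__(self, "kind", NoiseKind(self.kind))


def make_clean_ecg(
    duration_s: float,
    fs: float,
    heart_rate_bpm: float,
    seed: int,
) -> ECGRecord:
    """Generate a clean quasi-periodic PQRST waveform.

    Beat-to-beat RR intervals jitter uniformly within +-5% of the nominal
    interval. The R peak has unit amplitude. Deterministic for a fixed
    seed.
    """
    if not duration_s > 0:
        raise InvalidArgumentError(f"duration_s must be positive, got {duration_s}")
    if not fs > 0:
        raise InvalidArgumentError(f"fs must be positive, got {fs}")
    if not (30.0 <= heart_rate_bpm <= 220.0):
        raise InvalidArgumentError(
            f"heart_rate_bpm must lie in [30, 220], got {heart_rate_bpm}"
        )
    rng = np.random.default_rng(seed)
    n = round(duration_s * fs)
    t = np.arange(n) / fs
    rr0 = 60.0 / heart_rate_bpm

    # beat instants: start one beat before 0 so the first window has a full PQRST
    beat_times = []
    t_beat = -rr0
    while t_beat < duration_s + rr0:
        beat_times.append(t_beat)
        t_beat += rr0 * (1.0 + rng.uniform(-0.05, 0.05))

    x = np.zeros(n)
    for tb in beat_times:
        for off, width, amp in _PQRST:
            mu = tb + off * rr0
            sigma = width * rr0
            # contributions are negligible beyond 6 sigma; restrict for speed
            lo = max(0, int((mu - 6 * sigma) * fs))
            hi = min(n, int((mu + 6 * sigma) * fs) + 1)
            if lo >= hi:
                continue
            x[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - mu) / sigma) ** 2)
    return ECGRecord(
        x,
        fs=float(fs),
        lead_id="I",
        group_id=f"synthetic_{seed}",
        meta={"heart_rate_bpm": float(heart_rate_bpm), "seed": int(seed), "clean": True},
    )


def _raw_noise(kind: NoiseKind, n: int, fs: float, powerline_hz: float, rng) -> np.ndarray:
    t = np.arange(n) / fs
    if kind is NoiseKind.BASELINE_WANDER:
        f = rng.uniform(0.15, 0.5)
        return np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    if kind is NoiseKind.POWERLINE:
        return np.sin(2 * np.pi * powerline_hz * t + rng.uniform(0, 2 * np.pi))
    if kind is NoiseKind.EMG:
        white = rng.standard_normal(n)
        high = min(120.0, 0.45 * fs)
        b, a = butter(4, [20.0 / (fs / 2), high / (fs / 2)], btype="band")
        return filtfilt(b, a, white)
    if kind is NoiseKind.ELECTRODE_MOTION:
        noise = np.zeros(n)
        n_events = int(rng.integers(3, 9))
        for _ in range(n_events):
            center = int(rng.integers(0, n))
            amp = rng.uniform(0.5, 2.0) * rng.choice([-1.0, 1.0])
            if rng.random() < 0.5:  # baseline step with a soft edge
                edge = max(1, int(0.02 * fs))
                ramp = np.clip((np.arange(n) - center) / edge, 0.0, 1.0)
                noise += amp * ramp
            else:  # exponentially decaying spike
                tau = rng.uniform(0.02, 0.2) * fs
                idx = np.arange(center, n)
                noise[center:] += amp * np.exp(-(idx - center) / tau)
        if not np.any(noise):  # pathological draw; fall back to one hard step
            noise[n // 2 :] = 1.0
        return noise
    # composite: random convex mixture of the four families, each at unit power
    kinds = [
        NoiseKind.BASELINE_WANDER,
        NoiseKind.POWERLINE,
        NoiseKind.EMG,
        NoiseKind.ELECTRODE_MOTION,
    ]
    weights = rng.dirichlet(np.ones(len(kinds)))
    mix = np.zeros(n)
    for w, k in zip(weights, kinds):
        component = _raw_noise(k, n, fs, powerline_hz, rng)
        mix += w * component / math.sqrt(float(np.mean(component**2)))
    return mix


def add_noise(record: ECGRecord, spec: NoiseSpec) -> ECGRecord:
    """Add contamination scaled to an exact target SNR.

    The noise realization is drawn from ``spec.seed`` and scaled so that
    10*log10(P_signal / P_noise) equals ``spec.target_snr_db``; a target of
    +inf returns the record unchanged. Deterministic for a fixed spec.
    """
    if record.n_samples < 1:
        raise InvalidArgumentError("record must be non-empty")
    if spec.target_snr_db == math.inf:
        return replace(record, meta={**record.meta, "snr_db": math.inf})
    rng = np.random.default_rng(spec.seed)
    noise = _raw_noise(spec.kind, record.n_samples, record.fs, float(spec.powerline_hz), rng)
    p_signal = float(np.mean(record.samples**2))
    p_noise = float(np.mean(noise**2))
    if p_noise == 0.0:
        return replace(record, meta={**record.meta, "snr_db": math.inf})
    scale = math.sqrt(p_signal / (p_noise * 10.0 ** (spec.target_snr_db / 10.0)))
    return replace(
        record,
        samples=record.samples + scale * noise,
        meta={
            **record.meta,
            "clean": False,
            "noise_kind": spec.kind.value,
            "snr_db": float(spec.target_snr_db),
        },
    )


def make_labeled_corpus(
    n: int,
    ratio_acceptable: float,
    fs: float = 500.0,
    snr_acceptable_db: float = DEFAULT_SNR_ACCEPTABLE_DB,
    snr_unacceptable_db: float = DEFAULT_SNR_UNACCEPTABLE_DB,
    seed: int = 0,
) -> Corpus:
    """Generate a labeled corpus of 10-s synthetic records.

    round(n * ratio_acceptable) records are acceptable — clean or lightly
    contaminated at ``snr_acceptable_db`` — and the remainder unacceptable,
    heavily contaminated at ``snr_unacceptable_db`` with the noise family
    cycling through the full palette. Every record carries a unique
    group id. Heart rates vary uniformly in [50, 100] bpm.
    """
    if n < 2:
        raise InvalidArgumentError(f"corpus needs at least 2 records, got {n}")
    if not (0.0 < ratio_acceptable < 1.0):
        raise InvalidArgumentError(
            f"ratio_acceptable must lie in (0, 1), got {ratio_acceptable}"
        )
    if not snr_acceptable_db > snr_unacceptable_db:
        raise InvalidArgumentError(
            "snr_acceptable_db must exceed snr_unacceptable_db "
            f"({snr_acceptable_db} vs {snr_unacceptable_db})"
        )
    master = np.random.default_rng(seed)
    record_seeds = master.integers(0, 2**31 - 1, size=n)
    n_acceptable = round(n * ratio_acceptable)
    noise_palette = list(NoiseKind)

    items = []
    for i in range(n):
        rec_seed = int(record_seeds[i])
        rec_rng = np.random.default_rng(rec_seed)
        hr = float(rec_rng.uniform(50.0, 100.0))
        clean = make_clean_ecg(10.0, fs, hr, seed=rec_seed)
        acceptable = i < n_acceptable
        if acceptable and rec_rng.random() < 0.5:
            record = replace(clean, meta={**clean.meta, "snr_db": math.inf})
        else:
            kind = noise_palette[i % len(noise_palette)]
            snr = snr_acceptable_db if acceptable else snr_unacceptable_db
            record = add_noise(
                clean, NoiseSpec(kind=kind, target_snr_db=snr, seed=rec_seed + 1)
            )
        gid = f"syn_{seed}_{i:05d}"
        record = replace(record, group_id=gid)
        label = QualityLabel.ACCEPTABLE if acceptable else QualityLabel.UNACCEPTABLE
        items.append((record, label, gid))

    order = master.permutation(n)
    return Corpus(items=[items[i] for i in order])
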