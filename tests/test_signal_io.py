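"""Waveform reading, resampling, segmentation, and normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.io import wavfile

import ecgqual as eq
from ecgqual.errors import FormatError, InvalidArgumentError, MissingRateError
from ecgqual.signal_io import LabelRegion, QualityLabel


class TestReadWaveform:
    def test_twelve_column_text(self, tmp_path):
        data = np.random.default_rng(0).standard_normal((100, 12))
        path = tmp_path / "ecg12.txt"
        np.savetxt(path, data)
        records = eq.read_waveform(path, fs_hint=500)
        assert len(records) == 12
        assert all(r.group_id == "ecg12" for r in records)
        np.testing.assert_allclose(records[3].samples, data[:, 3], rtol=1e-6)

    def test_comma_delimited_with_header(self, tmp_path):
        path = tmp_path / "two_leads.csv"
        path.write_text("leadA,leadB\n1,4\n2,5\n3,6\n")
        records = eq.read_waveform(path, fs_hint=250)
        assert len(records) == 2
        np.testing.assert_array_equal(records[1].samples, [4, 5, 6])

    def test_mono_wav(self, tmp_path):
        path = tmp_path / "mono.wav"
        samples = (1000 * np.sin(2 * np.pi * 5 * np.arange(5000) / 500)).astype(np.int16)
        wavfile.write(path, 500, samples)
        records = eq.read_waveform(path)
        assert len(records) == 1
        assert records[0].n_samples == 5000
        assert records[0].fs == 500

    def test_zero_byte_file(self, tmp_path):
        path = tmp_path / "empty.txt"
        path.touch()
        with pytest.raises(FormatError):
            eq.read_waveform(path, fs_hint=500)

    def test_text_without_rate_hint(self, tmp_path):
        path = tmp_path / "nohint.txt"
        np.savetxt(path, np.ones(10))
        with pytest.raises(MissingRateError):
            eq.read_waveform(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FormatError):
            eq.read_waveform(tmp_path / "ghost.txt", fs_hint=500)


class TestResample:
    def test_downsample_length(self):
        rec = eq.ECGRecord(np.random.default_rng(1).standard_normal(10_000), fs=1000)
        out = eq.resample(rec, 500)
        assert out.n_samples == 5000
        assert out.fs == 500

    def test_identity(self):
        rec = eq.ECGRecord(np.arange(100, dtype=float), fs=500)
        out = eq.resample(rec, 500)
        np.testing.assert_array_equal(out.samples, rec.samples)

    def test_sinusoid_peak_preserved(self):
        """Oracle: the dominant DFT peak of a 5-Hz tone survives 1000->500 Hz."""
        t = np.arange(10_000) / 1000
        rec = eq.ECGRecord(np.sin(2 * np.pi * 5 * t), fs=1000)
        out = eq.resample(rec, 500)
        spectrum = np.abs(np.fft.rfft(out.samples))
        freqs = np.fft.rfftfreq(out.n_samples, d=1 / 500)
        assert freqs[int(spectrum.argmax())] == pytest.approx(5.0, abs=0.1)

    def test_round_trip_recovers_bandlimited_signal(self):
        t = np.arange(5000) / 500
        x = np.sin(2 * np.pi * 7 * t) + 0.5 * np.cos(2 * np.pi * 13 * t)
        rec = eq.ECGRecord(x, fs=500)
        back = eq.resample(eq.resample(rec, 1000), 500)
        interior = slice(100, -100)  # polyphase edges are not band-limited
        np.testing.assert_allclose(back.samples[interior], x[interior], atol=1e-3)

    def test_invalid_target(self):
        rec = eq.ECGRecord(np.ones(10), fs=500)
        with pytest.raises(InvalidArgumentError):
            eq.resample(rec, 0)


class TestSegmentLabeled:
    @staticmethod
    def _record(duration_s: float, fs: float = 500.0) -> eq.ECGRecord:
        n = round(duration_s * fs)
        return eq.ECGRecord(np.arange(n, dtype=float), fs=fs, group_id="parent")

    @pytest.mark.parametrize("region_s,expected", [(9.9, 0), (25, 2), (1200, 120)])
    def test_window_counts(self, region_s, expected):
        rec = self._record(region_s)
        regions = [LabelRegion(0, region_s, QualityLabel.ACCEPTABLE)]
        assert len(eq.segment_labeled(rec, regions)) == expected

    def test_windows_reproduce_region_prefix(self):
        rec = self._record(35)
        regions = [LabelRegion(5, 30, QualityLabel.UNACCEPTABLE)]
        windows = eq.segment_labeled(rec, regions)
        assert len(windows) == 2
        glued = np.concatenate([w.samples for w, _ in windows])
        np.testing.assert_array_equal(glued, rec.samples[2500 : 2500 + 10_000])
        assert all(label == QualityLabel.UNACCEPTABLE for _, label in windows)
        assert all(w.group_id == "parent" for w, _ in windows)

    def test_multiple_regions_sum(self):
        rec = self._record(60)
        regions = [
            LabelRegion(0, 25, QualityLabel.ACCEPTABLE),
            LabelRegion(30, 41, QualityLabel.UNACCEPTABLE),
            LabelRegion(45, 50, QualityLabel.ACCEPTABLE),
        ]
        assert len(eq.segment_labeled(rec, regions)) == 2 + 1 + 0

    def test_overlapping_regions_rejected(self):
        rec = self._record(40)
        regions = [
            LabelRegion(0, 20, QualityLabel.ACCEPTABLE),
            LabelRegion(15, 35, QualityLabel.UNACCEPTABLE),
        ]
        with pytest.raises(InvalidArgumentError):
            eq.segment_labeled(rec, regions)

    def test_region_past_record_end_rejected(self):
        rec = self._record(15)
        with pytest.raises(InvalidArgumentError):
            eq.segment_labeled(rec, [LabelRegion(0, 20, QualityLabel.ACCEPTABLE)])

    def test_nonpositive_window_rejected(self):
        rec = self._record(15)
        with pytest.raises(InvalidArgumentError):
            eq.segment_labeled(rec, [LabelRegion(0, 10, QualityLabel.ACCEPTABLE)], window_s=0)


class TestNormalize:
    @pytest.mark.parametrize(
        "samples,expected",
        [
            ([0, 5, 10], [-1, 0, 1]),
            ([3, 3, 3], [0, 0, 0]),
            ([-2, 2], [-1, 1]),
        ],
    )
    def test_examples(self, samples, expected):
        rec = eq.ECGRecord(np.array(samples, dtype=float), fs=500)
        np.testing.assert_allclose(eq.normalize(rec).samples, expected)

    @settings(max_examples=50)
    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=2,
            max_size=200,
        ).filter(lambda xs: max(xs) > min(xs))
    )
    def test_range_attained_exactly(self, samples):
        out = eq.normalize(eq.ECGRecord(np.array(samples), fs=500)).samples
        assert out.min() == -1.0
        assert out.max() == 1.0
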