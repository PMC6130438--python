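import numpy as np
import pytest
from scipy import signal

import ezloc
from ezloc.exceptions import (
    AnnotationError,
    ConfigurationError,
    FormatError,
)
from ezloc.preprocess import write_edf


def _sine_recording(freqs, fs=1000.0, dur=4.0, onset=1.0, offset=3.0):
    t = np.arange(int(dur * fs)) / fs
    samples = np.array([np.sin(2 * np.pi * f * t) for f in freqs])
    return ezloc.Recording(
        samples=samples, fs=fs,
        channel_labels=[f"C{i}" for i in range(len(freqs))],
        onset_index=int(onset * fs), offset_index=int(offset * fs),
    )


class TestRecordingInvariants:
    def test_duplicate_labels_rejected(self):
        with pytest.raises(FormatError):
            ezloc.Recording(
                samples=np.zeros((2, 100)), fs=100.0,
                channel_labels=["G1", "G1"], onset_index=10, offset_index=50,
            )

    def test_onset_must_precede_offset(self):
        with pytest.raises(AnnotationError):
            ezloc.Recording(
                samples=np.zeros((2, 100)), fs=100.0,
                channel_labels=["a", "b"], onset_index=50, offset_index=50,
            )

    def test_bad_channels_must_exist(self):
        with pytest.raises(AnnotationError):
            ezloc.Recording(
                samples=np.zeros((2, 100)), fs=100.0,
                channel_labels=["a", "b"], onset_index=10, offset_index=50,
                bad_channels={"zz"},
            )


class TestReadWrite:
    def test_edf_round_trip(self, tmp_path, rng):
        """Write a 3-channel EDF, read it back through MNE's reader."""
        fs = 200.0
        samples = rng.standard_normal((3, 2000)) * 50.0
        path = tmp_path / "clip.edf"
        write_edf(path, samples, fs, ["G1", "G2", "G3"])
        rec = ezloc.read_recording(path, {
            "onset_sec": 5.0, "offset_sec": 9.0, "cez": ["G1"],
            "outcome": "success", "center_id": "SYN",
        })
        assert rec.n_channels == 3
        assert rec.channel_labels == ["G1", "G2", "G3"]
        assert rec.fs == fs
        assert (rec.onset_index, rec.offset_index) == (1000, 1800)
        # 16-bit quantization of the per-channel extremum
        quantum = np.abs(samples).max(axis=1, keepdims=True) / 32767
        assert np.all(np.abs(rec.samples[:, :2000] - samples) <= quantum)

    def test_csv_round_trip(self, tmp_path, rng):
        samples = rng.standard_normal((4, 300))
        rec = ezloc.Recording(
            samples=samples, fs=100.0,
            channel_labels=["a", "b", "c", "d"],
            onset_index=100, offset_index=200, cez={"a"},
            outcome="failure", center_id="X",
        )
        ezloc.write_recording(rec, tmp_path / "m.csv", tmp_path / "m.json")
        back = ezloc.read_recording(tmp_path / "m.csv", tmp_path / "m.json")
        np.testing.assert_allclose(back.samples, samples, atol=1e-12)
        assert back.cez == {"a"}
        assert back.outcome == "failure"
        assert (back.onset_index, back.offset_index) == (100, 200)

    def test_onset_equal_offset_is_annotation_error(self, tmp_path, rng):
        samples = rng.standard_normal((2, 100))
        rec = ezloc.Recording(samples=samples, fs=100.0,
                              channel_labels=["a", "b"],
                              onset_index=10, offset_index=50)
        ezloc.write_recording(rec, tmp_path / "m.csv")
        with pytest.raises(AnnotationError):
            ezloc.read_recording(
                tmp_path / "m.csv",
                {"fs": 100.0, "onset_sec": 1.0, "offset_sec": 1.0},
            )

    def test_duplicate_csv_header_is_format_error(self, tmp_path):
        (tmp_path / "dup.csv").write_text("G1,G1\n0.0,1.0\n0.5,1.5\n")
        with pytest.raises(FormatError):
            ezloc.read_recording(
                tmp_path / "dup.csv",
                {"fs": 10.0, "onset_sec": 0.0, "offset_sec": 0.1},
            )


class TestNotchFilter:
    def test_60hz_attenuated_at_least_20db(self):
        rec = _sine_recording([60.0])
        out = ezloc.notch_filter(rec)
        core = slice(500, 3500)  # avoid filtfilt edge effects
        rms_in = np.sqrt(np.mean(rec.samples[0, core] ** 2))
        rms_out = np.sqrt(np.mean(out.samples[0, core] ** 2))
        attenuation_db = 20 * np.log10(rms_in / rms_out)
        assert attenuation_db >= 20.0
        # consistent with the cascaded forward-backward magnitude response
        sos = signal.butter(4, (59.5, 60.5), btype="bandstop", fs=rec.fs,
                            output="sos")
        _, h = signal.sosfreqz(sos, worN=[60.0], fs=rec.fs)
        predicted_db = -40 * np.log10(np.abs(h[0]))  # |H|^2: applied twice
        assert predicted_db >= 20.0

    def test_dc_passes_unchanged(self):
        rec = _sine_recording([60.0])
        rec.samples[0] = 1.0
        out = ezloc.notch_filter(rec)
        np.testing.assert_allclose(out.samples[0], 1.0, atol=1e-6)

    def test_zero_phase_in_passband(self):
        rec = _sine_recording([10.0])
        out = ezloc.notch_filter(rec)
        core = slice(500, 3500)
        xc = signal.correlate(out.samples[0, core], rec.samples[0, core],
                              mode="full")
        lag = np.argmax(xc) - (len(rec.samples[0, core]) - 1)
        assert lag == 0

    def test_idempotent_outside_stop_band(self):
        rec = _sine_recording([10.0, 25.0])
        once = ezloc.notch_filter(rec)
        twice = ezloc.notch_filter(once)
        core = slice(500, 3500)
        np.testing.assert_allclose(
            twice.samples[:, core], once.samples[:, core], atol=1e-3
        )

    def test_low_sampling_rate_rejected(self):
        rec = _sine_recording([10.0], fs=100.0)
        with pytest.raises(ConfigurationError):
            ezloc.notch_filter(rec)


class TestCommonAverageReference:
    def test_constant_channels(self):
        rec = ezloc.Recording(
            samples=np.array([[1.0] * 10, [2.0] * 10, [3.0] * 10]),
            fs=10.0, channel_labels=["a", "b", "c"],
            onset_index=2, offset_index=8,
        )
        out = ezloc.common_average_reference(rec)
        np.testing.assert_allclose(out.samples[:, 0], [-1.0, 0.0, 1.0])

    def test_identical_channels_zero_out(self, rng):
        x = rng.standard_normal(50)
        rec = ezloc.Recording(
            samples=np.tile(x, (3, 1)), fs=10.0,
            channel_labels=["a", "b", "c"], onset_index=5, offset_index=40,
        )
        out = ezloc.common_average_reference(rec)
        np.testing.assert_allclose(out.samples, 0.0, atol=1e-12)

    def test_retained_sum_is_zero_and_bad_channels_untouched(self, rng):
        samples = rng.standard_normal((5, 200))
        rec = ezloc.Recording(
            samples=samples, fs=100.0,
            channel_labels=list("abcde"), onset_index=10, offset_index=180,
            bad_channels={"c"},
        )
        out = ezloc.common_average_reference(rec)
        retained = out.retained_samples()
        scale = np.abs(samples).max()
        np.testing.assert_allclose(retained.sum(axis=0), 0.0,
                                   atol=1e-9 * scale)
        np.testing.assert_array_equal(out.samples[2], samples[2])

    def test_too_few_retained_channels(self):
        rec = ezloc.Recording(
            samples=np.zeros((2, 100)), fs=100.0,
            channel_labels=["a", "b"], onset_index=10, offset_index=50,
            bad_channels={"a"},
        )
        with pytest.raises(ConfigurationError):
            ezloc.common_average_reference(rec)


class TestExtractClip:
    def test_pads_60s_each_side(self, rng):
        fs = 100.0
        rec = ezloc.Recording(
            samples=rng.standard_normal((2, int(fs * 200))), fs=fs,
            channel_labels=["a", "b"],
            onset_index=int(fs * 70), offset_index=int(fs * 120),
        )
        clip = ezloc.extract_clip(rec)
        assert clip.n_samples == int(fs * (60 + 50 + 60))
        assert clip.onset_index == int(fs * 60)
        assert clip.offset_index == int(fs * 110)

    def test_truncated_with_warning(self, rng):
        fs = 100.0
        rec = ezloc.Recording(
            samples=rng.standard_normal((2, int(fs * 100))), fs=fs,
            channel_labels=["a", "b"],
            onset_index=int(fs * 10), offset_index=int(fs * 50),
        )
        with pytest.warns(UserWarning, match="truncated"):
            clip = ezloc.extract_clip(rec)
        assert clip.n_samples == rec.n_samples  # both ends truncated
        assert clip.onset_index == rec.onset_index
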