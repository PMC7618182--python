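"""I/O, framing, spectral features, folds and balancing."""

import numpy as np
import pytest

from ppgaug import (
    FrameSet,
    PPGRecording,
    frame_recordings,
    frame_signal,
    load_recordings,
    log_power_spectrum,
    patient_folds,
    save_recordings,
    subsample_balance,
)
from ppgaug.data import (
    FormatError,
    check_no_patient_leakage,
    load_frameset,
    save_frameset,
)


def _toy_recordings(fs=100.0, seconds=12.0, classes=(2, 5)):
    rng = np.random.default_rng(3)
    n = int(fs * seconds)
    return [
        PPGRecording(f"pat{i}", rng.standard_normal(n), fs, cls)
        for i, cls in enumerate(classes)
    ]


class TestRecordingIO:
    def test_round_trip(self, tmp_path):
        recs = _toy_recordings()
        save_recordings(recs, tmp_path)
        back = load_recordings(tmp_path)
        assert len(back) == len(recs)
        for orig, rt in zip(recs, back):
            np.testing.assert_allclose(rt.signal, orig.signal, rtol=0, atol=1e-15)
            assert rt.patient_id == orig.patient_id
            assert rt.fs == orig.fs

    def test_class_reindexing(self, tmp_path):
        save_recordings(_toy_recordings(classes=(2, 5, 5)), tmp_path)
        back = load_recordings(tmp_path)
        # on-disk labels {2, 5} -> consecutive {1, 2} in sorted order
        assert [r.severity_class for r in back] == [1, 2, 2]

    def test_missing_meta_field(self, tmp_path):
        (tmp_path / "a.csv").write_text("0.1\n0.2\n")
        (tmp_path / "a.meta").write_text("patient_id=x\nclass=1\n")  # no fs
        with pytest.raises(FormatError, match="fs"):
            load_recordings(tmp_path)

    def test_non_numeric_sample(self, tmp_path):
        (tmp_path / "a.csv").write_text("0.1\nnope\n")
        (tmp_path / "a.meta").write_text("patient_id=x\nclass=1\nfs=100\n")
        with pytest.raises(FormatError, match="non-numeric"):
            load_recordings(tmp_path)

    def test_empty_directory(self, tmp_path):
        with pytest.raises(FormatError, match="no .csv"):
            load_recordings(tmp_path)

    def test_unsupported_format(self, tmp_path):
        with pytest.raises(ValueError, match="unsupported format"):
            load_recordings(tmp_path, format="wfdb")


class TestFraming:
    def test_counts_and_shape(self):
        rec = _toy_recordings(seconds=12.0)[0]
        fr = frame_signal(rec, frame_seconds=5.0, overlap_frac=0.5)
        # 1200 samples, L=500, hop=250 -> (1200-500)//250 + 1 = 3 frames
        assert fr.frames.shape == (3, 500)
        np.testing.assert_array_equal(fr.frames[1], rec.signal[250:750])
        assert fr.labels.tolist() == [rec.severity_class] * 3
        assert set(fr.patient_ids) == {rec.patient_id}

    def test_no_overlap(self):
        rec = _toy_recordings(seconds=15.0)[0]
        fr = frame_signal(rec, 5.0, overlap_frac=0.0)
        assert len(fr) == 3
        np.testing.assert_array_equal(fr.frames.ravel(), rec.signal[:1500])

    def test_too_short_signal(self):
        rec = PPGRecording("p", np.zeros(400), 100.0, 1)
        with pytest.raises(ValueError, match="shorter"):
            frame_signal(rec, 5.0)

    def test_frame_recordings_mixed_fs(self):
        recs = _toy_recordings()
        recs[1] = PPGRecording("q", recs[1].signal, 50.0, 1)
        with pytest.raises(ValueError, match="sampling rate"):
            frame_recordings(recs)


class TestLogPowerSpectrum:
    def test_bin_count(self, sinusoid_frames):
        feats = log_power_spectrum(sinusoid_frames)
        assert feats.features.shape == (len(sinusoid_frames), 50)

    def test_tone_lands_in_right_bin(self):
        fs, L = 100.0, 500
        t = np.arange(L) / fs
        x = np.sin(2 * np.pi * 7.0 * t)
        fr = FrameSet(x[None, :], [1], ["p"], fs, 5.0)
        feats = log_power_spectrum(fr)
        # bins are 1..50 Hz, so 7 Hz is index 6
        assert int(np.argmax(feats.features[0])) == 6

    def test_non_integer_seconds_rejected(self):
        fr = FrameSet(np.zeros((2, 250)), [1, 1], ["p", "p"], 100.0, 2.5)
        with pytest.raises(ValueError, match="integer number of seconds"):
            log_power_spectrum(fr)


class TestFoldsAndBalance:
    def test_patient_folds_no_leakage(self, small_cohort_frames):
        folds = patient_folds(small_cohort_frames, patients_per_class=1, seed=0)
        assert len(folds) == 3  # 3 patients per class
        assert check_no_patient_leakage(small_cohort_frames, folds)
        n = len(small_cohort_frames)
        for train_idx, test_idx in folds:
            assert np.union1d(train_idx, test_idx).size == n
            # exactly one test patient per class
            for cls in small_cohort_frames.classes:
                sel = small_cohort_frames.labels[test_idx] == cls
                assert np.unique(small_cohort_frames.patient_ids[test_idx][sel]).size == 1

    def test_patient_folds_deterministic(self, small_cohort_frames):
        f1 = patient_folds(small_cohort_frames, seed=7)
        f2 = patient_folds(small_cohort_frames, seed=7)
        for (a, b), (c, d) in zip(f1, f2):
            np.testing.assert_array_equal(a, c)
            np.testing.assert_array_equal(b, d)

    def test_subsample_balance(self):
        rng = np.random.default_rng(0)
        fr = FrameSet(
            rng.standard_normal((10, 8)),
            [1, 1, 1, 1, 1, 1, 2, 2, 2, 2],
            [f"p{i}" for i in range(10)],
            8.0,
            1.0,
        )
        bal = subsample_balance(fr, seed=0)
        assert bal.class_counts() == {1: 4, 2: 4}
        # every retained frame is an original frame
        for row in bal.frames:
            assert any(np.array_equal(row, orig) for orig in fr.frames)

    def test_frameset_round_trip(self, tmp_path, small_cohort_frames):
        fr = small_cohort_frames.subset(np.arange(5))
        fr.provenance = np.array(["real"] * 5)
        path = tmp_path / "frames.npz"
        save_frameset(fr, path)
        back = load_frameset(path)
        np.testing.assert_array_equal(back.frames, fr.frames)
        np.testing.assert_array_equal(back.labels, fr.labels)
        np.testing.assert_array_equal(back.patient_ids, fr.patient_ids)
        np.testing.assert_array_equal(back.provenance, fr.provenance)
        assert back.fs == fr.fs and back.frame_seconds == fr.frame_seconds

    def test_frameset_validation(self):
        with pytest.raises(ValueError, match="align"):
            FrameSet(np.zeros((3, 4)), [1, 2], ["a", "b", "c"], 4.0, 1.0)
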